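"""Scenario engine: operating characteristics of borrowing designs.

For each scenario x design cell this module simulates basket trials,
applies the design's analysis and the posterior-probability rejection
rule, and accumulates per-indication rejection rates, MSE of the point
estimate, and (optionally) the design-stage MSE-based prior ESS — the
trio a trialist inspects side by side when judging a borrowing strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import Design, calibrate_phi
from .engine import generate_trial, run_replications
from .ess import ess_from_mse
from .types import OCResult, Scenario

__all__ = [
    "builtin_scenarios",
    "generate_trial",
    "StudySpec",
    "run_operating_characteristics",
    "summarize_by_truth",
    "results_to_tidy",
]


def builtin_scenarios(n_per_arm: int = 30, null_orr: float = 0.15,
                      target_orr: float = 0.3) -> list[Scenario]:
    """The five four-indication benchmark scenarios.

    Scenario 1 is the global null (all arms at the null ORR), Scenario 2
    the global alternative, and Scenarios 3-5 mix effective and
    ineffective arms — where the risks of borrowing surface.
    """
    p0, p1 = null_orr, target_orr
    patterns = [
        (p0, p0, p0, p0),
        (p1, p1, p1, p1),
        (p1, p0, p0, p0),
        (p1, p1, p0, p0),
        (p1, p1, p1, p0),
    ]
    return [Scenario(pat, (n_per_arm,) * 4, null_orr, target_orr,
                     label=f"Scenario {i + 1}")
            for i, pat in enumerate(patterns)]


@dataclass
class StudySpec:
    """Configuration of a simulation study."""

    scenarios: list[Scenario]
    designs: list[Design]
    reps: int = 1000
    seed: int = 0
    phi: float | str = "calibrate"  # shared threshold, or "calibrate"
    target_alpha: float = 0.05
    calibration_reps: int | None = None  # defaults to reps
    compute_ess: bool = True

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.scenarios or not self.designs:
            raise ValueError("need at least one scenario and one design")
        K = self.scenarios[0].K
        if any(s.K != K for s in self.scenarios):
            raise ValueError("scenario dimensions must be consistent")


def run_operating_characteristics(spec: StudySpec) -> list[OCResult]:
    """Simulate every scenario x design cell.

    A design's phi is calibrated once under the global-null scenario (all
    arms at the null rate) on a separate seed substream, then applied to
    fresh replications of every scenario.  The per-scenario prior ESS is
    computed from the pooled replication set, since the design-stage ESS
    is a functional of the MSE across replications rather than of any
    single trial.
    """
    null_scenario = Scenario(
        (spec.scenarios[0].null_orr,) * spec.scenarios[0].K,
        spec.scenarios[0].n, spec.scenarios[0].null_orr,
        spec.scenarios[0].target_orr, label="calibration null")
    results: list[OCResult] = []
    for d_idx, design in enumerate(spec.designs):
        if spec.phi == "calibrate":
            cal = calibrate_phi(
                null_scenario, design, spec.target_alpha,
                spec.calibration_reps or spec.reps,
                seed=_substream(spec.seed, d_idx, 0), )
            phi = cal.phi
        else:
            phi = float(spec.phi)
        for s_idx, scenario in enumerate(spec.scenarios):
            oc_seed = _substream(spec.seed, d_idx, 1 + s_idx)
            means, tails = run_replications(
                scenario, design.fit, spec.reps, oc_seed,
                threshold=scenario.null_orr)
            truth = np.asarray(scenario.true_orr)
            reject = (tails > phi).mean(axis=0)
            mse = ((means - truth) ** 2).mean(axis=0)
            if spec.compute_ess:
                prior_ess = tuple(
                    ess_from_mse(mse[k], truth[k], scenario.n[k]).prior_ess
                    if 0 < truth[k] < 1 else None
                    for k in range(scenario.K))
            else:
                prior_ess = (None,) * scenario.K
            results.append(OCResult(
                scenario=scenario.label or f"scenario{s_idx + 1}",
                design=design.name,
                true_orr=tuple(truth),
                reject_rate=tuple(float(r) for r in reject),
                mse=tuple(float(m) for m in mse),
                prior_ess=prior_ess,
                reps=spec.reps,
                seed=oc_seed,
                phi=phi,
                null_orr=scenario.null_orr,
            ))
    return results


def _substream(master: int, d_idx: int, cell: int) -> int:
    return int(np.random.SeedSequence([master, d_idx, cell])
               .generate_state(1)[0] & 0x7FFFFFFF)


def results_to_tidy(results: list[OCResult]) -> pd.DataFrame:
    """Long-format table: one row per scenario x design x indication."""
    rows = []
    for r in results:
        mc_se = [float(np.sqrt(max(p * (1 - p), 1e-12) / r.reps))
                 for p in r.reject_rate]
        for k in range(len(r.true_orr)):
            rows.append({
                "scenario": r.scenario,
                "design": r.design,
                "indication": k + 1,
                "true_orr": r.true_orr[k],
                "reject_pct": 100.0 * r.reject_rate[k],
                "mse": r.mse[k],
                "prior_ess": r.prior_ess[k],
                "reps": r.reps,
                "phi": r.phi,
                "reject_mc_se_pct": 100.0 * mc_se[k],
            })
    return pd.DataFrame(rows)


def summarize_by_truth(results: list[OCResult]) -> pd.DataFrame:
    """Average metrics over indications sharing the same true ORR.

    Groups are labeled "A" (alternative arms, ORR above the null rate)
    and "N" (null arms), matching how strategy comparisons are usually
    displayed.
    """
    if not results:
        raise ValueError("no results to summarize")
    tidy = results_to_tidy(results)
    null_rates = {r.scenario: r.null_orr for r in results}
    tidy["group"] = ["N" if np.isclose(t, null_rates[s]) else "A"
                     for t, s in zip(tidy.true_orr, tidy.scenario)]
    return (tidy.groupby(["scenario", "design", "group", "true_orr"],
                         as_index=False)
            .agg(reject_pct=("reject_pct", "mean"),
                 mse=("mse", "mean"),
                 prior_ess=("prior_ess", "mean"),
                 n_arms=("indication", "count")))
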