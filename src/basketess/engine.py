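"""Trial simulation plumbing: reproducible data generation and the
replication loop shared by the ESS, calibration and operating-characteristic
machinery.

Seed policy: a single master seed spawns independent per-replication
substreams (one for the trial data, one for the MCMC fit), so results do
not depend on evaluation order or worker count.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .types import BasketData, PosteriorSummary, Scenario

__all__ = ["generate_trial", "replication_seeds", "run_replications"]

_SEED_MASK = 0x7FFFFFFF  # keep derived seeds below 2**31


def generate_trial(scenario: Scenario, seed) -> BasketData:
    """Draw one synthetic basket trial: Y_k ~ Bin(n_k, p_k) independently."""
    rng = np.random.default_rng(seed)
    y = rng.binomial(scenario.n, scenario.true_orr)
    labels = [f"arm{k + 1}" for k in range(scenario.K)]
    return BasketData(labels, scenario.n, y)


def replication_seeds(master_seed: int, reps: int) -> list[tuple[np.random.SeedSequence, int]]:
    """(data substream, fit seed) pairs for ``reps`` replications."""
    children = np.random.SeedSequence(master_seed).spawn(2 * reps)
    out = []
    for r in range(reps):
        fit_seed = int(children[2 * r + 1].generate_state(1)[0] & _SEED_MASK)
        out.append((children[2 * r], fit_seed))
    return out


def run_replications(
    scenario: Scenario,
    fit: Callable[[BasketData, int], PosteriorSummary],
    reps: int,
    seed: int,
    threshold: float | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate ``reps`` trials and fit each one.

    Returns the (reps, K) matrix of posterior means and, when ``threshold``
    is given, the matching matrix of posterior tail probabilities
    Pr(p_k > threshold | data).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    means = np.empty((reps, scenario.K))
    tails = np.empty((reps, scenario.K)) if threshold is not None else None
    for r, (data_ss, fit_seed) in enumerate(replication_seeds(seed, reps)):
        data = generate_trial(scenario, data_ss)
        try:
            summary = fit(data, fit_seed)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"fit failed at replication {r}") from exc
        means[r] = summary.mean
        if tails is not None:
            tails[r] = summary.tail_prob(threshold)
    return means, tails
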