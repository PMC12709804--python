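"""Reading and writing: trial-data CSVs, result tables, configs, manifests.

The trial-data dialect is a UTF-8 CSV with header ``indication,n,y`` and
one row per basket (this matches how per-tumor-type counts are reported in
basket-trial publications, so published tables can be transcribed
directly).  Configuration files are YAML validated against a strict
schema; every run can write a JSON manifest that makes it reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .types import BasketData, ESSResult, PosteriorSummary, PriorSpec, PRIOR_A, PRIOR_B

__all__ = [
    "read_basket_csv",
    "write_basket_csv",
    "ess_results_to_df",
    "draws_to_df",
    "RunConfig",
    "load_config",
    "write_manifest",
    "prior_from_name",
]


def read_basket_csv(path) -> BasketData:
    """Load a basket trial from the ``indication,n,y`` CSV dialect.

    Rejects missing columns, duplicated labels, and inconsistent rows
    (negative counts, y > n) with row-level diagnostics.
    """
    df = pd.read_csv(path)
    required = ["indication", "n", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"expected header 'indication,n,y'")
    bad = []
    for idx, row in df.iterrows():
        try:
            n, y = int(row["n"]), int(row["y"])
            if n <= 0 or y < 0 or y > n:
                raise ValueError
        except (ValueError, TypeError):
            bad.append(int(idx) + 2)  # 1-based, plus header line
    if bad:
        raise ValueError(f"{path}: invalid counts at line(s) {bad} "
                         "(need integers with 0 <= y <= n, n > 0)")
    return BasketData(df["indication"].astype(str).tolist(),
                      df["n"].astype(int).tolist(),
                      df["y"].astype(int).tolist())


def write_basket_csv(data: BasketData, path) -> None:
    pd.DataFrame({"indication": data.labels, "n": data.n, "y": data.y}) \
        .to_csv(path, index=False)


def ess_results_to_df(data: BasketData, results: list[ESSResult]) -> pd.DataFrame:
    """One row per indication: ESS numbers plus the status flag."""
    rows = []
    for label, r in zip(data.labels, results):
        rows.append({
            "indication": label,
            "method": r.method,
            "posterior_ess": r.posterior_ess,
            "prior_ess": r.prior_ess,
            "mse_bayes": r.mse_bayes,
            "status": r.status,
        })
    return pd.DataFrame(rows)


def draws_to_df(data: BasketData, summary: PosteriorSummary) -> pd.DataFrame:
    """Posterior draws in long format (draw, indication, p, mu, sigma2)."""
    if summary.draws is None:
        raise ValueError("summary carries no draws (closed-form fit)")
    n_draws, K = summary.draws.shape
    frames = []
    for k, label in enumerate(data.labels):
        frames.append(pd.DataFrame({
            "draw": np.arange(n_draws),
            "indication": label,
            "p": summary.draws[:, k],
        }))
    out = pd.concat(frames, ignore_index=True)
    if summary.mu_draws is not None:
        out["mu"] = np.tile(summary.mu_draws, K)
    if summary.sigma2_draws is not None:
        out["sigma2"] = np.tile(summary.sigma2_draws, K)
    return out


def prior_from_name(name: str) -> PriorSpec:
    presets = {"A": PRIOR_A, "B": PRIOR_B,
               "prior a": PRIOR_A, "prior b": PRIOR_B}
    key = name.strip().lower().removeprefix("prior ").upper()
    if key in ("A", "B"):
        return PRIOR_A if key == "A" else PRIOR_B
    raise ValueError(f"unknown prior preset {name!r}; use 'A' or 'B'")


# ---------------------------------------------------------------------------
# Config schema (strict: unknown keys rejected)
# ---------------------------------------------------------------------------


class PriorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Literal["A", "B"] | None = None
    mu_mean: float = -2.19
    mu_sd: float = Field(default=2.0, gt=0)
    sigma2_shape: float | None = Field(default=None, gt=0)
    sigma2_scale: float | None = Field(default=None, gt=0)
    sigma2_fixed: float | None = Field(default=None, ge=0)

    def to_spec(self) -> PriorSpec:
        if self.preset is not None:
            return prior_from_name(self.preset)
        return PriorSpec(self.mu_mean, self.mu_sd, self.sigma2_shape,
                         self.sigma2_scale, self.sigma2_fixed)


class DesignBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["bhm", "cbhm", "power_prior", "ess_ms", "independent", "pooled"]
    prior: PriorBlock | None = None
    a: float | None = None  # tuning for cbhm / power_prior
    b: float | None = None
    beta_a: float = Field(default=0.5, gt=0)
    beta_b: float = Field(default=0.5, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if self.kind in ("bhm", "ess_ms") and self.prior is None:
            raise ValueError(f"design '{self.kind}' needs a prior block")
        return self


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reps: int = Field(default=1000, ge=1)
    n_per_arm: int = Field(default=30, ge=1)
    null_orr: float = Field(default=0.15, gt=0, lt=1)
    target_orr: float = Field(default=0.3, gt=0, lt=1)
    phi: float | Literal["calibrate"] = "calibrate"
    target_alpha: float = Field(default=0.05, gt=0, lt=1)


class McmcBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    iterations: int = Field(default=5000, ge=10)
    burn_in: int = Field(default=2000, ge=0)
    thin: int = Field(default=1, ge=1)


class RunConfig(BaseModel):
    """Top-level YAML configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    data: str | None = None
    seed: int = 0
    out_dir: str = "results"
    prior: PriorBlock = PriorBlock()
    designs: list[DesignBlock] = []
    simulation: SimulationBlock = SimulationBlock()
    mcmc: McmcBlock = McmcBlock()


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def write_manifest(path, *, seed: int, config: dict | None = None,
                   extra: dict | None = None) -> None:
    """JSON manifest that makes a run reproducible (seed, version, config)."""
    from . import __version__

    manifest = {"package": "basketess", "version": __version__, "seed": seed}
    if config:
        manifest["config"] = config
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
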