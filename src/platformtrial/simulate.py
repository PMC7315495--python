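"""Patient-level simulation of a two-stage trial that adds an arm.

Responses follow ``X_j = mu_{T_j} + tau(j) + eps_j`` with i.i.d. normal
errors of known variance.  Allocation is restricted randomization within
each stage: one random permutation of the stage's allocation multiset, so
per-arm per-stage counts are exact in every realisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import EffectSpec, TrendSpec, TrialDesign

__all__ = ["TrialData", "allocate", "trend_value", "simulate_trial"]


@dataclass(frozen=True)
class TrialData:
    """One realised trial: enrolment order, stage, arm and response per patient."""

    design: TrialDesign
    stage: np.ndarray  # 1 or 2, shape (n_total,)
    arm: np.ndarray    # allocated treatment T_j in 0..K+1
    x: np.ndarray      # response X_j

    @property
    def j(self) -> np.ndarray:
        """Global enrolment order, 1-based and continuing across stages."""
        return np.arange(1, self.x.size + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"j": self.j, "stage": self.stage, "arm": self.arm, "response": self.x}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def allocate(design: TrialDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw one restricted-randomization arm sequence for the whole trial.

    Stage one is a uniformly random permutation of a multiset holding
    exactly ``n_k1`` copies of each initial arm ``k``; stage two likewise
    with ``n_k2`` copies of arms ``0 .. K+1``.  Counts are exact by
    construction, which is what keeps stage-wise contrasts trend-balanced
    for the initial arms.
    """
    n_ks = design.n_ks
    stage1 = np.repeat(np.arange(design.K + 2), n_ks[:, 0])
    stage2 = np.repeat(np.arange(design.K + 2), n_ks[:, 1])
    return np.concatenate([rng.permutation(stage1), rng.permutation(stage2)])


def trend_value(trend: TrendSpec, j, total_n: int, stage) -> np.ndarray | float:
    """Evaluate the trend tau(j) for enrolment positions ``j``.

    ``linear`` drifts from 0 at the first patient up to ``lam`` at the
    last one: ``lam * (j - 1) / (total_n - 1)``.  ``step`` adds ``lam`` to
    every stage-two patient.  Accepts scalars or arrays; negative ``lam``
    is allowed (a deteriorating trend).
    """
    j = np.asarray(j)
    if np.any(j < 1) or np.any(j > total_n):
        raise ValueError("enrolment index out of range")
    if trend.family == "none":
        return np.zeros(j.shape) if j.shape else 0.0
    if trend.family == "linear":
        if total_n < 2:
            raise ValueError("linear trend needs at least two patients")
        return trend.lam * (j - 1) / (total_n - 1)
    # step
    return trend.lam * (np.asarray(stage) == 2).astype(float)


def simulate_trial(
    design: TrialDesign,
    effects: EffectSpec,
    trend: TrendSpec,
    rng: np.random.Generator,
) -> TrialData:
    """Generate one trial under the additive response model.

    ``X_j = mu_{T_j} + tau(j) + eps_j`` with ``eps_j ~ N(0, sigma^2)``.
    Deterministic given the generator state; ``sigma2 = 0`` yields the
    noiseless mean surface, handy for exact checks.
    """
    mu = effects.mu(design.K)
    arm = allocate(design, rng)
    n_total = design.n_total
    stage = np.where(np.arange(n_total) < design.n_stage1, 1, 2)
    j = np.arange(1, n_total + 1)
    tau = trend_value(trend, j, n_total, stage)
    eps = rng.normal(0.0, np.sqrt(design.sigma2), size=n_total)
    x = mu[arm] + tau + eps
    return TrialData(design=design, stage=stage, arm=arm, x=x)
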