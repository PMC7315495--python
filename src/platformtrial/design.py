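"""Trial-design data model for a two-stage platform trial that adds one arm.

A trial starts with ``K`` experimental arms plus a shared control (arm 0).
After a fraction ``timing = n_01 / n_0`` of the control patients have been
enrolled, stage one ends and a new experimental arm (labelled ``K + 1``)
joins for stage two with ``n_new`` patients.  Everything downstream — the
simulator, the estimators and the closed-form operating characteristics —
works off the stage-wise sample-size matrix derived here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "TrialDesign",
    "TrendSpec",
    "EffectSpec",
    "derive_stage_sizes",
    "design_from_config",
]

_TREND_FAMILIES = ("none", "linear", "step")


def _round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def derive_stage_sizes(
    K: int,
    n_arm: Sequence[int],
    timing: float,
    n_new: int,
) -> np.ndarray:
    """Split per-arm totals into stage-wise sample sizes.

    Parameters
    ----------
    K : int
        Number of initial experimental arms (control excluded).
    n_arm : sequence of int
        Total sample sizes ``n_0, ..., n_K`` for control and initial arms.
    timing : float
        Fraction ``n_01 / n_0`` of control patients enrolled before the new
        arm is added; must lie strictly in (0, 1).
    n_new : int
        Stage-two sample size of the added arm ``K + 1``.

    Returns
    -------
    numpy.ndarray
        Integer matrix of shape ``(K + 2, 2)`` whose ``[k, s-1]`` entry is
        ``n_ks``.  Row ``K + 1`` is ``(0, n_new)``: the added arm enrols in
        stage two only.

    Notes
    -----
    The stage-one control size is ``round(timing * n_0)`` with half-up
    rounding, and each initial experimental arm follows the control split
    (balanced allocation among concurrently open arms).  A ``timing`` that
    would leave the control arm with zero concurrent or zero non-concurrent
    patients is rejected: both kinds of control data must exist for the
    design to pose the question this package studies.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    n_arm = [int(n) for n in n_arm]
    if len(n_arm) != K + 1:
        raise ValueError(f"n_arm must have K+1={K + 1} entries, got {len(n_arm)}")
    if any(n <= 0 for n in n_arm) or n_new <= 0:
        raise ValueError("all arm sizes must be positive")
    if not 0.0 < timing < 1.0:
        raise ValueError(f"timing must be in (0, 1), got {timing}")

    n0 = n_arm[0]
    n01 = _round_half_up(timing * n0)
    if n01 in (0, n0):
        raise ValueError(
            f"timing {timing} leaves the control arm without "
            f"{'non-concurrent' if n01 == 0 else 'concurrent'} patients"
        )
    frac1 = n01 / n0
    n_ks = np.zeros((K + 2, 2), dtype=int)
    for k, nk in enumerate(n_arm):
        nk1 = _round_half_up(frac1 * nk)
        n_ks[k] = (nk1, nk - nk1)
    if np.any(n_ks < 0):
        raise ValueError("derived stage sizes must be non-negative")
    n_ks[K + 1] = (0, n_new)
    return n_ks


@dataclass(frozen=True)
class TrialDesign:
    """Two-stage add-one-arm design.

    Attributes
    ----------
    K : int
        Number of initial experimental arms; control is arm 0, the added
        arm is ``K + 1``.
    n_arm : tuple of int
        Per-arm totals ``n_0, ..., n_K``.
    timing : float
        Fraction of control patients enrolled before the new arm joins.
    n_new : int
        Sample size of the added arm (stage two only).
    sigma2 : float
        Known response variance sigma^2.
    alpha : float
        One-sided significance level for every superiority test.
    """

    K: int
    n_arm: tuple[int, ...]
    timing: float
    n_new: int
    sigma2: float = 1.0
    alpha: float = 0.05
    n_ks: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        object.__setattr__(self, "n_arm", tuple(int(n) for n in self.n_arm))
        n_ks = derive_stage_sizes(self.K, self.n_arm, self.timing, self.n_new)
        n_ks.setflags(write=False)
        object.__setattr__(self, "n_ks", n_ks)

    # --- derived sizes -------------------------------------------------
    @property
    def n_stage1(self) -> int:
        """Stage-one total N1 (initial arms only)."""
        return int(self.n_ks[: self.K + 1, 0].sum())

    @property
    def n_stage2(self) -> int:
        """Stage-two total, including the added arm."""
        return int(self.n_ks[:, 1].sum())

    @property
    def n_total(self) -> int:
        """Overall number of patients N + n_{K+1,2}."""
        return self.n_stage1 + self.n_stage2

    def n_k(self, k: int) -> int:
        """Total sample size of arm ``k`` (works for the added arm too)."""
        return int(self.n_ks[k].sum())

    # --- configuration round-trip --------------------------------------
    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "n_arm": list(self.n_arm),
            "timing": self.timing,
            "n_new": self.n_new,
            "sigma2": self.sigma2,
            "alpha": self.alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialDesign":
        return cls(
            K=int(d["K"]),
            n_arm=tuple(int(n) for n in d["n_arm"]),
            timing=float(d["timing"]),
            n_new=int(d["n_new"]),
            sigma2=float(d.get("sigma2", 1.0)),
            alpha=float(d.get("alpha", 0.05)),
        )


@dataclass(frozen=True)
class TrendSpec:
    """Time-trend family and magnitude.

    ``family`` is one of ``none``, ``linear`` (drift growing with enrolment
    order from 0 up to ``lam`` at the last patient) or ``step`` (a shift of
    ``lam`` for every stage-two patient).  ``lam`` is in response units —
    a fraction of the standard deviation when sigma^2 = 1 — and may be
    negative.
    """

    family: str = "none"
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in _TREND_FAMILIES:
            raise ValueError(f"family must be one of {_TREND_FAMILIES}")
        if self.family == "none" and self.lam != 0.0:
            object.__setattr__(self, "lam", 0.0)

    def to_dict(self) -> dict:
        return {"family": self.family, "lam": self.lam}

    @classmethod
    def from_dict(cls, d: dict) -> "TrendSpec":
        return cls(family=str(d.get("family", "none")), lam=float(d.get("lam", 0.0)))


@dataclass(frozen=True)
class EffectSpec:
    """True control mean and treatment-vs-control effects.

    ``delta[k-1]`` is ``delta_k = mu_k - mu_0`` for arms ``1 .. K+1``; the
    vector therefore has ``K + 1`` entries, the last one belonging to the
    added arm.
    """

    mu0: float
    delta: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "delta", tuple(float(d) for d in self.delta))

    @classmethod
    def null(cls, K: int, mu0: float = 0.0) -> "EffectSpec":
        """Global null: every arm has the control mean."""
        return cls(mu0=mu0, delta=(0.0,) * (K + 1))

    @classmethod
    def uniform(cls, K: int, delta: float, mu0: float = 0.0) -> "EffectSpec":
        """Common effect ``delta`` for every experimental arm."""
        return cls(mu0=mu0, delta=(delta,) * (K + 1))

    def mu(self, K: int) -> np.ndarray:
        """Arm means ``mu_0 .. mu_{K+1}`` as an array."""
        if len(self.delta) != K + 1:
            raise ValueError(
                f"delta must have K+1={K + 1} entries, got {len(self.delta)}"
            )
        return self.mu0 + np.concatenate(([0.0], np.asarray(self.delta)))

    def to_dict(self) -> dict:
        return {"mu0": self.mu0, "delta": list(self.delta)}

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        return cls(mu0=float(d.get("mu0", 0.0)), delta=tuple(d["delta"]))


def design_from_config(path: str | Path) -> tuple[TrialDesign, EffectSpec | None, TrendSpec]:
    """Load a design (and optional effects/trend) from a YAML or JSON file.

    The file holds a mapping with a ``design`` key mirroring
    :class:`TrialDesign` fields, and optional ``effects`` and ``trend``
    keys.  Integer sizes round-trip bit-exactly.
    """
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if "design" not in cfg:
        raise KeyError("configuration must contain a 'design' mapping")
    design = TrialDesign.from_dict(cfg["design"])
    effects = EffectSpec.from_dict(cfg["effects"]) if "effects" in cfg else None
    trend = TrendSpec.from_dict(cfg.get("trend", {}))
    return design, effects, trend
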