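"""Closed-form operating characteristics under the known-variance normal model.

Covers the one-sided Z-test power, the generalized-least-squares variance
and marginal power of the stage-wise mean-difference model in both control
scopes, and the borrowing-of-strength measure quantifying the variance
reduction from non-concurrent control data.  These formulas double as
oracles for the Monte-Carlo engine: with no time trend, empirical rejection
rates must match them to simulation error.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import TrialDesign

__all__ = [
    "ztest_power",
    "wls_design_matrices",
    "wls_variance",
    "wls_marginal_power",
    "borrowing_of_strength",
    "oc_curves",
]

_VARIANTS = ("all", "s2")


def ztest_power(
    delta: float, sigma2: float, n_k: int, n_0: int, alpha: float = 0.05
) -> float:
    """Marginal power of the one-sided Z-test for a single contrast.

    Evaluates ``Phi( delta / sqrt(sigma^2/n_k + sigma^2/n_0) - z_{1-alpha} )``
    — the exact rejection probability of ``H0: mu_k = mu_0`` against the
    one-sided alternative when the contrast estimate is normal with known
    variance.  At ``delta = 0`` this returns ``alpha``.
    """
    if n_k <= 0 or n_0 <= 0:
        raise ValueError("sample sizes must be positive")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    se = np.sqrt(sigma2 / n_k + sigma2 / n_0)
    return float(norm.cdf(delta / se - norm.ppf(1.0 - alpha)))


def wls_design_matrices(
    design: TrialDesign, variant: str
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Build the contrast-to-parameter map D and covariance Sigma.

    The response vector of the stage-wise model stacks the observed
    treatment-minus-control mean differences: for each initial arm
    ``k = 1..K`` one contrast per stage against that stage's control mean,
    plus one contrast for the added arm — against the stage-two control
    mean (``variant='s2'``) or against the overall control mean
    (``variant='all'``, which mixes in the non-concurrent data).

    Returns ``(D, Sigma, labels)`` where row ``i`` of the 0/1 matrix ``D``
    maps contrast ``i`` to its ``delta`` parameter and ``labels[i]`` is the
    ``(arm, stage)`` pair (stage 0 marks the overall-control contrast).
    Covariances arise solely from the shared control cells: contrasts
    built on the same stage-``s`` control co-vary by ``sigma^2 / n_0s``,
    contrasts on different stages are independent, and the overall-control
    contrast co-varies with every stage contrast by ``sigma^2 / n_0``.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    K = design.K
    s2 = design.sigma2
    n_ks = design.n_ks
    n0 = design.n_k(0)

    labels: list[tuple[int, int]] = []
    for k in range(1, K + 1):
        labels.append((k, 1))
        labels.append((k, 2))
    labels.append((K + 1, 2 if variant == "s2" else 0))

    m = len(labels)
    D = np.zeros((m, K + 1))
    Sigma = np.zeros((m, m))
    for i, (k, s) in enumerate(labels):
        D[i, k - 1] = 1.0
        if s == 0:
            Sigma[i, i] = s2 / design.n_new + s2 / n0
        else:
            n_cell = n_ks[k, s - 1]
            if n_cell <= 0 or n_ks[0, s - 1] <= 0:
                raise ValueError(f"empty cell for arm {k}, stage {s}")
            Sigma[i, i] = s2 / n_cell + s2 / n_ks[0, s - 1]
        for jdx in range(i):
            kj, sj = labels[jdx]
            if s == 0 or sj == 0:
                cov = s2 / n0
            elif s == sj:
                cov = s2 / n_ks[0, s - 1]
            else:
                cov = 0.0
            Sigma[i, jdx] = Sigma[jdx, i] = cov
    return D, Sigma, labels


def wls_variance(design: TrialDesign, variant: str) -> np.ndarray:
    """Covariance of the GLS effect estimates, ``(D' Sigma^-1 D)^-1``.

    Entry ``[k-1, k-1]`` is ``var(delta_k_hat)``; the last index belongs
    to the added arm.  Raises on a singular contrast covariance (zero or
    duplicated cells).
    """
    D, Sigma, _ = wls_design_matrices(design, variant)
    try:
        Sinv = np.linalg.inv(Sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular contrast covariance for variant {variant!r}") from exc
    info = D.T @ Sinv @ D
    return np.linalg.inv(info)


def wls_marginal_power(
    design: TrialDesign, delta: Sequence[float], variant: str
) -> np.ndarray:
    """Per-arm marginal power of the one-sided GLS test at level alpha.

    ``Phi( delta_k / sqrt(var(delta_k_hat)) - z_{1-alpha} )`` using the
    marginal distribution of each estimate from :func:`wls_variance` — no
    multiplicity adjustment.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (design.K + 1,):
        raise ValueError(f"delta must have K+1={design.K + 1} entries")
    var = np.diag(wls_variance(design, variant))
    return norm.cdf(delta / np.sqrt(var) - norm.ppf(1.0 - design.alpha))


def borrowing_of_strength(design: TrialDesign) -> float:
    """Proportional variance reduction for the added arm, ``(V0 - Va)/V0``.

    ``V0`` is ``var(delta_hat)`` for the added arm when only concurrent
    (stage-two) control data enter the GLS fit; ``Va`` when all control
    data do.  Lies in ``[0, 1)``: including unbiased extra control
    information can only shrink a GLS variance.  Defined for the added
    arm only — initial arms have no non-concurrent controls to borrow.
    """
    v0 = wls_variance(design, "s2")[-1, -1]
    va = wls_variance(design, "all")[-1, -1]
    return float((v0 - va) / v0)


def _resolve_n_new(option, design: TrialDesign) -> int:
    """Map a symbolic new-arm size ('n02', 'n0', '2n0') to patients."""
    if isinstance(option, str):
        n0 = design.n_k(0)
        table = {"n02": int(design.n_ks[0, 1]), "n0": n0, "2n0": 2 * n0}
        if option not in table:
            raise ValueError(f"unknown n_new option {option!r}")
        return table[option]
    return int(option)


def oc_curves(
    n_arm: Sequence[int],
    delta: Sequence[float],
    timings: Iterable[float] | None = None,
    n_new_options: Iterable = ("n02", "n0", "2n0"),
    sigma2: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Analytic power/variance/BoS curves over a (timing, n_new) grid.

    For each grid point, evaluates the added-arm operating characteristics
    of the independent Z-tests (concurrent-only and all-control) and of
    both GLS variants, plus the borrowing-of-strength.  Symbolic new-arm
    sizes are resolved per timing (``'n02'`` tracks the concurrent control
    count).  Returns a tidy table ready for Fig-1-style plotting.
    """
    if timings is None:
        timings = np.round(np.arange(0.05, 0.951, 0.05), 10)
    K = len(n_arm) - 1
    delta = np.asarray(delta, dtype=float)
    rows = []
    for timing in timings:
        for option in n_new_options:
            probe = TrialDesign(K, tuple(n_arm), float(timing), 1, sigma2, alpha)
            n_new = _resolve_n_new(option, probe)
            d = TrialDesign(K, tuple(n_arm), float(timing), n_new, sigma2, alpha)
            n0 = d.n_k(0)
            n02 = int(d.n_ks[0, 1])
            bos = borrowing_of_strength(d)
            entries = {
                "Z_concurrent": (
                    sigma2 / n_new + sigma2 / n02,
                    ztest_power(delta[-1], sigma2, n_new, n02, alpha),
                ),
                "Z_all": (
                    sigma2 / n_new + sigma2 / n0,
                    ztest_power(delta[-1], sigma2, n_new, n0, alpha),
                ),
                "WLS_all": (
                    wls_variance(d, "all")[-1, -1],
                    wls_marginal_power(d, delta, "all")[-1],
                ),
                "WLS_s2": (
                    wls_variance(d, "s2")[-1, -1],
                    wls_marginal_power(d, delta, "s2")[-1],
                ),
            }
            for method, (var, power) in entries.items():
                rows.append(
                    {
                        "timing": float(timing),
                        "n_new_option": str(option),
                        "n_new": n_new,
                        "method": method,
                        "var_delta": float(var),
                        "power": float(power),
                        "bos": bos,
                    }
                )
    return pd.DataFrame(rows)
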