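"""Analysis approaches for one realised trial.

Six ways to estimate and test the treatment-versus-control effects, all
under known sigma^2 with one-sided marginal tests and no multiplicity
adjustment:

* independent Z-tests, with concurrent-only or all control data;
* the stage-wise mean-difference GLS model (``WLS_all`` / ``WLS_s2``);
* patient-level regressions — ``Ma1``/``Ma2`` on all arms with a linear
  enrolment-order term or a stage indicator, ``Mb1``/``Mb2`` on the
  control and added arms only.

Estimates of the added-arm effect differ across methods in how much
non-concurrent control information they absorb, which is exactly what
makes them differently exposed to time trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .analytic import wls_design_matrices
from .design import TrialDesign
from .simulate import TrialData

__all__ = [
    "JointEstimate",
    "stage_means",
    "z_test",
    "wls_stagewise",
    "regression_fit",
]

REGRESSION_MODELS = ("Ma1", "Ma2", "Mb1", "Mb2")


@dataclass(frozen=True)
class JointEstimate:
    """Estimated contrasts, known-variance covariance and one-sided tests."""

    method: str
    params: tuple[str, ...]
    estimate: np.ndarray
    cov: np.ndarray
    zstat: np.ndarray
    reject: np.ndarray
    alpha: float
    nuisance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-parameter export."""
        se = np.sqrt(np.diag(self.cov))
        return pd.DataFrame(
            {
                "method": self.method,
                "parameter": self.params,
                "estimate": self.estimate,
                "std_error": se,
                "zstat": self.zstat,
                "reject": self.reject,
            }
        )


def _one_sided(estimate: np.ndarray, var: np.ndarray, alpha: float):
    """Z statistics and rejections; var = 0 gives z = sign(est) * inf."""
    estimate = np.atleast_1d(np.asarray(estimate, dtype=float))
    var = np.broadcast_to(np.asarray(var, dtype=float), estimate.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = estimate / np.sqrt(var)
    z = np.where(var == 0.0, np.sign(estimate) * np.inf, z)
    z = np.where((var == 0.0) & (estimate == 0.0), 0.0, z)
    return z, z > norm.ppf(1.0 - alpha)


def stage_means(data: TrialData, design: TrialDesign) -> pd.DataFrame:
    """Stage-wise and overall sample means per arm.

    Returns a frame indexed by arm with columns ``stage1``, ``stage2``,
    ``overall``; cells the design plans as empty (the added arm in stage
    one) are NaN.  The overall mean is the count-weighted combination of
    the stage means.  Raises if realised counts disagree with the design
    (the simulator's restricted randomization guarantees agreement).
    """
    K = design.K
    out = np.full((K + 2, 3), np.nan)
    for k in range(K + 2):
        for s in (1, 2):
            planned = design.n_ks[k, s - 1]
            sel = (data.arm == k) & (data.stage == s)
            if sel.sum() != planned:
                raise ValueError(
                    f"arm {k} stage {s}: found {int(sel.sum())} patients, "
                    f"design plans {planned}"
                )
            if planned > 0:
                out[k, s - 1] = data.x[sel].mean()
        n_k = design.n_k(k)
        w = design.n_ks[k] / n_k
        out[k, 2] = np.nansum(w * out[k, :2])
    return pd.DataFrame(
        out, index=pd.RangeIndex(K + 2, name="arm"), columns=["stage1", "stage2", "overall"]
    )


def z_test(
    data: TrialData, design: TrialDesign, k: int, control_scope: str = "all"
) -> JointEstimate:
    """Independent Z-test of ``H0k: mu_k = mu_0`` for a single arm.

    ``control_scope='all'`` contrasts the arm's overall mean against the
    overall control mean; ``'concurrent'`` (meaningful only for the added
    arm) uses stage-two data on both sides.  Known-variance one-sided
    test at the design's alpha.
    """
    if not 1 <= k <= design.K + 1:
        raise ValueError(f"arm index {k} out of range 1..{design.K + 1}")
    if control_scope not in ("all", "concurrent"):
        raise ValueError("control_scope must be 'all' or 'concurrent'")
    if control_scope == "concurrent" and k <= design.K:
        raise ValueError(
            "concurrent-only scope is ill-defined for an initial arm: all its "
            "control data are concurrent"
        )
    means = stage_means(data, design)
    s2 = design.sigma2
    if control_scope == "concurrent":
        est = means.loc[k, "stage2"] - means.loc[0, "stage2"]
        var = s2 / design.n_ks[k, 1] + s2 / design.n_ks[0, 1]
    else:
        est = means.loc[k, "overall"] - means.loc[0, "overall"]
        var = s2 / design.n_k(k) + s2 / design.n_k(0)
    z, rej = _one_sided(est, var, design.alpha)
    return JointEstimate(
        method="Z_concurrent" if control_scope == "concurrent" else "Z_all",
        params=(f"delta_{k}",),
        estimate=np.atleast_1d(float(est)),
        cov=np.array([[var]]),
        zstat=z,
        reject=rej,
        alpha=design.alpha,
    )


def wls_stagewise(data: TrialData, design: TrialDesign, variant: str) -> JointEstimate:
    """GLS fit of the stage-wise mean-difference model.

    Stacks the observed treatment-minus-control stage means into the
    contrast vector defined by :func:`platformtrial.analytic.wls_design_matrices`
    and solves ``delta_hat = (D' S^-1 D)^-1 D' S^-1 y`` with
    ``cov(delta_hat) = (D' S^-1 D)^-1``.  ``variant='all'`` lets the
    added-arm contrast borrow the non-concurrent (stage-one) control
    data; ``'s2'`` keeps it concurrent-only.
    """
    if design.K < 1:
        raise ValueError("the stage-wise model needs at least one initial arm")
    D, Sigma, labels = wls_design_matrices(design, variant)
    means = stage_means(data, design)
    y = np.empty(len(labels))
    for i, (k, s) in enumerate(labels):
        if s == 0:
            y[i] = means.loc[k, "stage2"] - means.loc[0, "overall"]
        else:
            col = f"stage{s}"
            y[i] = means.loc[k, col] - means.loc[0, col]
    try:
        Sinv = np.linalg.inv(Sigma)
        cov = np.linalg.inv(D.T @ Sinv @ D)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular contrast covariance; check stage cell sizes") from exc
    est = cov @ D.T @ Sinv @ y
    z, rej = _one_sided(est, np.diag(cov), design.alpha)
    return JointEstimate(
        method=f"WLS_{variant}",
        params=tuple(f"delta_{k}" for k in range(1, design.K + 2)),
        estimate=est,
        cov=cov,
        zstat=z,
        reject=rej,
        alpha=design.alpha,
    )


def _design_matrix(data: TrialData, design: TrialDesign, model: str):
    """Columns, labels and row subset for one of the patient-level models."""
    K = design.K
    j = data.j.astype(float)
    c = (data.stage == 2).astype(float)
    time_col, time_name = (j, "gamma") if model in ("Ma1", "Mb1") else (c, "nu")
    if model.startswith("Ma"):
        cols = [np.ones(data.x.size)]
        names = ["intercept"]
        for k in range(1, K + 2):
            cols.append((data.arm == k).astype(float))
            names.append(f"delta_{k}")
        keep = np.ones(data.x.size, dtype=bool)
    else:  # Mb: control + added arm only, control absorbed by the intercept
        keep = (data.arm == 0) | (data.arm == K + 1)
        cols = [np.ones(int(keep.sum())), (data.arm[keep] == K + 1).astype(float)]
        names = ["intercept", f"delta_{K + 1}"]
        time_col = time_col[keep]
    cols.append(time_col)
    names.append(time_name)
    return np.column_stack(cols), names, keep


def regression_fit(data: TrialData, design: TrialDesign, model: str) -> JointEstimate:
    """Ordinary least squares on patient-level data, known-sigma^2 inference.

    ``Ma1``/``Ma2`` use every patient with arm indicators plus a linear
    enrolment-order term (``Ma1``) or a stage indicator (``Ma2``); ``Mb1``
    and ``Mb2`` restrict to the control and added arms.  Coefficients come
    from the OLS fit; their covariance is ``sigma^2 (Z'Z)^-1`` since the
    response variance is known.  One-sided tests on the treatment effects.
    """
    if model not in REGRESSION_MODELS:
        raise ValueError(f"model must be one of {REGRESSION_MODELS}")
    Z, names, keep = _design_matrix(data, design, model)
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix for {model} (rank {rank} < {Z.shape[1]}); "
            f"columns: {names}"
        )
    fit = sm.OLS(data.x[keep], Z).fit()
    beta = fit.params
    cov_all = design.sigma2 * np.linalg.inv(Z.T @ Z)

    is_delta = [n.startswith("delta_") for n in names]
    idx = np.flatnonzero(is_delta)
    est = beta[idx]
    cov = cov_all[np.ix_(idx, idx)]
    z, rej = _one_sided(est, np.diag(cov), design.alpha)
    nuisance = {n: float(b) for n, b, d in zip(names, beta, is_delta) if not d}
    return JointEstimate(
        method=model,
        params=tuple(names[i] for i in idx),
        estimate=est,
        cov=cov,
        zstat=z,
        reject=rej,
        alpha=design.alpha,
        nuisance=nuisance,
    )
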