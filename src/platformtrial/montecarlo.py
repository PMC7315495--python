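"""Monte-Carlo engine for the operating characteristics of the design.

Replicates the whole pipeline — restricted randomization, trend, noise,
and all eight analysis methods — many thousands of times per scenario and
aggregates bias, rejection rate and root-mean-squared error per method and
per hypothesis.  The engine is vectorised across replicates: allocations
are row-wise permutations of the stage multisets, and every estimator is
reduced to cell means or small cross-product matrices solved in batch.
Per-scenario seeds derive deterministically from a master seed and the
scenario coordinates, so any subset of the grid reproduces exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .analytic import _resolve_n_new, wls_design_matrices, wls_variance
from .design import EffectSpec, TrendSpec, TrialDesign
from .simulate import trend_value

__all__ = [
    "METHODS",
    "TABLE1_METHODS",
    "ScenarioSummary",
    "run_scenario",
    "default_grid",
    "scenario_seed",
    "run_grid",
    "reproduce_table1",
    "reproduce_power_and_error_surfaces",
    "reproduce_rmse_tables",
]

METHODS = ("Z_concurrent", "Z_all", "WLS_all", "WLS_s2", "Ma1", "Ma2", "Mb1", "Mb2")
TABLE1_METHODS = ("WLS_all", "WLS_s2", "Ma1", "Ma2", "Mb1", "Mb2")

# Methods whose inference concerns only the added arm.
_ADDED_ONLY = {"Z_concurrent", "Mb1", "Mb2"}


@dataclass(frozen=True)
class ScenarioSummary:
    """Aggregated Monte-Carlo metrics for one scenario."""

    design: TrialDesign
    effects: EffectSpec
    trend: TrendSpec
    n_reps: int
    table: pd.DataFrame  # method, param, bias, bias_se, reject_rate, reject_se, rmse


def _simulate_batch(design, effects, trend, n_reps, rng):
    """Arm allocations and responses for ``n_reps`` trials at once."""
    n_ks = design.n_ks
    arms = np.arange(design.K + 2)
    t1 = np.repeat(arms, n_ks[:, 0])
    t2 = np.repeat(arms, n_ks[:, 1])
    A1 = np.tile(t1, (n_reps, 1))
    A2 = np.tile(t2, (n_reps, 1))
    rng.permuted(A1, axis=1, out=A1)
    rng.permuted(A2, axis=1, out=A2)
    arm = np.concatenate([A1, A2], axis=1)

    n_total = design.n_total
    j = np.arange(1, n_total + 1)
    stage = np.where(j <= design.n_stage1, 1, 2)
    tau = np.asarray(trend_value(trend, j, n_total, stage), dtype=float)
    mu = effects.mu(design.K)
    X = mu[arm] + tau
    if design.sigma2 > 0:
        X += rng.standard_normal((n_reps, n_total)) * np.sqrt(design.sigma2)
    return arm, X


def _estimate_batch(design, arm, X, methods=METHODS):
    """Added-arm and initial-arm effect estimates for a batch of trials.

    Returns ``{method: (params, est, var)}`` where ``est`` has one column
    per reported parameter and ``var`` is either a fixed vector (methods
    whose design matrix is allocation-free) or per-replicate (the
    enrolment-order regressions, whose cross-products depend on where
    each arm's patients landed).  Matches the single-trial estimators in
    :mod:`platformtrial.estimators` to machine precision.
    """
    K = design.K
    s2 = design.sigma2
    n_ks = design.n_ks
    N1 = design.n_stage1
    n_total = design.n_total
    R = X.shape[0]
    j = np.arange(1, n_total + 1, dtype=float)

    masks = [arm == k for k in range(K + 2)]
    # cell sums/means and per-arm enrolment-order sums
    m = np.full((K + 2, 2, R), np.nan)
    T = np.empty((K + 2, R))   # sum of responses per arm
    S = np.empty((K + 2, R))   # sum of enrolment indices per arm
    for k, Mk in enumerate(masks):
        s1 = (X[:, :N1] * Mk[:, :N1]).sum(axis=1)
        stot = (X * Mk).sum(axis=1)
        if n_ks[k, 0] > 0:
            m[k, 0] = s1 / n_ks[k, 0]
        if n_ks[k, 1] > 0:
            m[k, 1] = (stot - s1) / n_ks[k, 1]
        T[k] = stot
        S[k] = (Mk * j).sum(axis=1)

    n_arm_tot = n_ks.sum(axis=1)
    n0 = n_arm_tot[0]
    n_new = int(n_ks[K + 1, 1])
    w0 = n_ks[0] / n0
    # overall means: count-weighted stage means (the added arm has stage 2 only)
    xbar = (n_ks[:, :, None] * np.nan_to_num(m)).sum(axis=1) / n_arm_tot[:, None]
    xbar0 = w0[0] * m[0, 0] + w0[1] * m[0, 1]

    delta_params = tuple(f"delta_{k}" for k in range(1, K + 2))
    out = {}

    if "Z_concurrent" in methods:
        est = (m[K + 1, 1] - m[0, 1])[:, None]
        var = np.array([s2 / n_new + s2 / n_ks[0, 1]])
        out["Z_concurrent"] = ((delta_params[-1],), est, var)

    if "Z_all" in methods:
        est = np.stack([xbar[k] - xbar0 for k in range(1, K + 2)], axis=1)
        var = np.array([s2 / n_arm_tot[k] + s2 / n0 for k in range(1, K + 2)])
        out["Z_all"] = (delta_params, est, var)

    for variant in ("all", "s2"):
        name = f"WLS_{variant}"
        if name not in methods:
            continue
        D, Sigma, labels = wls_design_matrices(design, variant)
        y = np.empty((R, len(labels)))
        for i, (k, s) in enumerate(labels):
            if s == 0:
                y[:, i] = m[k, 1] - xbar0
            else:
                y[:, i] = m[k, s - 1] - m[0, s - 1]
        cov = wls_variance(design, variant)
        A = cov @ D.T @ np.linalg.inv(Sigma)
        out[name] = (delta_params, y @ A.T, np.diag(cov).copy())

    c = (j > N1).astype(float)
    Sj, Sj2 = j.sum(), (j * j).sum()
    n2tot = n_total - N1

    if "Ma1" in methods:
        p = K + 3
        ZtZ = np.zeros((R, p, p))
        ZtZ[:, 0, 0] = n_total
        ZtZ[:, 0, -1] = ZtZ[:, -1, 0] = Sj
        ZtZ[:, -1, -1] = Sj2
        for k in range(1, K + 2):
            ZtZ[:, 0, k] = ZtZ[:, k, 0] = n_arm_tot[k]
            ZtZ[:, k, k] = n_arm_tot[k]
            ZtZ[:, k, -1] = ZtZ[:, -1, k] = S[k]
        ZtX = np.empty((R, p))
        ZtX[:, 0] = X.sum(axis=1)
        for k in range(1, K + 2):
            ZtX[:, k] = T[k]
        ZtX[:, -1] = (X * j).sum(axis=1)
        beta = np.linalg.solve(ZtZ, ZtX[:, :, None])[:, :, 0]
        covd = s2 * np.diagonal(np.linalg.inv(ZtZ), axis1=1, axis2=2)
        out["Ma1"] = (delta_params, beta[:, 1 : K + 2], covd[:, 1 : K + 2])

    if "Ma2" in methods:
        p = K + 3
        ZtZ = np.zeros((p, p))
        ZtZ[0, 0] = n_total
        ZtZ[0, -1] = ZtZ[-1, 0] = n2tot
        ZtZ[-1, -1] = n2tot
        for k in range(1, K + 2):
            ZtZ[0, k] = ZtZ[k, 0] = n_arm_tot[k]
            ZtZ[k, k] = n_arm_tot[k]
            ZtZ[k, -1] = ZtZ[-1, k] = n_ks[k, 1]
        Zinv = np.linalg.inv(ZtZ)
        ZtX = np.empty((R, p))
        ZtX[:, 0] = X.sum(axis=1)
        for k in range(1, K + 2):
            ZtX[:, k] = T[k]
        ZtX[:, -1] = X[:, N1:].sum(axis=1)
        beta = ZtX @ Zinv.T
        var = s2 * np.diag(Zinv)[1 : K + 2]
        out["Ma2"] = (delta_params, beta[:, 1 : K + 2], var.copy())

    if "Mb1" in methods:
        Msub = masks[0] | masks[K + 1]
        n_sub = n0 + n_new
        S_sub = S[0] + S[K + 1]
        Sj2_sub = (Msub * (j * j)).sum(axis=1)
        ZtZ = np.zeros((R, 3, 3))
        ZtZ[:, 0, 0] = n_sub
        ZtZ[:, 0, 1] = ZtZ[:, 1, 0] = n_new
        ZtZ[:, 1, 1] = n_new
        ZtZ[:, 0, 2] = ZtZ[:, 2, 0] = S_sub
        ZtZ[:, 1, 2] = ZtZ[:, 2, 1] = S[K + 1]
        ZtZ[:, 2, 2] = Sj2_sub
        ZtX = np.stack(
            [T[0] + T[K + 1], T[K + 1], (Msub * X * j).sum(axis=1)], axis=1
        )
        beta = np.linalg.solve(ZtZ, ZtX[:, :, None])[:, :, 0]
        covd = s2 * np.diagonal(np.linalg.inv(ZtZ), axis1=1, axis2=2)
        out["Mb1"] = ((delta_params[-1],), beta[:, 1:2], covd[:, 1:2])

    if "Mb2" in methods:
        # saturated three-cell model: coefficient is the concurrent contrast
        est = (m[K + 1, 1] - m[0, 1])[:, None]
        var = np.array([s2 / n_new + s2 / n_ks[0, 1]])
        out["Mb2"] = ((delta_params[-1],), est, var)

    return out


def run_scenario(
    design: TrialDesign,
    effects: EffectSpec,
    trend: TrendSpec,
    n_reps: int,
    seed,
    methods: Sequence[str] = METHODS,
    chunk_size: int = 2000,
) -> ScenarioSummary:
    """Simulate ``n_reps`` independent trials and aggregate every method.

    For each method and each hypothesis it reports the bias of the
    contrast estimate, the empirical one-sided rejection rate at the
    design's alpha, the root-mean-squared error and Monte-Carlo standard
    errors.  Deterministic given ``seed`` (an int, ``SeedSequence`` or
    ``Generator``); replicates are independent.  Work proceeds in chunks
    to bound memory.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zcrit = norm.ppf(1.0 - design.alpha)
    true = dict(
        zip([f"delta_{k}" for k in range(1, design.K + 2)], effects.mu(design.K)[1:] - effects.mu0)
    )

    acc: dict[tuple[str, str], dict[str, float]] = {}
    done = 0
    while done < n_reps:
        r = min(chunk_size, n_reps - done)
        arm, X = _simulate_batch(design, effects, trend, r, rng)
        try:
            results = _estimate_batch(design, arm, X, methods)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(
                f"estimator failure in replicates {done + 1}..{done + r}: {exc}"
            ) from exc
        for method, (params, est, var) in results.items():
            z = est / np.sqrt(np.broadcast_to(var, est.shape))
            rej = z > zcrit
            for i, param in enumerate(params):
                a = acc.setdefault(
                    (method, param), {"s": 0.0, "s2": 0.0, "rej": 0.0}
                )
                a["s"] += est[:, i].sum()
                a["s2"] += (est[:, i] ** 2).sum()
                a["rej"] += rej[:, i].sum()
        done += r

    rows = []
    for (method, param), a in acc.items():
        mean = a["s"] / n_reps
        var_mc = max(a["s2"] / n_reps - mean**2, 0.0)
        bias = mean - true[param]
        rate = a["rej"] / n_reps
        rows.append(
            {
                "method": method,
                "param": param,
                "bias": bias,
                "bias_se": np.sqrt(var_mc / n_reps),
                "reject_rate": rate,
                "reject_se": np.sqrt(rate * (1.0 - rate) / n_reps),
                "rmse": np.sqrt(bias**2 + var_mc),
                "n_reps": n_reps,
            }
        )
    table = pd.DataFrame(rows)
    return ScenarioSummary(design, effects, trend, n_reps, table)


# ---------------------------------------------------------------------------
# scenario grid of the simulation study
# ---------------------------------------------------------------------------

def default_grid(
    n0: int = 550,
    K: int = 1,
    timings: Sequence[float] = (0.25, 0.5, 0.75),
    n_new_options: Sequence = ("n02", "n0", "2n0"),
    sigma2: float = 1.0,
    alpha: float = 0.05,
) -> list[dict]:
    """The nine (timing x new-arm size) designs of the simulation study.

    Symbolic sizes resolve per timing: ``'n02'`` matches the concurrent
    control count, ``'n0'`` the full control arm, ``'2n0'`` twice it.
    """
    grid = []
    n_arm = (n0,) * (K + 1)
    for ti, timing in enumerate(timings):
        probe = TrialDesign(K, n_arm, timing, 1, sigma2, alpha)
        for oi, option in enumerate(n_new_options):
            n_new = _resolve_n_new(option, probe)
            grid.append(
                {
                    "timing": timing,
                    "n_new_option": str(option),
                    "design": TrialDesign(K, n_arm, timing, n_new, sigma2, alpha),
                    "coords": (ti, oi),
                }
            )
    return grid


def scenario_seed(master_seed: int, *coords) -> np.random.SeedSequence:
    """Deterministic per-scenario seed from a master seed and coordinates.

    Strings are hashed with CRC-32 and floats keyed at 1e-4 resolution,
    so scenarios can run in any order or in parallel and still reproduce.
    """
    key = []
    for cv in coords:
        if isinstance(cv, str):
            key.append(zlib.crc32(cv.encode()))
        elif isinstance(cv, float):
            key.append(int(round(cv * 10_000)) % (2**31))
        else:
            key.append(int(cv) % (2**31))
    return np.random.SeedSequence(int(master_seed), spawn_key=tuple(key))


def run_grid(
    n_reps: int,
    seed: int,
    trends: Iterable[TrendSpec],
    regimes: Sequence[str] = ("null", "alternative"),
    delta: float = 0.15,
    methods: Sequence[str] = METHODS,
    grid: list[dict] | None = None,
    chunk_size: int = 2000,
) -> pd.DataFrame:
    """Run every (scenario, trend, regime) combination and stack the metrics.

    ``regimes`` selects the global null (all effects zero) and/or the
    alternative where every experimental arm has effect ``delta``.
    Returns one long table with scenario coordinates attached, the raw
    material for the bias table and the power/type-I-error and rMSE
    surfaces.
    """
    grid = default_grid() if grid is None else grid
    frames = []
    for sc in grid:
        design = sc["design"]
        for trend in trends:
            for regime in regimes:
                effects = (
                    EffectSpec.null(design.K)
                    if regime == "null"
                    else EffectSpec.uniform(design.K, delta)
                )
                ss = scenario_seed(
                    seed, sc["timing"], sc["n_new_option"], trend.family,
                    float(trend.lam), regime,
                )
                summary = run_scenario(
                    design, effects, trend, n_reps, ss, methods, chunk_size
                )
                tab = summary.table.copy()
                tab.insert(0, "timing", sc["timing"])
                tab.insert(1, "n_new_option", sc["n_new_option"])
                tab.insert(2, "n_new", design.n_new)
                tab.insert(3, "family", trend.family)
                tab.insert(4, "lam", trend.lam)
                tab.insert(5, "regime", regime)
                frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def reproduce_table1(
    n_reps: int,
    seed: int,
    families: Sequence[str] = ("linear", "step"),
    lambdas: Sequence[float] = (0.02, 0.04, 0.06, 0.08),
    methods: Sequence[str] = TABLE1_METHODS,
    zero_threshold: float = 1e-3,
    grid: list[dict] | None = None,
) -> pd.DataFrame:
    """Maximum and median absolute bias of the added-arm estimate per method.

    Aggregates over the nine-scenario grid for each (trend family, lambda)
    under the alternative.  Values below ``zero_threshold`` are reported
    as 0: at that level the residual is Monte-Carlo error, as the same
    magnitude appears for unbiased estimators without any trend.
    """
    trends = [TrendSpec(f, lam) for f in families for lam in lambdas]
    raw = run_grid(
        n_reps, seed, trends, regimes=("alternative",), methods=methods, grid=grid
    )
    K1_param = f"delta_{(grid or default_grid())[0]['design'].K + 1}"
    added = raw[raw["param"] == K1_param]
    rows = []
    for (family, lam, method), g in added.groupby(["family", "lam", "method"], sort=False):
        ab = g["bias"].abs()
        mx, med = ab.max(), ab.median()
        rows.append(
            {
                "family": family,
                "lam": lam,
                "method": method,
                "max_abs_bias": 0.0 if mx < zero_threshold else mx,
                "median_abs_bias": 0.0 if med < zero_threshold else med,
            }
        )
    return pd.DataFrame(rows)


def reproduce_power_and_error_surfaces(
    n_reps: int,
    seed: int,
    families: Sequence[str] = ("none", "linear", "step"),
    lambdas: Sequence[float] = (0.02, 0.04, 0.06, 0.08),
    methods: Sequence[str] = METHODS,
    grid: list[dict] | None = None,
) -> pd.DataFrame:
    """Empirical marginal power and type-I error over the scenario grid.

    The alternative-regime rejection rate of a true effect is the
    marginal power; the null-regime rate is the type-I error.  Covers
    every method, scenario and trend magnitude — the numeric content of
    the power/error figures.
    """
    trends = [TrendSpec("none", 0.0)] if "none" in families else []
    trends += [TrendSpec(f, lam) for f in families if f != "none" for lam in lambdas]
    raw = run_grid(n_reps, seed, trends, regimes=("null", "alternative"),
                   methods=methods, grid=grid)
    out = raw[
        ["timing", "n_new_option", "n_new", "family", "lam", "regime",
         "method", "param", "reject_rate", "reject_se", "n_reps"]
    ].copy()
    out["metric"] = np.where(out["regime"] == "null", "type_I_error", "power")
    return out


def reproduce_rmse_tables(
    n_reps: int,
    seed: int,
    families: Sequence[str] = ("none", "linear", "step"),
    lambdas: Sequence[float] = (0.02, 0.04, 0.06, 0.08),
    methods: Sequence[str] = METHODS,
    grid: list[dict] | None = None,
) -> pd.DataFrame:
    """Root-mean-squared error of the added-arm estimate per scenario/method."""
    trends = [TrendSpec("none", 0.0)] if "none" in families else []
    trends += [TrendSpec(f, lam) for f in families if f != "none" for lam in lambdas]
    raw = run_grid(n_reps, seed, trends, regimes=("alternative",),
                   methods=methods, grid=grid)
    K1_param = f"delta_{(grid or default_grid())[0]['design'].K + 1}"
    out = raw[raw["param"] == K1_param][
        ["timing", "n_new_option", "n_new", "family", "lam",
         "method", "bias", "rmse", "n_reps"]
    ].reset_index(drop=True)
    return out
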