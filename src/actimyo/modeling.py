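"""Penalized linear mixed modelling of muscle atrophy.

The core estimator is a Gaussian linear mixed model with patient random
intercepts whose fixed effects are L1-penalized (LASSO), fitted by
alternating

* coordinate descent with soft-thresholding on the GLS-whitened problem
  (exact zeros; the intercept is unpenalized), and
* maximum-likelihood variance-component updates via the profiled likelihood
  of the residuals (one-dimensional search over the variance ratio
  rho = sigma_b^2 / sigma_e^2).

Around it: iterative VIF pruning, z-score standardization fitted on
training data only, a patient-grouped stratified 80/20 split, 4-outer /
2-inner nested cross-validation of the penalty weight (final lambda = mean
of the outer optima), test-set metrics, and a BCa cluster bootstrap that
resamples patients.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

# ---------------------------------------------------------------------------
# grouped data layout
# ---------------------------------------------------------------------------


class _Grouped:
    """Rows sorted by cluster with reduceat boundaries for fast group sums."""

    def __init__(self, groups):
        groups = np.asarray(groups)
        self.labels, inv = np.unique(groups, return_inverse=True)
        self.order = np.argsort(inv, kind="stable")
        sorted_inv = inv[self.order]
        self.starts = np.concatenate(([0], np.flatnonzero(np.diff(sorted_inv)) + 1))
        self.sizes = np.diff(np.concatenate((self.starts, [len(sorted_inv)])))
        self.n = len(sorted_inv)
        self.n_groups = len(self.starts)

    def sort(self, v: np.ndarray) -> np.ndarray:
        return v[self.order]

    def group_sums(self, v: np.ndarray) -> np.ndarray:
        return np.add.reduceat(v, self.starts)


def _whiten(vs: np.ndarray, grp: _Grouped, c: np.ndarray) -> np.ndarray:
    """Apply V^{-1/2} (up to the 1/sigma_e factor) to group-sorted columns.

    For a cluster of size m with variance ratio rho, V^{-1/2} acts as
    v -> v - (1 - 1/sqrt(1 + m*rho)) * mean(v), columnwise.
    """
    if vs.ndim == 1:
        means = grp.group_sums(vs) / grp.sizes
        return vs - np.repeat(c * means, grp.sizes)
    means = np.add.reduceat(vs, grp.starts, axis=0) / grp.sizes[:, None]
    return vs - np.repeat(c[:, None] * means, grp.sizes, axis=0)


def _profile_variances(e_sorted: np.ndarray, grp: _Grouped) -> tuple[float, float, float]:
    """ML variance components for fixed residuals, via the profiled likelihood.

    The profiled negative log-likelihood over the variance ratio
    rho = sigma_b^2/sigma_e^2 is minimised by root-finding on its
    derivative (monotone pieces, bracketed by doubling), with the rho = 0
    boundary handled explicitly.  Returns ``(rho, sigma_e2, nll)`` where
    nll omits the constant n/2*(log(2*pi)+1).
    """
    ss = grp.group_sums(e_sorted**2)
    s1sq = grp.group_sums(e_sorted) ** 2
    n, sizes = grp.n, grp.sizes

    def q_of(rho: float) -> float:
        return float(np.sum(ss - rho * s1sq / (1.0 + sizes * rho)))

    def nll(rho: float) -> float:
        return 0.5 * (
            n * math.log(max(q_of(rho), 1e-300) / n)
            + float(np.log1p(sizes * rho).sum())
        )

    def dnll(rho: float) -> float:
        denom = 1.0 + sizes * rho
        q = float(np.sum(ss - rho * s1sq / denom))
        dq = -float(np.sum(s1sq / denom**2))
        return 0.5 * (n * dq / max(q, 1e-300) + float(np.sum(sizes / denom)))

    rho = 0.0
    if dnll(0.0) < 0.0:
        hi = 1.0
        while dnll(hi) < 0.0 and hi < 1e8:
            hi *= 8.0
        if dnll(hi) >= 0.0:
            rho = float(optimize.brentq(dnll, hi / 8.0 if hi > 1.0 else 0.0, hi,
                                        xtol=1e-12, rtol=1e-12))
        else:
            rho = hi
    sigma_e2 = q_of(rho) / n
    return rho, sigma_e2, nll(rho)


def _variances_at_rho(e_sorted: np.ndarray, grp: _Grouped, rho: float) -> tuple[float, float, float]:
    """Residual variance and profiled NLL at a fixed variance ratio."""
    ss = grp.group_sums(e_sorted**2)
    s1sq = grp.group_sums(e_sorted) ** 2
    denom = 1.0 + grp.sizes * rho
    q = float(np.sum(ss - rho * s1sq / denom))
    nll = 0.5 * (grp.n * math.log(max(q, 1e-300) / grp.n) + float(np.log(denom).sum()))
    return rho, q / grp.n, nll


def _soft(x: float, thr: float) -> float:
    if x > thr:
        return x - thr
    if x < -thr:
        return x + thr
    return 0.0


def _coordinate_descent(
    AX: np.ndarray,
    Ay: np.ndarray,
    beta: np.ndarray,
    lam_eff: float,
    max_sweeps: int = 150,
    tol: float = 1e-11,
) -> np.ndarray:
    """LASSO coordinate descent on the Gram (covariance-update) form.

    Minimises 1/2 beta' G beta - c' beta + lam_eff * sum(|beta_j|, j >= 1);
    column 0 (intercept) is unpenalized.  Each coordinate update costs
    O(p), independent of the number of rows.
    """
    G = AX.T @ AX
    c = AX.T @ Ay
    diag = np.diag(G).copy()
    Gb = G @ beta
    p1 = beta.shape[0]

    def sweep(indices) -> float:
        nonlocal Gb
        max_delta = 0.0
        for j in indices:
            dj = diag[j]
            if dj <= 1e-300:
                continue
            g = c[j] - Gb[j] + dj * beta[j]
            bnew = g / dj if j == 0 else _soft(g, lam_eff) / dj
            d = bnew - beta[j]
            if d != 0.0:
                Gb += G[:, j] * d
                beta[j] = bnew
                ad = abs(d)
                if ad > max_delta:
                    max_delta = ad
        return max_delta

    all_idx = range(p1)
    budget = max_sweeps
    while budget > 0:
        budget -= 1
        if sweep(all_idx) < tol * (1.0 + float(np.abs(beta).max())):
            break
        # iterate the active set until stable, then re-verify on all
        active = [j for j in all_idx if j == 0 or beta[j] != 0.0]
        while budget > 0:
            budget -= 1
            if sweep(active) < tol * (1.0 + float(np.abs(beta).max())):
                break
    return beta


@dataclass
class LassoLMMFit:
    """Fitted L1-penalized linear mixed model (patient random intercepts)."""

    beta0: float
    beta: np.ndarray
    columns: list[str]
    sigma_b: float
    sigma_e: float
    lam: float
    n_iter: int
    converged: bool
    objective: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Population-level predictions (random effect set to 0)."""
        return self.beta0 + np.asarray(X, dtype=float) @ self.beta

    @property
    def coef_vector(self) -> np.ndarray:
        return np.concatenate(([self.beta0], self.beta))

    def selected(self) -> list[str]:
        return [c for c, b in zip(self.columns, self.beta) if b != 0.0]


def fit_lmm_lasso(
    X: np.ndarray,
    y: np.ndarray,
    groups,
    lam: float,
    *,
    columns: list[str] | None = None,
    beta_init: np.ndarray | None = None,
    rho_init: float | None = None,
    fix_rho: float | None = None,
    max_outer: int = 200,
    tol: float = 1e-8,
) -> LassoLMMFit:
    """Fit the L1-penalized linear mixed model at penalty weight ``lam``.

    Minimises the penalized negative Gaussian log-likelihood of
    ``y = beta0 + X beta + Z b + eps`` (cluster random intercepts b,
    variance sigma_b^2; residual variance sigma_e^2) plus
    ``lam * sum(|beta_j|)`` over the penalized coefficients.  Convergence:
    change of the penalized objective below ``tol``.  Non-convergence is
    flagged on the returned fit, not raised.

    ``fix_rho`` pins the variance ratio sigma_b^2/sigma_e^2 instead of
    profiling it (``fix_rho=0`` reduces the model to an ordinary LASSO).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    n, p = X.shape
    grp = _Grouped(groups)
    if grp.n_groups < 2:
        raise ValueError("at least two clusters are required")
    Xs = grp.sort(X)
    ys = grp.sort(y)
    X1 = np.column_stack((np.ones(n), Xs))

    beta = np.zeros(p + 1)
    if beta_init is not None:
        beta[:] = beta_init
    else:
        beta[0] = float(y.mean())
    e = ys - X1 @ beta
    if fix_rho is not None:
        rho, sigma_e2, _ = _variances_at_rho(e, grp, fix_rho)
    elif rho_init is not None:
        rho, sigma_e2, _ = _variances_at_rho(e, grp, float(rho_init))
    else:
        rho, sigma_e2, _ = _profile_variances(e, grp)

    const = 0.5 * n * (math.log(2 * math.pi) + 1.0)
    obj = math.inf
    converged = False
    it = 0
    for it in range(1, max_outer + 1):
        c = 1.0 - 1.0 / np.sqrt(1.0 + grp.sizes * rho)
        AX = _whiten(X1, grp, c)
        Ay = _whiten(ys, grp, c)
        beta = _coordinate_descent(AX, Ay, beta, lam * sigma_e2)
        e = ys - X1 @ beta
        if fix_rho is not None:
            rho, sigma_e2, nll_prof = _variances_at_rho(e, grp, fix_rho)
        else:
            rho, sigma_e2, nll_prof = _profile_variances(e, grp)
        new_obj = nll_prof + const + lam * float(np.abs(beta[1:]).sum())
        if abs(obj - new_obj) < tol:
            obj = new_obj
            converged = True
            break
        obj = new_obj
    return LassoLMMFit(
        beta0=float(beta[0]),
        beta=beta[1:].copy(),
        columns=list(columns) if columns is not None else [f"x{j}" for j in range(p)],
        sigma_b=math.sqrt(rho * sigma_e2),
        sigma_e=math.sqrt(sigma_e2),
        lam=lam,
        n_iter=it,
        converged=converged,
        objective=obj,
    )


def lambda_max(X: np.ndarray, y: np.ndarray, groups) -> float:
    """Smallest penalty that shrinks every penalized coefficient to zero."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    null = fit_lmm_lasso(np.empty((len(y), 0)), y, groups, 0.0)
    grp = _Grouped(groups)
    rho = (null.sigma_b / null.sigma_e) ** 2 if null.sigma_e > 0 else 0.0
    c = 1.0 - 1.0 / np.sqrt(1.0 + grp.sizes * rho)
    AX = _whiten(grp.sort(X), grp, c)
    Ar = _whiten(grp.sort(y) - null.beta0, grp, c)
    score = np.abs(AX.T @ Ar) / null.sigma_e**2
    return float(score.max()) if score.size else 0.0


def lambda_grid(
    X: np.ndarray, y: np.ndarray, groups, n_lambdas: int = 50, min_ratio: float = 1e-3
) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to lambda_max*min_ratio,
    returned in ascending order."""
    lmax = lambda_max(X, y, groups)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax * min_ratio, lmax, n_lambdas)


def fit_lambda_path(X, y, groups, lambdas_desc, columns=None) -> list[LassoLMMFit]:
    """Fit a descending lambda path with warm starts.

    Path fits feed cross-validation MSE curves, so they run at
    prediction-grade tolerance; the final model is refit at full precision.
    """
    fits = []
    beta_init = None
    rho_init = None
    for lam in lambdas_desc:
        fit = fit_lmm_lasso(
            X, y, groups, float(lam), columns=columns,
            beta_init=beta_init, rho_init=rho_init, max_outer=40, tol=1e-6,
        )
        beta_init = fit.coef_vector
        rho_init = (fit.sigma_b / fit.sigma_e) ** 2 if fit.sigma_e > 0 else 0.0
        fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# VIF pruning
# ---------------------------------------------------------------------------


def _vif_values(X: np.ndarray) -> np.ndarray:
    n, p = X.shape
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack((np.ones(n), np.delete(X, j, axis=1)))
        xj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        sst = float(((xj - xj.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sst
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def vif_filter(predictors: pd.DataFrame, threshold: float = 5.0):
    """Iteratively drop the predictor with the largest VIF while any exceeds
    the threshold.

    VIF_j = 1 / (1 - R^2_j) from regressing column j on the remaining
    predictors (with intercept).  Returns ``(reduced frame, removal log)``
    where the log lists ``(column, vif_at_removal)`` in removal order.
    """
    df = predictors.copy()
    if df.shape[1] < 2:
        raise ValueError("VIF filtering needs at least two predictors")
    stds = df.std(ddof=0)
    constant = list(stds.index[stds < 1e-12])
    if constant:
        raise ValueError(f"constant predictor column(s): {constant}")
    removal_log: list[tuple[str, float]] = []
    while df.shape[1] >= 2:
        vifs = _vif_values(df.to_numpy(float))
        worst = int(np.argmax(vifs))
        if vifs[worst] <= threshold:
            break
        removal_log.append((df.columns[worst], float(vifs[worst])))
        df = df.drop(columns=df.columns[worst])
    return df, removal_log


# ---------------------------------------------------------------------------
# standardization and split
# ---------------------------------------------------------------------------


@dataclass
class Standardizer:
    """Column z-scoring with constants fitted on training data only."""

    means: np.ndarray
    sds: np.ndarray
    columns: list[str]

    @classmethod
    def fit(cls, df: pd.DataFrame) -> "Standardizer":
        X = df.to_numpy(float)
        sds = X.std(axis=0, ddof=0)
        if np.any(sds < 1e-12):
            bad = [c for c, s in zip(df.columns, sds) if s < 1e-12]
            raise ValueError(f"cannot standardize constant column(s): {bad}")
        return cls(means=X.mean(axis=0), sds=sds, columns=list(df.columns))

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        return (df[self.columns].to_numpy(float) - self.means) / self.sds


@dataclass
class ModelMatrix:
    """Outcome, z-scored predictors and patient grouping for one data side."""

    y: np.ndarray
    X: np.ndarray
    groups: np.ndarray
    columns: list[str]
    standardizer: Standardizer


def build_model_matrices(
    train: pd.DataFrame,
    test: pd.DataFrame | None,
    predictor_columns: list[str],
    outcome_column: str = "outcome_pct_change",
    group_column: str = "patient_id",
) -> tuple[ModelMatrix, ModelMatrix | None]:
    """Standardize on the training rows only and apply to both sides."""
    scaler = Standardizer.fit(train[predictor_columns])
    mm_train = ModelMatrix(
        y=train[outcome_column].to_numpy(float),
        X=scaler.transform(train),
        groups=train[group_column].to_numpy(),
        columns=list(predictor_columns),
        standardizer=scaler,
    )
    mm_test = None
    if test is not None:
        mm_test = ModelMatrix(
            y=test[outcome_column].to_numpy(float),
            X=scaler.transform(test),
            groups=test[group_column].to_numpy(),
            columns=list(predictor_columns),
            standardizer=scaler,
        )
    return mm_train, mm_test


def grouped_stratified_split(
    table: pd.DataFrame,
    test_frac: float = 0.2,
    seed: int = 0,
    *,
    group_column: str = "patient_id",
    outcome_column: str = "outcome_pct_change",
    n_strata: int = 4,
):
    """Patient-grouped stratified train/test split.

    All rows of a patient land on the same side (no leakage across legs or
    days).  Patients are stratified by quartile of their mean outcome; the
    number of test patients is the rounded target within each stratum
    (largest-remainder allocation), hence within +/-1 of the overall
    target.  With too few patients to stratify, falls back to an
    unstratified grouped split with a warning.
    """
    means = table.groupby(group_column)[outcome_column].mean().sort_index()
    patients = means.index.to_numpy()
    n_pat = len(patients)
    if n_pat < 5:
        raise ValueError("grouped split requires at least 5 patients")
    if n_pat < 2 * n_strata:
        warnings.warn(
            "too few patients per stratum; falling back to unstratified grouped split",
            stacklevel=2,
        )
        strata = np.zeros(n_pat, dtype=int)
    else:
        order = np.argsort(means.to_numpy(), kind="stable")
        strata = np.empty(n_pat, dtype=int)
        strata[order] = (np.arange(n_pat) * n_strata) // n_pat
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B117]))
    target_total = int(round(test_frac * n_pat))
    quotas = np.array([(strata == s).sum() * test_frac for s in range(strata.max() + 1)])
    counts = np.floor(quotas).astype(int)
    rem = quotas - counts
    short = target_total - counts.sum()
    # largest-remainder allocation; remainder ties broken symmetrically from
    # the extremes of the outcome ordering (0, K-1, 1, K-2, ...) so neither
    # tail of the outcome distribution is systematically favoured
    k_str = len(quotas)
    sym = [s for pair in zip(range(k_str), range(k_str - 1, -1, -1)) for s in pair][:k_str]
    sym = list(dict.fromkeys(sym))
    pref = sorted(range(k_str), key=lambda s: (-rem[s], sym.index(s)))
    for s in pref[: max(short, 0)]:
        counts[s] += 1
    test_patients: list = []
    for s in range(strata.max() + 1):
        members = patients[strata == s]
        take = min(counts[s], len(members))
        if take > 0:
            test_patients.extend(rng.choice(members, size=take, replace=False))
    test_set = set(test_patients)
    is_test = table[group_column].isin(test_set)
    return table[~is_test].copy(), table[is_test].copy()


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class NestedCVResult:
    lambda_grid: np.ndarray
    outer_lambdas: list[float]
    inner_mse_curves: list[np.ndarray]  # one curve (over the grid) per outer fold
    outer_val_mse: list[float]
    final_lambda: float
    final_fit: LassoLMMFit


def _patient_folds(patients: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(np.sort(patients))
    return [fold for fold in np.array_split(perm, k) if len(fold)]


def _argmin_prefer_larger(values: np.ndarray) -> int:
    """Index of the minimum; ties broken toward the larger lambda (ascending grid)."""
    m = values.min()
    return int(np.flatnonzero(values <= m + 1e-12)[-1])


def nested_cv(
    mm: ModelMatrix,
    lambdas: np.ndarray,
    outer_k: int = 4,
    inner_k: int = 2,
    seed: int = 0,
) -> NestedCVResult:
    """Nested cross-validation of the penalty weight over patients.

    Outer folds partition patients; within each outer-training set an
    inner ``inner_k``-fold CV computes the mean validation MSE per lambda
    (predictions for unseen patients use random effect 0).  The per-outer
    optimum is the argmin (ties toward larger lambda); the final lambda is
    the arithmetic mean of the outer optima, and the final model is refit
    on the full training set at that value.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(lambdas <= 0) or np.any(np.diff(lambdas) < 0):
        raise ValueError("lambda grid must be strictly positive and ascending")
    patients = np.unique(mm.groups)
    if len(patients) < outer_k:
        raise ValueError("need at least outer_k patients")
    ss = np.random.SeedSequence([seed, 0xCF01D])
    rng_outer, rng_inner = [np.random.default_rng(s) for s in ss.spawn(2)]
    outer_folds = _patient_folds(patients, outer_k, rng_outer)
    desc = lambdas[::-1]

    outer_lambdas: list[float] = []
    curves: list[np.ndarray] = []
    outer_val_mse: list[float] = []
    for fold in outer_folds:
        val_mask = np.isin(mm.groups, fold)
        tr_groups = mm.groups[~val_mask]
        tr_X, tr_y = mm.X[~val_mask], mm.y[~val_mask]
        inner_patients = np.unique(tr_groups)
        inner_folds = _patient_folds(inner_patients, inner_k, rng_inner)
        mse = np.zeros((len(inner_folds), len(lambdas)))
        for fi, ifold in enumerate(inner_folds):
            imask = np.isin(tr_groups, ifold)
            fits = fit_lambda_path(tr_X[~imask], tr_y[~imask], tr_groups[~imask], desc)
            for li, fit in enumerate(fits):
                pred = fit.predict(tr_X[imask])
                mse[fi, len(lambdas) - 1 - li] = float(np.mean((pred - tr_y[imask]) ** 2))
        curve = mse.mean(axis=0)
        best = _argmin_prefer_larger(curve)
        lam_star = float(lambdas[best])
        outer_lambdas.append(lam_star)
        curves.append(curve)
        fit_star = fit_lmm_lasso(tr_X, tr_y, tr_groups, lam_star, columns=mm.columns)
        pred = fit_star.predict(mm.X[val_mask])
        outer_val_mse.append(float(np.mean((pred - mm.y[val_mask]) ** 2)))

    final_lambda = float(np.mean(outer_lambdas))
    final_fit = fit_lmm_lasso(mm.X, mm.y, mm.groups, final_lambda, columns=mm.columns)
    return NestedCVResult(
        lambda_grid=lambdas,
        outer_lambdas=outer_lambdas,
        inner_mse_curves=curves,
        outer_val_mse=outer_val_mse,
        final_lambda=final_lambda,
        final_fit=final_fit,
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricReport:
    mse: float
    rmse: float
    mae: float
    r2: float
    r2_defined: bool

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "r2": self.r2,
            "r2_defined": self.r2_defined,
        }


def evaluate(fit: LassoLMMFit, mm: ModelMatrix) -> MetricReport:
    """Test-set metrics with predictions at random effect 0.

    R^2 is the squared Pearson correlation of predicted and actual values;
    it is flagged undefined for constant predictions.
    """
    pred = fit.predict(mm.X)
    resid = pred - mm.y
    mse = float(np.mean(resid**2))
    sd_pred = pred.std()
    sd_y = mm.y.std()
    if sd_pred < 1e-12 or sd_y < 1e-12:
        r2, defined = math.nan, False
    else:
        r = float(np.corrcoef(pred, mm.y)[0, 1])
        r2, defined = r * r, True
    return MetricReport(
        mse=mse,
        rmse=math.sqrt(mse),
        mae=float(np.mean(np.abs(resid))),
        r2=r2,
        r2_defined=defined,
    )


def relative_effect_pct(beta_pp: float, reference_mm: float) -> float:
    """A standardized effect (percentage points of atrophy per SD) expressed
    relative to the cohort's mean baseline thickness, in percent."""
    if reference_mm <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * abs(beta_pp) / reference_mm


# ---------------------------------------------------------------------------
# BCa cluster bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapCI:
    columns: list[str]  # "intercept" + predictor names
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    z0: np.ndarray
    accel: np.ndarray
    n_resamples: int
    degenerate: np.ndarray  # flag: coefficient constant across resamples

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.columns,
                "point": self.point,
                "lower": self.lower,
                "upper": self.upper,
                "z0": self.z0,
                "accel": self.accel,
                "degenerate": self.degenerate,
            }
        )


def _refit_on_patients(
    mm: ModelMatrix, idx_by_patient: dict, chosen: np.ndarray, lam: float, beta_init, rho_init
) -> np.ndarray:
    rows = []
    labels = []
    for k, pat in enumerate(chosen):
        idx = idx_by_patient[pat]
        rows.append(idx)
        labels.append(np.full(len(idx), k))
    rows = np.concatenate(rows)
    labels = np.concatenate(labels)
    fit = fit_lmm_lasso(
        mm.X[rows], mm.y[rows], labels, lam,
        beta_init=beta_init, rho_init=rho_init, max_outer=25, tol=1e-6,
    )
    return fit.coef_vector


def bootstrap_bca(
    mm: ModelMatrix,
    lam: float,
    n_resamples: int = 10_000,
    seed: int = 0,
    conf_level: float = 0.95,
) -> BootstrapCI:
    """Bias-corrected and accelerated CIs for the penalized coefficients.

    Patients (clusters) are resampled with replacement and the model refit
    at the fixed penalty; a patient drawn twice enters as two distinct
    clusters.  The bias correction z0 comes from the fraction of bootstrap
    coefficients below the point estimate, the acceleration from the
    jackknife-over-patients skewness formula.  A coefficient constant
    across all resamples yields a degenerate flagged interval.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be at least 100")
    patients = np.unique(mm.groups)
    n_pat = len(patients)
    idx_by_patient = {pat: np.flatnonzero(mm.groups == pat) for pat in patients}
    point_fit = fit_lmm_lasso(mm.X, mm.y, mm.groups, lam, columns=mm.columns)
    point = point_fit.coef_vector
    rho0 = (point_fit.sigma_b / point_fit.sigma_e) ** 2 if point_fit.sigma_e > 0 else 0.0

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB007]))
    boot = np.empty((n_resamples, len(point)))
    for b in range(n_resamples):
        chosen = rng.choice(patients, size=n_pat, replace=True)
        boot[b] = _refit_on_patients(mm, idx_by_patient, chosen, lam, point.copy(), rho0)

    jack = np.empty((n_pat, len(point)))
    for i, pat in enumerate(patients):
        keep = patients[patients != pat]
        jack[i] = _refit_on_patients(mm, idx_by_patient, keep, lam, point.copy(), rho0)
    jack_mean = jack.mean(axis=0)
    d = jack_mean - jack
    denom = np.power((d**2).sum(axis=0), 1.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        accel = np.where(denom > 0, (d**3).sum(axis=0) / (6.0 * denom), 0.0)

    alpha = 1.0 - conf_level
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    lower = np.empty(len(point))
    upper = np.empty(len(point))
    z0 = np.zeros(len(point))
    degenerate = np.zeros(len(point), dtype=bool)
    for j in range(len(point)):
        bj = boot[:, j]
        if np.all(bj == bj[0]):
            degenerate[j] = True
            lower[j] = upper[j] = bj[0]
            continue
        frac = float(np.mean(bj < point[j]))
        frac = min(max(frac, 1.0 / (n_resamples + 1)), n_resamples / (n_resamples + 1.0))
        z0[j] = norm.ppf(frac)
        a = accel[j]
        a1 = norm.cdf(z0[j] + (z0[j] + z_lo) / (1.0 - a * (z0[j] + z_lo)))
        a2 = norm.cdf(z0[j] + (z0[j] + z_hi) / (1.0 - a * (z0[j] + z_hi)))
        lower[j] = float(np.quantile(bj, a1))
        upper[j] = float(np.quantile(bj, a2))
    return BootstrapCI(
        columns=["intercept"] + list(mm.columns),
        point=point,
        lower=lower,
        upper=upper,
        z0=z0,
        accel=accel,
        n_resamples=n_resamples,
        degenerate=degenerate,
    )
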