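"""Secondary analyses: limb-group GEE, temporalis OLS, Welch t-test.

These complement the main penalized mixed model: a Gaussian GEE with
exchangeable working correlation compares atrophy across limb groups
(active movement vs immobile with/without an upper-motor-neuron lesion)
with Bonferroni-adjusted pairwise contrasts; an ordinary least-squares
model checks whether thigh %active contributes to temporalis (TM) atrophy,
a muscle unaffected by leg movement; and a Welch two-sample t-test
contrasts %active between healthy controls and patients.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

LIMB_GROUPS = ("active", "immobile_umnl", "immobile_no_umnl")


def bonferroni(p: float, n_comparisons: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    return min(p * n_comparisons, 1.0)


@dataclass
class GeeLimbGroupResult:
    group_means: pd.Series
    contrasts: pd.DataFrame  # group_a, group_b, estimate, se, z, p, p_bonferroni
    fit: object


def fit_gee_limbgroups(
    table: pd.DataFrame,
    *,
    outcome_column: str = "outcome_pct_change",
    group_column: str = "limb_group",
    cluster_column: str = "patient_id",
    working_correlation: str = "exchangeable",
) -> GeeLimbGroupResult:
    """Gaussian GEE of atrophy on limb group with robust (sandwich) variances.

    Identity link, exchangeable working correlation within patient (or
    independence on request), and all pairwise group contrasts Wald-tested
    with Bonferroni multiplication by the number of contrasts.
    """
    groups_present = [g for g in table[group_column].unique()]
    if len(groups_present) < 2:
        raise ValueError("at least two limb groups are required")
    for g in groups_present:
        sub = table[table[group_column] == g]
        if sub[cluster_column].nunique() < 2:
            raise ValueError(f"limb group {g!r} has a single patient; GEE not identifiable")
    levels = sorted(groups_present)
    dummies = pd.get_dummies(
        pd.Categorical(table[group_column], categories=levels), drop_first=False
    ).astype(float)
    X = dummies.to_numpy()  # cell-means coding: one column per group, no intercept
    cov = (
        sm.cov_struct.Exchangeable()
        if working_correlation == "exchangeable"
        else sm.cov_struct.Independence()
    )
    model = sm.GEE(
        table[outcome_column].to_numpy(float),
        X,
        groups=table[cluster_column].to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=cov,
    )
    fit = model.fit()
    means = pd.Series(fit.params, index=levels)
    V = np.asarray(fit.cov_params())
    rows = []
    pairs = list(combinations(range(len(levels)), 2))
    for i, j in pairs:
        c = np.zeros(len(levels))
        c[i], c[j] = 1.0, -1.0
        est = float(c @ fit.params)
        se = float(np.sqrt(c @ V @ c))
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            {
                "group_a": levels[i],
                "group_b": levels[j],
                "estimate": est,
                "se": se,
                "z": z,
                "p": p,
                "p_bonferroni": bonferroni(p, len(pairs)),
            }
        )
    return GeeLimbGroupResult(group_means=means, contrasts=pd.DataFrame(rows), fit=fit)


def fit_ols_tm(
    table: pd.DataFrame,
    covariates: list[str],
    outcome_column: str = "tm_atrophy_pct",
) -> pd.DataFrame:
    """OLS for day-10 temporalis atrophy on clinical covariates + %active.

    Complete rows only; returns a coefficient table with 95% CIs.  A
    rank-deficient design raises, naming the aliased columns.
    """
    cols = list(covariates)
    if "pct_active" not in cols:
        raise ValueError("the covariate list must include pct_active")
    data = table.dropna(subset=cols + [outcome_column])
    X = data[cols].to_numpy(float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few complete rows (n={n}) for {p} covariates plus intercept")
    design = sm.add_constant(pd.DataFrame(X, columns=cols))
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        aliased = [
            c
            for c in cols
            if np.linalg.matrix_rank(design.drop(columns=[c]).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")
    fit = sm.OLS(data[outcome_column].to_numpy(float), design).fit()
    ci = fit.conf_int(alpha=0.05)
    return pd.DataFrame(
        {
            "coefficient": design.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "ci_lower": ci[0].to_numpy(),
            "ci_upper": ci[1].to_numpy(),
        }
    )


def welch_ttest(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance t-test: returns (t, df, two-sided p).

    Degenerate case: both groups constant with equal means yields
    ``(0, nan, 1)`` by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return (0.0, float("nan"), 1.0)
        return (float("inf") if a.mean() > b.mean() else float("-inf"), float("nan"), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return (float(res.statistic), float(res.df), float(res.pvalue))
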