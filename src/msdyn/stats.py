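"""Group comparisons, effect sizes, FDR correction, and pain correlations.

Continuous metrics are routed by per-group Shapiro-Wilk normality tests
(alpha = .05) to either a pooled-variance two-sample t-test or a
Mann-Whitney U test; Cohen's d (HP minus LP, pooled SD) is always
reported. Families of related tests (the four classes of one temporal
parameter; the twelve transition pairs) are corrected together with the
Benjamini-Hochberg step-up procedure. A Gaussian identity-link GLM
provides covariate-adjusted group effects as a sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

__all__ = [
    "StatsResult",
    "DegenerateDataError",
    "cohens_d",
    "cohens_d_from_samples",
    "route_and_compare",
    "chi_square_2x2",
    "mixed_anova",
    "glm_adjust",
    "fdr_bh",
    "apply_fdr",
    "correlate_with_nrs",
    "power_t_test",
    "compare_groups",
]


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined (e.g. zero variance in
    both groups)."""


@dataclass
class StatsResult:
    """One comparison: test used, statistic, raw and corrected p, effect size."""

    name: str
    test: str
    statistic: float
    p: float
    p_fdr: float = float("nan")
    d: float = float("nan")
    family: str = ""

    def as_dict(self) -> dict:
        return {
            "comparison": self.name,
            "family": self.family,
            "test": self.test,
            "statistic": self.statistic,
            "p_raw": self.p,
            "p_fdr": self.p_fdr,
            "d": self.d,
        }


def cohens_d(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> float:
    """Pooled-SD standardized mean difference (group 1 minus group 2)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be nonnegative")
    if s1 == 0 and s2 == 0:
        raise DegenerateDataError("both SDs zero: d undefined")
    sp = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    return float((m1 - m2) / sp)


def cohens_d_from_samples(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size)


def route_and_compare(
    x: np.ndarray,
    y: np.ndarray,
    name: str = "",
    family: str = "",
    normality_alpha: float = 0.05,
    t_variant: str = "student",
) -> StatsResult:
    """Normality-routed two-group comparison (HP values first).

    Both groups pass Shapiro-Wilk at ``normality_alpha`` -> two-sample
    t-test (pooled variance by default, Welch via ``t_variant="welch"``);
    otherwise Mann-Whitney U with the tie-corrected normal approximation.
    Cohen's d is reported either way.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least three subjects per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise DegenerateDataError(f"{name}: zero variance in both groups")
    normal = (
        sps.shapiro(x).pvalue > normality_alpha
        and sps.shapiro(y).pvalue > normality_alpha
    )
    if normal:
        res = sps.ttest_ind(x, y, equal_var=(t_variant == "student"))
        test = "t" if t_variant == "student" else "welch-t"
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        test = "mann-whitney"
    return StatsResult(
        name=name,
        test=test,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        d=cohens_d_from_samples(x, y),
        family=family,
    )


def chi_square_2x2(table: np.ndarray, name: str = "") -> StatsResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1, without
    continuity correction."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return StatsResult(name=name, test="chi2", statistic=float(chi2), p=float(p))


def mixed_anova(
    metrics: pd.DataFrame,
    parameter: str,
    groups: pd.Series | np.ndarray,
    class_names: tuple[str, ...] = ("A", "B", "C", "D"),
    posthoc: bool = True,
    alpha: float = 0.05,
) -> tuple[list[StatsResult], list[StatsResult]]:
    """2 (group, between) x 4 (class, within) mixed ANOVA on one temporal
    parameter ("dur", "occ", or "cov" column prefix).

    Returns (ANOVA effects, per-class post-hoc results). Post-hoc tests
    run through :func:`route_and_compare` with BH correction across the
    four classes whenever a main or interaction effect is significant.
    """
    import pingouin as pg

    cols = [f"{parameter}_{c}" for c in class_names]
    missing = [c for c in cols if c not in metrics.columns]
    if missing:
        raise ValueError(f"missing class columns: {missing}")
    if metrics[cols].isna().any().any():
        raise ValueError("incomplete per-class metrics")

    groups = np.asarray(groups)
    long = metrics[cols].copy()
    long["subject"] = metrics.index if metrics.index.is_unique else np.arange(len(metrics))
    long["group"] = groups
    long = long.melt(
        id_vars=["subject", "group"], value_vars=cols,
        var_name="ms_class", value_name="value",
    )
    # coverage is compositional (rows sum to 100), so its between-subject
    # variance is structurally zero and the between-group F is undefined;
    # pingouin emits a harmless 0/0 warning in that case
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        aov = pg.mixed_anova(
            data=long, dv="value", within="ms_class", subject="subject", between="group"
        )
    effects = []
    for _, row in aov.iterrows():
        effects.append(
            StatsResult(
                name=f"{parameter}:{row['Source']}",
                test="F",
                statistic=float(row["F"]),
                p=float(row["p_unc"] if "p_unc" in row else row["p-unc"]),
                family=f"{parameter}_anova",
            )
        )
    post: list[StatsResult] = []
    if posthoc and any(e.p < alpha for e in effects):
        hp = groups == groups[0] if "HP" not in set(groups) else groups == "HP"
        for c, col in zip(class_names, cols):
            post.append(
                route_and_compare(
                    metrics.loc[hp, col].to_numpy(),
                    metrics.loc[~hp, col].to_numpy(),
                    name=col, family=parameter,
                )
            )
        post = apply_fdr(post)
    return effects, post


def glm_adjust(
    df: pd.DataFrame,
    metric: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "surgery", "bdi_ii", "alnd"),
) -> StatsResult:
    """Covariate-adjusted group effect from a Gaussian identity-link
    linear model: metric ~ group + covariates.

    Reports the adjusted HP-vs-LP coefficient with its Wald p value.
    Categorical covariates are handled by treatment coding; a singular
    design is rejected with a diagnostic.
    """
    for c in (metric, group_col, *covariates):
        if c not in df.columns:
            raise ValueError(f"column {c!r} missing")
    work = df[[metric, group_col, *covariates]].copy()
    # HP indicator so the sign convention matches HP - LP
    work["_grp"] = (work[group_col] == "HP").astype(float)
    # constant covariates carry no information; keeping them would only
    # make the design singular
    keep = [c for c in covariates if work[c].nunique() > 1]
    terms = " + ".join(
        f"C({c})" if work[c].dtype == object else c for c in keep
    )
    formula = f"{metric} ~ _grp" + (f" + {terms}" if terms else "")
    model = smf.ols(formula, data=work)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("singular design matrix: collinear covariates")
    fit = model.fit()
    return StatsResult(
        name=f"{metric}|adjusted",
        test="glm",
        statistic=float(fit.params["_grp"]),
        p=float(fit.pvalues["_grp"]),
        family="glm",
    )


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[StatsResult]) -> list[StatsResult]:
    """Fill corrected p values family-by-family."""
    out = list(results)
    families: dict[str, list[int]] = {}
    for i, r in enumerate(out):
        families.setdefault(r.family, []).append(i)
    for idxs in families.values():
        adj = fdr_bh([out[i].p for i in idxs])
        for i, a in zip(idxs, adj):
            out[i] = replace(out[i], p_fdr=float(a))
    return out


def correlate_with_nrs(
    metric: np.ndarray, nrs: np.ndarray
) -> dict[str, tuple[float, float]]:
    """Pearson r and Spearman rho (tie-handled) between a metric and the
    pain rating, each with its p value."""
    metric = np.asarray(metric, dtype=float)
    nrs = np.asarray(nrs, dtype=float)
    if metric.size < 4:
        raise ValueError("need at least four subjects")
    if metric.std() == 0 or nrs.std() == 0:
        raise DegenerateDataError("zero-variance input: correlation undefined")
    pr = sps.pearsonr(metric, nrs)
    sr = sps.spearmanr(metric, nrs)
    return {
        "pearson": (float(pr.statistic), float(pr.pvalue)),
        "spearman": (float(sr.statistic), float(sr.pvalue)),
    }


def power_t_test(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Analytic two-sided power of the pooled two-sample t-test at
    standardized effect ``d`` (noncentral-t)."""
    df = n1 + n2 - 2
    delta = d * np.sqrt(n1 * n2 / (n1 + n2))
    tc = sps.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - sps.nct.cdf(tc, df, delta) + sps.nct.cdf(-tc, df, delta))


def compare_groups(
    metrics: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    class_names: tuple[str, ...] = ("A", "B", "C", "D"),
    t_variant: str = "student",
) -> pd.DataFrame:
    """All primary group comparisons with per-family FDR correction.

    Families: the four classes of each temporal parameter (duration,
    occurrence, coverage) and the twelve transition percentages. Returns a
    tidy results table (one row per comparison).
    """
    groups = np.asarray(groups)
    hp = groups == "HP"
    results: list[StatsResult] = []
    fams = {
        "duration": [f"dur_{c}" for c in class_names],
        "occurrence": [f"occ_{c}" for c in class_names],
        "coverage": [f"cov_{c}" for c in class_names],
        "transition": [c for c in metrics.columns if c.startswith("tr_")],
    }
    for fam, cols in fams.items():
        for col in cols:
            results.append(
                route_and_compare(
                    metrics.loc[hp, col].to_numpy(),
                    metrics.loc[~hp, col].to_numpy(),
                    name=col, family=fam, t_variant=t_variant,
                )
            )
    results = apply_fdr(results)
    return pd.DataFrame([r.as_dict() for r in results])
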