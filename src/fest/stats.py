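"""Inferential machinery for FEST analyses.

Covers the analysis chain applied to arcsine-transformed scores: a
two-way mixed ANOVA (between-subject listener group × within-subject
sequence coherence) with partial eta-squared effect sizes, OLS
regression of order-correct scores on listener covariates with squared
bivariate and squared semi-partial correlations, commonality analysis
partitioning the regression R² into unique and shared components over
all predictor subsets, Bonferroni-corrected pairwise t-tests, and
Pearson correlation tables with a two-tier significance flag.

Commonality analysis writes the model R² as an exact sum of 2^k − 1
components, one per non-empty predictor subset: the singleton ("unique")
component of predictor *i* equals its squared semi-partial correlation
(the R² increment when *i* joins the other k−1 predictors); multi-
predictor components capture variance attributable to the subset
jointly but to no single member, and may legitimately be negative in
suppression scenarios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "AnovaResult",
    "RegressionResult",
    "CommonalityResult",
    "mixed_anova",
    "fit_regression",
    "commonality_partition",
    "unique_pct_of_effect",
    "pairwise_t_bonferroni",
    "pearson_matrix",
]


@dataclass
class AnovaResult:
    """Mixed-ANOVA summary: one row per effect.

    ``table`` has index {between-name, within-name, "Interaction"} and
    columns F, df_num, df_den, p, partial_eta_sq.
    """

    table: pd.DataFrame
    between: str
    within: str

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def mixed_anova(
    scores: pd.DataFrame,
    *,
    dv: str,
    within: str = "condition",
    between: str = "group",
    subject: str = "listener_id",
) -> AnovaResult:
    """Two-way mixed ANOVA on a long-format score table.

    Classical sums-of-squares decomposition for a k-group between ×
    2-level within design; partial eta-squared is
    SS_effect / (SS_effect + SS_error_for_that_effect).  Requires every
    subject to have one observation per within level.
    """
    import pingouin as pg

    counts = scores.groupby(subject)[within].nunique()
    n_levels = scores[within].nunique()
    incomplete = counts[counts < n_levels]
    if len(incomplete):
        raise ValueError(
            f"subjects missing a {within} level: {sorted(incomplete.index.tolist())}"
        )
    if scores[between].nunique() < 2:
        raise ValueError("need at least two between-subject groups")
    data = scores[[subject, within, between, dv]].rename(columns={dv: "_dv_"})
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = pg.mixed_anova(
            data=data, dv="_dv_", within=within, between=between, subject=subject
        )
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    table = pd.DataFrame(
        {
            "F": aov["F"].to_numpy(dtype=float),
            "df_num": aov["DF1"].to_numpy(dtype=int),
            "df_den": aov["DF2"].to_numpy(dtype=int),
            "p": aov[pcol].to_numpy(dtype=float),
            "partial_eta_sq": aov["np2"].to_numpy(dtype=float),
            "_ss": aov["SS"].to_numpy(dtype=float),
        },
        index=pd.Index(aov["Source"], name="effect"),
    )
    # a zero effect sum-of-squares is F = 0 by definition; pingouin
    # yields 0/0 = NaN when the error SS is also zero (degenerate data)
    degenerate = table["F"].isna() & (table["_ss"] == 0)
    table.loc[degenerate, ["F", "partial_eta_sq"]] = 0.0
    table.loc[degenerate, "p"] = 1.0
    table = table.drop(columns="_ss")
    return AnovaResult(table=table, between=between, within=within)


@dataclass
class RegressionResult:
    """OLS summary in the layout of the FEST covariate-regression tables.

    ``coefficients`` has one row per predictor with columns estimate,
    se, ci_low, ci_high, beta, p, r2_bivariate, r2_semipartial.
    """

    coefficients: pd.DataFrame
    r2: float
    adj_r2: float
    f: float
    df_model: int
    df_resid: int
    f_p: float
    n: int


def fit_regression(y: pd.Series | np.ndarray, X: pd.DataFrame) -> RegressionResult:
    """OLS of a (transformed) score on a covariate table.

    Reports, per predictor: unstandardised estimate with SE and 95% CI,
    standardised beta, p value, squared bivariate correlation with the
    outcome, and squared semi-partial correlation (the R² drop when the
    predictor is removed from the full model).  Rows with missing values
    are dropped listwise with a warning.
    """
    import statsmodels.api as sm

    y = pd.Series(np.asarray(y, dtype=float), index=X.index, name="y")
    data = pd.concat([y, X.astype(float)], axis=1)
    n_before = len(data)
    data = data.dropna()
    if len(data) < n_before:
        warnings.warn(
            f"listwise deletion dropped {n_before - len(data)} rows; effective n = {len(data)}",
            stacklevel=2,
        )
    yv = data["y"]
    Xv = data[X.columns]
    k = Xv.shape[1]
    if len(data) <= k + 1:
        raise ValueError(f"need n > k+1 observations (n={len(data)}, k={k})")
    design = sm.add_constant(Xv)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(yv, design).fit()

    zy = (yv - yv.mean()) / yv.std(ddof=1)
    zX = (Xv - Xv.mean()) / Xv.std(ddof=1)
    zfit = sm.OLS(zy, sm.add_constant(zX)).fit()

    ci = fit.conf_int(alpha=0.05)
    rows = []
    for name in X.columns:
        reduced = sm.OLS(yv, sm.add_constant(Xv.drop(columns=[name]))).fit()
        rows.append(
            {
                "estimate": fit.params[name],
                "se": fit.bse[name],
                "ci_low": ci.loc[name, 0],
                "ci_high": ci.loc[name, 1],
                "beta": zfit.params[name],
                "p": fit.pvalues[name],
                "r2_bivariate": float(np.corrcoef(yv, Xv[name])[0, 1] ** 2),
                "r2_semipartial": float(fit.rsquared - reduced.rsquared),
            }
        )
    coefs = pd.DataFrame(rows, index=pd.Index(X.columns, name="predictor"))
    return RegressionResult(
        coefficients=coefs,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        f=float(fit.fvalue),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        f_p=float(fit.f_pvalue),
        n=len(data),
    )


@dataclass
class CommonalityResult:
    """All-subsets variance partition of a regression R².

    ``components`` maps each non-empty predictor subset (a frozenset of
    names) to its commonality coefficient; they sum to ``r2_full``.
    ``pct_of_effect`` expresses each as a percentage of R² (sums to 100).
    Negative components are reported as-is.
    """

    components: dict[frozenset, float]
    r2_full: float

    @property
    def pct_of_effect(self) -> dict[frozenset, float]:
        if self.r2_full == 0:
            raise ZeroDivisionError("model R² is zero; percentages undefined")
        return {s: 100.0 * c / self.r2_full for s, c in self.components.items()}

    def unique(self, predictor: str) -> float:
        return self.components[frozenset([predictor])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component": ("Unique: " if len(s) == 1 else "Shared: ")
                + ", ".join(sorted(s)),
                "size": len(s),
                "variance": c,
                "pct_of_effect": 100.0 * c / self.r2_full if self.r2_full else np.nan,
            }
            for s, c in self.components.items()
        ]
        return (
            pd.DataFrame(rows)
            .sort_values(["size", "component"])
            .reset_index(drop=True)
        )


def _subset_r2(y: np.ndarray, X: np.ndarray, cols: tuple[int, ...]) -> float:
    """R² of an OLS fit of y on the selected columns (with intercept)."""
    n = len(y)
    design = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - np.sum(resid**2) / tss)


def all_subset_r2(y: pd.Series | np.ndarray, X: pd.DataFrame) -> dict[frozenset, float]:
    """R² for every subset of predictors (empty set → 0)."""
    names = list(X.columns)
    yv = np.asarray(y, dtype=float)
    Xv = X.to_numpy(dtype=float)
    out: dict[frozenset, float] = {frozenset(): 0.0}
    idx = {name: j for j, name in enumerate(names)}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            out[frozenset(combo)] = _subset_r2(yv, Xv, tuple(idx[c] for c in combo))
    return out


def commonality_partition(y: pd.Series | np.ndarray, X: pd.DataFrame) -> CommonalityResult:
    """Partition the full-model R² into 2^k − 1 commonality components.

    For a non-empty subset S the coefficient is

        C(S) = Σ_{∅≠T⊆S} (−1)^{|S|−|T|} · [R²(full) − R²(full \\ T)]

    so C({i}) is exactly predictor i's squared semi-partial correlation,
    and the full set of components sums to R²(full).  Limited to k ≤ 12
    predictors (the number of subset regressions doubles per predictor).
    """
    names = list(X.columns)
    k = len(names)
    if k > 12:
        raise ValueError(f"commonality analysis limited to k <= 12 predictors (got {k})")
    r2 = all_subset_r2(y, X)
    full = frozenset(names)
    r2_full = r2[full]
    components: dict[frozenset, float] = {}
    for r in range(1, k + 1):
        for combo in combinations(names, r):
            S = frozenset(combo)
            c = 0.0
            for rr in range(1, len(combo) + 1):
                for sub in combinations(combo, rr):
                    T = frozenset(sub)
                    sign = (-1) ** (len(S) - len(T))
                    c += sign * (r2_full - r2[full - T])
            components[S] = c
    return CommonalityResult(components=components, r2_full=r2_full)


def unique_pct_of_effect(semi_partial_sq: float, r2_full: float) -> float:
    """A component's share of the regression effect, percent of R²."""
    if r2_full <= 0:
        raise ValueError("r2_full must be positive")
    if not 0 <= semi_partial_sq <= r2_full:
        raise ValueError(
            f"semi-partial² {semi_partial_sq} outside [0, r2_full={r2_full}]"
        )
    return 100.0 * semi_partial_sq / r2_full


def pairwise_t_bonferroni(
    groups: Mapping[str, Sequence[float]],
    m: int | None = None,
    *,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """All pairwise independent-samples t-tests with Bonferroni control.

    ``m`` defaults to the number of pairs.  The classical pooled-variance
    t is used unless ``welch``.  Returns one row per pair with t, df, p,
    the adjusted threshold alpha/m, and the significance decision.
    """
    names = list(groups)
    pairs = list(combinations(names, 2))
    if m is None:
        m = len(pairs)
    if m < 1:
        raise ValueError("m must be >= 1")
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {a if len(xa) < 2 else b!r} has n < 2")
        t, p = _st.ttest_ind(xa, xb, equal_var=not welch)
        if welch:
            va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
            df = (va + vb) ** 2 / (va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1))
        else:
            df = len(xa) + len(xb) - 2
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "df": float(df),
                "p": float(p),
                "alpha_adjusted": alpha / m,
                "significant": bool(p < alpha / m),
            }
        )
    return pd.DataFrame(rows)


def pearson_matrix(
    scores: pd.DataFrame, covariates: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r between every score column and every covariate column.

    Rows are covariates, columns are score measures; each cell carries r,
    its p value, and a two-tier flag ("**" at p < .05, "*" at the
    exploratory p < .1 tier).  Requires ≥3 complete pairs per cell and
    non-degenerate columns.
    """
    rows = []
    for cov in covariates.columns:
        row: dict[str, object] = {"covariate": cov}
        for sc in scores.columns:
            pair = pd.concat([scores[sc], covariates[cov]], axis=1).dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({sc}, {cov})")
            x, yv = pair.iloc[:, 0], pair.iloc[:, 1]
            if x.std(ddof=0) == 0 or yv.std(ddof=0) == 0:
                raise ValueError(f"zero-variance column in pair ({sc}, {cov})")
            r, p = _st.pearsonr(x, yv)
            row[f"{sc}_r"] = float(r)
            row[f"{sc}_p"] = float(p)
            row[f"{sc}_flag"] = "**" if p < 0.05 else ("*" if p < 0.1 else "")
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")
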