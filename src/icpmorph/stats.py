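"""Cohort statistics for patient-level morphology summaries.

The analysis design: age and mean ICP are each cut into four levels at
their upwards-rounded quartiles, a 4x4 factorial ANOVA (Type III sums of
squares, sum-to-zero coding) with partial eta-squared effect sizes and
Bonferroni post-hoc comparisons quantifies their main and interaction
effects on the pulse shape index (PSI) or pulse amplitude (AmpICP);
multiple regression with Rotterdam CT score entered as dummy variables
adjusts for structural injury; independent-samples t-tests and logistic
regression with ROC/AUC relate the morphology metrics to six-month
mortality.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sstats
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.outliers_influence import variance_inflation_factor

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# quartile categorization

@dataclass(frozen=True)
class FactorSpec:
    """Four-level categorization of a continuous variable.

    Three ascending boundaries define the levels (<=b1, (b1,b2], (b2,b3],
    >b3), labelled 1-4.
    """

    variable: str
    boundaries: tuple[float, float, float]

    def __post_init__(self) -> None:
        b1, b2, b3 = self.boundaries
        if not (b1 < b2 < b3):
            raise ValueError(f"boundaries must be ascending, got {self.boundaries}")

    def assign(self, values) -> np.ndarray:
        """Level (1-4) for each value."""
        v = np.asarray(values, dtype=float)
        b1, b2, b3 = self.boundaries
        return np.select([v <= b1, v <= b2, v <= b3], [1, 2, 3], default=4)


def quartile_boundaries(values, variable: str = "") -> FactorSpec:
    """Quartile cut points, rounded upwards to integers.

    Q1, median and Q3 are computed with the linear-interpolation quantile
    definition and each is rounded up (ceiling), giving integer boundaries
    that put a comparable number of observations in each of four levels.
    """
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    if v.size < 8:
        raise ValueError(f"need >= 8 non-missing values, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("degenerate input: all values equal")
    q = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
    bounds = tuple(int(math.ceil(x)) for x in q)
    if not (bounds[0] < bounds[1] < bounds[2]):
        raise ValueError(
            f"quartile boundaries collapse after rounding: {bounds}")
    return FactorSpec(variable=variable, boundaries=bounds)


# ---------------------------------------------------------------------------
# factorial ANOVA

@dataclass
class AnovaResult:
    terms: pd.DataFrame          # per term: F, df_effect, df_error, p, partial_eta2
    cell_means: pd.DataFrame     # factor_a level x factor_b level: mean, se, n
    posthoc: dict[str, pd.DataFrame]
    n: int

    def report(self) -> str:
        """Text report in the 'F(df effect, df error) = F, p' convention."""
        lines = [f"Factorial ANOVA (Type III SS, sum-to-zero coding), N = {self.n}"]
        for term, row in self.terms.iterrows():
            lines.append(
                f"  {term}: F({int(row.df_effect)}, {int(row.df_error)}) = "
                f"{row.F:.3f}, p = {row.p:.4g}, partial eta2 = "
                f"{row.partial_eta2:.3f}")
        return "\n".join(lines)


def factorial_anova(table: pd.DataFrame, response: str,
                    factor_a: FactorSpec, factor_b: FactorSpec
                    ) -> AnovaResult:
    """Two-way factorial ANOVA with interaction on an unbalanced design.

    Type III sums of squares with sum-to-zero factor coding; partial
    eta-squared = SS_effect / (SS_effect + SS_error); Bonferroni post-hoc
    tables for marginal (main effect) and cell (interaction) means, with
    raw p-values multiplied by the family size and capped at 1.

    Raises if any cell of the full factorial is empty (naming the cell) or
    if the response is missing for any retained row.
    """
    df = table.dropna(subset=[response, factor_a.variable,
                              factor_b.variable]).copy()
    df["_A"] = factor_a.assign(df[factor_a.variable])
    df["_B"] = factor_b.assign(df[factor_b.variable])

    counts = df.groupby(["_A", "_B"]).size()
    for a in (1, 2, 3, 4):
        for b in (1, 2, 3, 4):
            if (a, b) not in counts.index:
                raise ValueError(
                    f"empty design cell: {factor_a.variable} level {a} x "
                    f"{factor_b.variable} level {b}")

    model = smf.ols(f"{response} ~ C(_A, Sum) * C(_B, Sum)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = anova_lm(model, typ=3)
    ss_err = float(aov.loc["Residual", "sum_sq"])
    df_err = int(aov.loc["Residual", "df"])

    name_map = {
        "C(_A, Sum)": factor_a.variable,
        "C(_B, Sum)": factor_b.variable,
        "C(_A, Sum):C(_B, Sum)": f"{factor_a.variable}:{factor_b.variable}",
    }
    rows = {}
    for raw_name, name in name_map.items():
        ss = float(aov.loc[raw_name, "sum_sq"])
        rows[name] = {
            "ss": ss,
            "df_effect": int(aov.loc[raw_name, "df"]),
            "df_error": df_err,
            "F": float(aov.loc[raw_name, "F"]),
            "p": float(aov.loc[raw_name, "PR(>F)"]),
            "partial_eta2": ss / (ss + ss_err),
        }
    terms = pd.DataFrame(rows).T

    mse = ss_err / df_err
    cells = df.groupby(["_A", "_B"])[response].agg(["mean", "count"])
    cells["se"] = np.sqrt(mse / cells["count"])
    cell_means = cells.rename_axis(
        [factor_a.variable, factor_b.variable]).reset_index()

    posthoc = {
        factor_a.variable: _bonferroni_pairs(df, response, "_A", mse, df_err),
        factor_b.variable: _bonferroni_pairs(df, response, "_B", mse, df_err),
        f"{factor_a.variable}:{factor_b.variable}": _bonferroni_pairs(
            df.assign(_cell=list(zip(df["_A"], df["_B"]))),
            response, "_cell", mse, df_err),
    }
    return AnovaResult(terms=terms, cell_means=cell_means, posthoc=posthoc,
                       n=len(df))


def _bonferroni_pairs(df: pd.DataFrame, response: str, group: str,
                      mse: float, df_err: int) -> pd.DataFrame:
    """All pairwise mean comparisons within one family, Bonferroni-adjusted.

    t statistics use the pooled ANOVA error (MSE with df_error degrees of
    freedom); adjusted p = min(1, m * p_raw) where m is the family size,
    reported in every row.
    """
    stats_by = df.groupby(group)[response].agg(["mean", "count"])
    levels = list(stats_by.index)
    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        m1, n1 = stats_by.loc[[g1], "mean"].iloc[0], stats_by.loc[[g1], "count"].iloc[0]
        m2, n2 = stats_by.loc[[g2], "mean"].iloc[0], stats_by.loc[[g2], "count"].iloc[0]
        se = np.sqrt(mse * (1 / n1 + 1 / n2))
        t = (m1 - m2) / se if se > 0 else np.nan
        p_raw = 2 * sstats.t.sf(abs(t), df_err) if np.isfinite(t) else np.nan
        rows.append({"level_1": g1, "level_2": g2, "diff": m1 - m2,
                     "t": t, "p_raw": p_raw,
                     "p_bonferroni": min(1.0, m * p_raw) if np.isfinite(p_raw) else np.nan,
                     "m_comparisons": m})
    return pd.DataFrame(rows)


def bonferroni_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, m * p) per value."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# multiple regression with dummy variables

@dataclass
class RegressionResult:
    beta: pd.Series              # standardized coefficients
    p_values: pd.Series
    r_squared: float
    vif: pd.Series
    n: int
    n_dropped: int


def multiple_regression(table: pd.DataFrame, response: str,
                        continuous: tuple[str, ...] = ("age", "mean_icp"),
                        dummy: str | None = "rotterdam") -> RegressionResult:
    """OLS of a standardized response on standardized predictors.

    Continuous predictors are z-scored so coefficients are standardized
    betas; the dummy variable (Rotterdam CT score) enters as indicator
    columns against its lowest observed level.  Rows with any missing
    value are dropped (complete-case) and the count is logged.  Variance
    inflation factors flag collinearity.  Rank deficiency raises with the
    aliased columns named.
    """
    cols = [response, *continuous] + ([dummy] if dummy else [])
    df = table[cols].dropna()
    n_dropped = len(table) - len(df)
    if n_dropped:
        logger.info("multiple_regression: dropped %d incomplete rows", n_dropped)
    if len(df) < len(cols) + 2:
        raise ValueError(f"too few complete cases ({len(df)})")

    X = pd.DataFrame(index=df.index)
    for c in continuous:
        sd = df[c].std(ddof=1)
        if sd == 0:
            raise ValueError(f"predictor {c!r} is constant")
        X[c] = (df[c] - df[c].mean()) / sd
    if dummy:
        levels = sorted(df[dummy].unique())
        for lev in levels[1:]:
            X[f"{dummy}_{lev:g}" if isinstance(lev, float) else
              f"{dummy}_{lev}"] = (df[dummy] == lev).astype(float)
    y = (df[response] - df[response].mean()) / df[response].std(ddof=1)

    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        aliased = _aliased_columns(Xc)
        raise ValueError(f"design matrix is rank deficient; aliased columns: "
                         f"{aliased}")
    fit = sm.OLS(y, Xc).fit()
    vif = pd.Series(
        {col: variance_inflation_factor(Xc.to_numpy(), i)
         for i, col in enumerate(Xc.columns) if col != "const"})
    return RegressionResult(beta=fit.params.drop("const"),
                            p_values=fit.pvalues.drop("const"),
                            r_squared=float(fit.rsquared), vif=vif,
                            n=len(df), n_dropped=n_dropped)


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    kept: list[str] = []
    aliased: list[str] = []
    for col in X.columns:
        trial = X[kept + [col]].to_numpy()
        if np.linalg.matrix_rank(trial) == len(kept) + 1:
            kept.append(col)
        else:
            aliased.append(col)
    return aliased


# ---------------------------------------------------------------------------
# group comparison and logistic regression / ROC

@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_1: float
    sd_1: float
    n_1: int
    mean_2: float
    sd_2: float
    n_2: int

    def report(self, label: str = "") -> str:
        return (f"{label}: {self.mean_1:.1f} +/- {self.sd_1:.1f} (n={self.n_1}) "
                f"vs {self.mean_2:.1f} +/- {self.sd_2:.1f} (n={self.n_2}), "
                f"t({self.df}) = {self.t:.2f}, p = {self.p:.4g}")


def group_ttest(table: pd.DataFrame, response: str,
                groups: str = "died6m") -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance).

    Group 1 is the group with the truthy/higher group label (e.g. the
    deceased), group 2 the other; means are reported as mean +/- SD.
    """
    df = table[[response, groups]].dropna()
    labels = sorted(df[groups].unique(), reverse=True)
    if len(labels) != 2:
        raise ValueError(f"expected 2 groups, got {labels}")
    g1 = df.loc[df[groups] == labels[0], response].to_numpy(dtype=float)
    g2 = df.loc[df[groups] == labels[1], response].to_numpy(dtype=float)
    t, p = sstats.ttest_ind(g1, g2, equal_var=True)
    return TTestResult(t=float(t), df=g1.size + g2.size - 2, p=float(p),
                       mean_1=float(g1.mean()), sd_1=float(g1.std(ddof=1)),
                       n_1=g1.size, mean_2=float(g2.mean()),
                       sd_2=float(g2.std(ddof=1)), n_2=g2.size)


def auc_rank(scores, outcomes) -> float:
    """AUC by the rank (concordance) method, ties counted half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome groups must be non-empty")
    ranks = sstats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def auc_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil rank-based standard error of the AUC."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
           + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


@dataclass
class LogisticRocResult:
    coefficients: pd.Series
    chi2: float                  # likelihood-ratio vs intercept-only
    df: int
    p: float
    auc: float
    auc_se: float
    n: int
    n_dropped: int
    retained: list[str] = field(default_factory=list)
    separation: bool = False


def logistic_auc(table: pd.DataFrame, predictors: list[str],
                 outcome: str = "died6m",
                 eliminate: bool = False) -> LogisticRocResult:
    """Logistic regression of a binary outcome with ROC/AUC evaluation.

    Maximum-likelihood fit; chi2 is the likelihood-ratio statistic against
    the intercept-only model with df = number of retained predictors; AUC
    is computed from the fitted probabilities by the rank (concordance)
    method with a Hanley-McNeil standard error.  Rows with a missing
    outcome or predictor are dropped (complete-case, count logged).

    With ``eliminate=True``, backward elimination removes predictors whose
    likelihood-ratio test exceeds alpha = 0.05, mirroring redundancy
    screening in a multivariate model.  Complete separation is flagged and
    handled with an L2-penalized fallback fit.
    """
    df = table[[outcome, *predictors]].dropna()
    n_dropped = len(table) - len(df)
    if n_dropped:
        logger.info("logistic_auc: dropped %d rows with missing data", n_dropped)
    y = df[outcome].astype(float).to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("outcome must take exactly two values")

    retained = list(predictors)
    if eliminate:
        retained = _backward_eliminate(df, retained, outcome, alpha=0.05)

    X = sm.add_constant(df[retained]) if retained else \
        pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0)
        probs = np.asarray(fit.predict(X))
        llf, llnull = fit.llf, fit.llnull
        coefs = fit.params
        if np.all(np.abs(probs - y) < 1e-8):
            separation = True
    except Exception:
        separation = True
        warnings.warn("complete separation (or non-convergence) detected; "
                      "using L2-penalized fallback fit")
        fit = sm.Logit(y, X).fit_regularized(
            method="l1", alpha=1e-4, disp=0)  # near-MLE, bounded coefs
        probs = np.asarray(fit.predict(X))
        probs = np.clip(probs, 1e-12, 1 - 1e-12)
        llf = float(np.sum(y * np.log(probs) + (1 - y) * np.log(1 - probs)))
        p_bar = y.mean()
        llnull = float(len(y) * (p_bar * np.log(p_bar)
                                 + (1 - p_bar) * np.log(1 - p_bar)))
        coefs = fit.params

    k = len(retained)
    chi2 = max(0.0, 2 * (llf - llnull))
    p = float(sstats.chi2.sf(chi2, k)) if k else 1.0
    auc = auc_rank(probs, y.astype(bool))
    return LogisticRocResult(
        coefficients=pd.Series(coefs, index=X.columns), chi2=chi2, df=k,
        p=p, auc=auc, auc_se=auc_se(auc, int(y.sum()), int((1 - y).sum())),
        n=len(df), n_dropped=n_dropped, retained=retained,
        separation=separation)


def _loglik(df: pd.DataFrame, predictors: list[str], outcome: str) -> float:
    y = df[outcome].astype(float).to_numpy()
    X = sm.add_constant(df[predictors]) if predictors else \
        pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    return float(sm.Logit(y, X).fit(disp=0).llf)


def _backward_eliminate(df: pd.DataFrame, predictors: list[str],
                        outcome: str, alpha: float = 0.05) -> list[str]:
    """Drop, one at a time, the predictor with the weakest LR-test support."""
    current = list(predictors)
    while current:
        ll_full = _loglik(df, current, outcome)
        worst, worst_p = None, -1.0
        for pred in current:
            reduced = [c for c in current if c != pred]
            lr = max(0.0, 2 * (ll_full - _loglik(df, reduced, outcome)))
            p = sstats.chi2.sf(lr, 1)
            if p > worst_p:
                worst, worst_p = pred, p
        if worst_p > alpha:
            logger.info("backward elimination: dropping %s (LR p = %.3g)",
                        worst, worst_p)
            current.remove(worst)
        else:
            break
    return current
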