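"""Group-level frequentist statistics.

Covers the analysis battery applied to the per-subject SDT summaries:
fully within-subject repeated-measures ANOVA (two-level factors, partial eta
squared), Pearson correlations of trait scores with sensitivity/bias under a
Bonferroni-adjusted alpha, and ordinary least squares with collinearity
screening (VIF / tolerance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "AnovaResult",
    "CorrelationResult",
    "RegressionResult",
    "rm_anova",
    "pearson_with_bonferroni",
    "ols_with_vif",
]


@dataclass
class AnovaResult:
    table: pd.DataFrame          # per effect: F, df1, df2, p, partial_eta_sq
    factors: list = field(default_factory=list)

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


@dataclass
class CorrelationResult:
    table: pd.DataFrame          # per pair: r, p, n, significant
    alpha: float = 0.05
    alpha_adjusted: float = 0.0125


@dataclass
class RegressionResult:
    coefficients: pd.Series
    std_errors: pd.Series
    r_squared: float
    vif: pd.Series
    tolerance: pd.Series
    model: object = None


def rm_anova(
    summary: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "subject_id",
) -> AnovaResult:
    """Repeated-measures ANOVA on a complete balanced within-subject design
    (up to three two-level factors).

    Returns F, degrees of freedom, p and partial eta squared
    (F*df1 / (F*df1 + df2)) per main effect and interaction.  With two-level
    factors sphericity holds by design, so no correction is applied.
    """
    if summary[subject].nunique() < 3:
        raise ValueError("need at least 3 subjects")
    cells = summary.groupby(within, observed=True).size()
    n_sub = summary[subject].nunique()
    if (cells != n_sub).any() or len(summary) != n_sub * int(np.prod(
        [summary[w].nunique() for w in within]
    )):
        raise ValueError("design incomplete: every subject needs every cell")
    fit = AnovaRM(summary, depvar=dv, subject=subject, within=list(within)).fit()
    tab = fit.anova_table.rename(
        columns={"F Value": "F", "Num DF": "df1", "Den DF": "df2", "Pr > F": "p"}
    )
    _zero_degenerate_effects(tab, summary, dv, list(within), subject)
    tab["partial_eta_sq"] = tab["F"] * tab["df1"] / (tab["F"] * tab["df1"] + tab["df2"])
    return AnovaResult(table=tab, factors=list(within))


def _zero_degenerate_effects(tab, summary, dv, within, subject) -> None:
    """With a constant per-subject effect contrast the F ratio is 0/0 and
    the least-squares fit returns numerical noise; such effects are truly
    null (F = 0, p = 1).  Only two-level factors are screened (the ±1
    contrast is exact there)."""
    if any(summary[w].nunique() != 2 for w in within):
        return
    cell = summary.set_index([subject, *within])[dv]
    for effect in tab.index:
        parts = effect.split(":")
        signs = None
        for w in within:
            lvls = sorted(summary[w].unique())
            col = cell.index.get_level_values(w)
            s = np.where(col == lvls[0], 1.0, -1.0) if w in parts else 1.0
            signs = s if signs is None else signs * s
        contrast = (cell * signs).groupby(level=0).mean()
        if np.allclose(contrast, 0.0, atol=1e-12):
            tab.loc[effect, ["F", "p"]] = [0.0, 1.0]


def pearson_with_bonferroni(
    trait_matrix: pd.DataFrame,
    outcome: pd.Series | np.ndarray,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson r of an outcome against each trait column, flagged for
    significance at alpha / n_comparisons (0.0125 for the four O-LIFE
    subscales at the default alpha)."""
    outcome = np.asarray(outcome, dtype=float)
    if len(trait_matrix) != len(outcome):
        raise ValueError("trait matrix and outcome length mismatch")
    if len(outcome) < 4:
        raise ValueError("need at least 4 observations")
    if np.std(outcome) == 0:
        raise ValueError("outcome is constant: correlation undefined")
    adj = alpha / trait_matrix.shape[1]
    rows = []
    for name in trait_matrix.columns:
        x = trait_matrix[name].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise ValueError(f"trait {name} is constant: correlation undefined")
        r, p = sps.pearsonr(x, outcome)
        rows.append({"trait": name, "r": r, "p": p, "n": len(outcome),
                     "significant": p < adj})
    return CorrelationResult(
        table=pd.DataFrame(rows).set_index("trait"), alpha=alpha, alpha_adjusted=adj
    )


def ols_with_vif(covariates: pd.DataFrame, response) -> RegressionResult:
    """OLS of the response on the covariates (intercept added), with
    per-covariate variance inflation factors and tolerances.

    VIF_j = 1/(1 - R²_j) from regressing covariate j on the others;
    tolerance is its reciprocal.
    """
    y = np.asarray(response, dtype=float)
    X = covariates.astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError("need more observations than covariates plus one")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise ValueError("covariates are collinear (rank deficient)")
    Xc = sm.add_constant(X)
    model = sm.OLS(y, Xc).fit()
    vif = pd.Series(
        [variance_inflation_factor(Xc.to_numpy(), i + 1) for i in range(k)],
        index=X.columns,
    )
    return RegressionResult(
        coefficients=model.params,
        std_errors=model.bse,
        r_squared=float(model.rsquared),
        vif=vif,
        tolerance=1.0 / vif,
        model=model,
    )
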