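"""Determinant models: linear regression for hemoglobin and logistic
regression for anemia.

The hemoglobin model is ordinary least squares on log10-transformed biomarker
predictors, screened for multicollinearity with the variance inflation factor
(VIF < 2.5).  Each predictor's unique contribution is quantified by the
squared semipartial correlation, computed by explicit nested refit
(R2_full - R2_without_j) with a partial-F p-value; an algebraic identity from
the full-model t statistic serves as an independent cross-check in the test
suite.

The anemia model follows the classic epidemiological two-stage recipe: a
bivariate logistic screen of each candidate factor (retain Wald p < alpha),
then a multivariate maximum-likelihood logistic fit reporting odds ratios
with 95% Wald confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LinearModelResult",
    "LogisticModelResult",
    "transform_predictors",
    "vif_screen",
    "fit_hb_model",
    "bivariate_screen",
    "fit_anemia_model",
    "percent_odds_reduction",
    "SeparationWarning",
]

Z_95 = float(stats.norm.ppf(0.975))


class SeparationWarning(UserWarning):
    """The outcome is (quasi-)separable on a factor; estimates are unstable."""


def transform_predictors(
    cohort: pd.DataFrame, skewed: list[str], epsilon: float = 0.01
) -> pd.DataFrame:
    """log10-transform the listed right-skewed columns; others untouched.

    Values at or below ``epsilon`` (in the column's own units) are rejected
    with the offending row ids rather than silently floored, since flooring
    would distort downstream regression fits.
    """
    out = cohort.copy()
    for col in skewed:
        vals = out[col].to_numpy(dtype=float)
        bad = np.nonzero(vals <= epsilon)[0]
        if bad.size:
            raise ValueError(
                f"column {col!r}: nonpositive/near-zero values at rows "
                f"{bad[:10].tolist()}; cannot log-transform"
            )
        out[col] = np.log10(vals)
    return out


def _vif_table(X: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R2_j) from regressing predictor j on the others."""
    vifs = {}
    Xc = sm.add_constant(X, has_constant="add")
    for col in X.columns:
        others = Xc.drop(columns=[col])
        r2 = sm.OLS(Xc[col], others).fit().rsquared
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs)


def vif_screen(
    X: pd.DataFrame, threshold: float = 2.5, drop: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Iterative VIF screen: drop the worst offender and recompute each round.

    Returns the retained design matrix and a table recording every round's
    VIFs and which predictor (if any) was dropped.
    """
    if X.shape[1] < 2:
        raise ValueError("VIF screening needs at least two predictors")
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    history = []
    current = X.copy()
    round_ix = 0
    while True:
        vifs = _vif_table(current)
        worst = vifs.idxmax()
        dropped = drop and (vifs[worst] >= threshold) and current.shape[1] > 2
        for col, v in vifs.items():
            history.append(
                {"round": round_ix, "predictor": col, "vif": float(v),
                 "dropped": bool(dropped and col == worst)}
            )
        if not dropped:
            # a final offender in a 2-column design is flagged but kept
            break
        current = current.drop(columns=[worst])
        round_ix += 1
    return current, pd.DataFrame(history)


@dataclass
class LinearModelResult:
    """OLS fit summary with per-predictor squared semipartial correlations."""

    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    semipartial_r2: pd.Series
    semipartial_pvalues: pd.Series
    r2: float
    adjusted_r2_percent: float
    n: int
    log10_predictors: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "r2": self.r2,
            "adjusted_r2_percent": self.adjusted_r2_percent,
            "predictors": {
                name: {
                    "coefficient": float(self.params[name]),
                    "ci95": [float(self.conf_int.loc[name, 0]),
                             float(self.conf_int.loc[name, 1])],
                    "p_value": float(self.pvalues[name]),
                    "semipartial_r2": float(self.semipartial_r2[name]),
                    "semipartial_p_value": float(self.semipartial_pvalues[name]),
                    "log10_transformed": name in self.log10_predictors,
                }
                for name in self.params.index
                if name != "const"
            },
        }

    def to_text(self) -> str:
        lines = [
            f"Linear model for hemoglobin (n = {self.n}, "
            f"adjusted R^2 = {self.adjusted_r2_percent:.1f}%)",
            f"{'predictor':<14s} {'coef':>8s} {'95% CI':>20s} {'p':>8s} "
            f"{'sr^2':>7s} {'p(sr^2)':>8s}",
        ]
        for name in self.params.index:
            if name == "const":
                continue
            lo, hi = self.conf_int.loc[name, 0], self.conf_int.loc[name, 1]
            lines.append(
                f"{name:<14s} {self.params[name]:8.3f} "
                f"({lo:8.3f}, {hi:8.3f}) {self.pvalues[name]:8.3f} "
                f"{self.semipartial_r2[name]:7.3f} "
                f"{self.semipartial_pvalues[name]:8.3f}"
            )
        return "\n".join(lines)


def fit_hb_model(design: pd.DataFrame, hb) -> LinearModelResult:
    """OLS for hemoglobin with squared semipartial correlations by refit.

    The semipartial for predictor j is R2(full) - R2(full minus j), i.e. the
    variance uniquely attributable to j; its p-value is the partial F test of
    the nested comparison.  Adjusted R^2 is reported as a percentage.
    """
    y = np.asarray(hb, dtype=float)
    if len(design) <= design.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    X = sm.add_constant(design, has_constant="add")
    full = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix; run vif_screen first")
    n, p = len(y), design.shape[1]
    sr2 = {}
    sr2_p = {}
    for col in design.columns:
        reduced = sm.OLS(y, X.drop(columns=[col])).fit()
        delta = full.rsquared - reduced.rsquared
        sr2[col] = delta
        # partial F for one dropped column
        f_stat = delta / ((1.0 - full.rsquared) / (n - p - 1))
        sr2_p[col] = float(stats.f.sf(f_stat, 1, n - p - 1))
    return LinearModelResult(
        params=full.params,
        conf_int=full.conf_int(),
        pvalues=full.pvalues,
        semipartial_r2=pd.Series(sr2),
        semipartial_pvalues=pd.Series(sr2_p),
        r2=float(full.rsquared),
        adjusted_r2_percent=float(100.0 * full.rsquared_adj),
        n=n,
    )


@dataclass
class LogisticModelResult:
    """Odds ratios with 95% Wald confidence intervals."""

    odds_ratios: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    n: int
    converged: bool
    separation_flagged: bool = False
    reference_levels: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "converged": self.converged,
            "separation_flagged": self.separation_flagged,
            "factors": {
                name: {
                    "odds_ratio": float(self.odds_ratios[name]),
                    "ci95": [float(self.conf_int.loc[name, 0]),
                             float(self.conf_int.loc[name, 1])],
                    "p_value": float(self.pvalues[name]),
                    "reference": self.reference_levels.get(name, ""),
                }
                for name in self.odds_ratios.index
                if name != "const"
            },
        }

    def to_text(self) -> str:
        lines = [
            f"Logistic model for anemia (n = {self.n})",
            f"{'factor':<16s} {'OR':>8s} {'95% CI':>22s} {'p':>8s}",
        ]
        for name in self.odds_ratios.index:
            if name == "const":
                continue
            lo, hi = self.conf_int.loc[name, 0], self.conf_int.loc[name, 1]
            lines.append(
                f"{name:<16s} {self.odds_ratios[name]:8.3f} "
                f"({lo:9.3f}, {hi:9.3f}) {self.pvalues[name]:8.3f}"
            )
        return "\n".join(lines)


def _check_separation(X: pd.DataFrame, y: np.ndarray) -> bool:
    for col in X.columns:
        x = X[col].to_numpy()
        if len(np.unique(x)) <= 2:
            tab = pd.crosstab(x, y)
            if (tab.to_numpy() == 0).any():
                return True
    return False


def fit_anemia_model(factors: pd.DataFrame, outcome) -> LogisticModelResult:
    """Multivariate ML logistic regression for a binary anemia outcome.

    Odds ratio = exp(coefficient); 95% CI = exp(coef +/- 1.96 SE).  A
    quasi-separated factor (zero cell against the outcome) triggers a
    :class:`SeparationWarning` and sets ``separation_flagged``.  An outcome
    with fewer than 10 events draws a small-sample warning.
    """
    y = np.asarray(outcome, dtype=int)
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    events = int(y.sum())
    if min(events, len(y) - events) < 10:
        warnings.warn(
            f"only {min(events, len(y) - events)} events; odds ratios will "
            f"be unstable",
            stacklevel=2,
        )
    separated = _check_separation(factors, y)
    if separated:
        warnings.warn(
            "quasi-complete separation detected; Wald intervals unreliable",
            SeparationWarning,
            stacklevel=2,
        )
    X = sm.add_constant(factors.astype(float), has_constant="add")
    if separated:
        # penalized (ridge) fallback: the unpenalized likelihood has no
        # maximum under separation
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit_pen = glm.fit_regularized(alpha=1e-3, L1_wt=0.0)
        params = pd.Series(np.asarray(fit_pen.params), index=X.columns)
        eta = X.to_numpy() @ params.to_numpy()
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        info = X.to_numpy().T @ (X.to_numpy() * w[:, None])
        cov = np.linalg.pinv(info)
        se = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
        pvalues = pd.Series(
            2.0 * stats.norm.sf(np.abs(params / se)), index=X.columns
        )
        converged = True
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels' overflow chatter
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        if not converged:
            raise RuntimeError(
                f"logistic fit did not converge: {fit.mle_retvals}"
            )
        params, se, pvalues = fit.params, fit.bse, fit.pvalues
    ors = np.exp(params)
    ci = pd.DataFrame(
        {0: np.exp(params - Z_95 * se), 1: np.exp(params + Z_95 * se)},
        index=params.index,
    )
    return LogisticModelResult(
        odds_ratios=ors,
        conf_int=ci,
        pvalues=pvalues,
        n=len(y),
        converged=converged,
        separation_flagged=separated,
    )


def bivariate_screen(
    factors: pd.DataFrame, outcome, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """One-factor logistic screen; retain factors with Wald p < alpha.

    For a binary factor forming a 2x2 table with a zero cell, a
    continuity-corrected (add 0.5 to all cells) odds ratio and its Woolf SE
    replace the unstable ML estimate, with a warning.
    """
    y = np.asarray(outcome, dtype=int)
    if y.min() == y.max():
        raise ValueError("outcome has no variation")
    rows = []
    retained = []
    for col in factors.columns:
        x = factors[col].to_numpy(dtype=float)
        binary = set(np.unique(x)) <= {0.0, 1.0}
        zero_cell = False
        if binary:
            a = np.sum((x == 1) & (y == 1))
            b = np.sum((x == 1) & (y == 0))
            c = np.sum((x == 0) & (y == 1))
            d = np.sum((x == 0) & (y == 0))
            zero_cell = 0 in (a, b, c, d)
        if zero_cell:
            warnings.warn(
                f"factor {col!r}: zero cell in its 2x2 table; using a "
                f"continuity-corrected odds ratio",
                SeparationWarning,
                stacklevel=2,
            )
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            log_or = np.log((a * d) / (b * c))
            se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
            p = 2.0 * stats.norm.sf(abs(log_or / se))
            or_, lo, hi = np.exp(log_or), np.exp(log_or - Z_95 * se), np.exp(log_or + Z_95 * se)
        else:
            X = sm.add_constant(pd.DataFrame({col: x}), has_constant="add")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            or_ = float(np.exp(fit.params[col]))
            lo = float(np.exp(fit.params[col] - Z_95 * fit.bse[col]))
            hi = float(np.exp(fit.params[col] + Z_95 * fit.bse[col]))
            p = float(fit.pvalues[col])
        keep = p < alpha
        if keep:
            retained.append(col)
        rows.append(
            {"factor": col, "odds_ratio": float(or_), "ci_low": float(lo),
             "ci_high": float(hi), "p_value": float(p), "retained": keep,
             "continuity_corrected": zero_cell}
        )
    return retained, pd.DataFrame(rows)


def percent_odds_reduction(odds_ratio: float) -> float:
    """(1 - OR) x 100: percent lower odds for the index vs reference level.

    The standard prose rendering of a protective odds ratio, e.g. OR 0.035
    reads as '96.5% less likely'.
    """
    return (1.0 - odds_ratio) * 100.0
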