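"""Food-insecurity scoring, asset-based wealth index, and covariate recodes.

The HFIAS (Household Food Insecurity Access Scale) instrument asks nine
occurrence questions about the previous four weeks, ranging from worry about
food to spending whole days and nights without eating; each affirmative
answer carries a frequency code (1 = rarely, 2 = sometimes, 3 = often).  The
continuous score is the sum of the nine frequency codes (0-27).  The
four-level access category follows the FANTA most-severe-condition rule: each
(item, frequency) combination triggers a severity level per the packaged
decision table, and the household's category is the worst triggered level.

The wealth index is the standard DHS-style first principal component of
standardized household asset indicators, cut into quintiles on ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic_cohort import _HFIAS_LUT, HFIAS_CATEGORIES

__all__ = [
    "HFIASResponse",
    "WealthIndexResult",
    "hfias_score",
    "hfias_category",
    "wealth_index",
    "recode_covariates",
    "score_cohort",
]


@dataclass(frozen=True)
class HFIASResponse:
    """Nine (occurrence, frequency) pairs; frequency > 0 requires occurrence."""

    items: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.items) != 9:
            raise ValueError("HFIAS has exactly nine items")
        for i, (occ, freq) in enumerate(self.items, start=1):
            if occ not in (0, 1):
                raise ValueError(f"item {i}: occurrence must be 0/1")
            if freq not in (0, 1, 2, 3):
                raise ValueError(f"item {i}: frequency must be 0-3")
            if freq > 0 and occ == 0:
                raise ValueError(
                    f"item {i}: frequency {freq} reported without occurrence"
                )
            if occ == 1 and freq == 0:
                raise ValueError(
                    f"item {i}: occurrence reported without a frequency"
                )

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f for _, f in self.items], dtype=int)


def hfias_score(r: HFIASResponse) -> int:
    """Continuous food-insecurity score: sum of frequency codes, 0-27."""
    return int(r.frequencies.sum())


def hfias_category(r: HFIASResponse) -> str:
    """Four-level access category by the FANTA most-severe-condition rule."""
    freqs = r.frequencies
    codes = [_HFIAS_LUT[item, f] for item, f in zip(range(1, 10), freqs)]
    return HFIAS_CATEGORIES[max(codes) - 1]


def hfias_category_codes(freq_matrix: np.ndarray) -> np.ndarray:
    """Vectorized category codes (1-4) for an (n, 9) frequency matrix."""
    items = np.arange(1, 10)
    return _HFIAS_LUT[items[None, :], freq_matrix].max(axis=1)


@dataclass(frozen=True)
class WealthIndexResult:
    """First-principal-component wealth scores with quintile assignment."""

    scores: np.ndarray
    quintiles: np.ndarray
    loadings: dict[str, float]
    explained_variance_fraction: float
    dropped_indicators: tuple[str, ...]


def wealth_index(assets: pd.DataFrame) -> WealthIndexResult:
    """DHS-style asset wealth index.

    Indicators are standardized to zero mean/unit variance; the score is the
    projection on the first principal component, sign-oriented so the
    indicator with the largest absolute loading loads positively.  Quintiles
    are cut at the 20/40/60/80 rank percentiles with average-rank ties, so
    group sizes differ by at most one.
    """
    X = assets.astype(float)
    variances = X.var(axis=0, ddof=1)
    dropped = tuple(X.columns[variances == 0.0])
    if dropped:
        warnings.warn(
            f"dropping zero-variance asset indicators: {list(dropped)}",
            stacklevel=2,
        )
        X = X.drop(columns=list(dropped))
    if X.shape[1] < 2:
        raise ValueError("need at least two asset indicators with variance")
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    # PCA via SVD of the standardized matrix
    _, s, vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    loadings = vt[0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    scores = Z.to_numpy() @ loadings
    evf = float(s[0] ** 2 / np.sum(s**2))
    ranks = rankdata(scores, method="average")
    quintiles = np.ceil(5.0 * ranks / len(scores)).astype(int)
    quintiles = np.clip(quintiles, 1, 5)
    return WealthIndexResult(
        scores=scores,
        quintiles=quintiles,
        loadings=dict(zip(X.columns, loadings)),
        explained_variance_fraction=evf,
        dropped_indicators=dropped,
    )


# Covariate recodes used by the anemia determinant models.  Each entry maps a
# model factor to (indicator rule, reference-level description).
def recode_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Binary model covariates at the survey's printed cuts.

    low_muac: MUAC < 22 cm; young_age: age <= 21 years; low_gravidity:
    gravidity 1-3 (reference 4-8); illiterate; low_zinc: plasma zinc < 10.7
    umol/L; low_tfr: sTfR < 8.3 mg/L (reference >= 8.3, the at-risk band);
    low_agp: AGP <= 1 g/L (reference > 1).
    """
    out = pd.DataFrame(index=df.index)
    out["low_muac"] = (df["muac"] < 22.0).astype(int)
    out["young_age"] = (df["age"] <= 21.0).astype(int)
    out["low_gravidity"] = df["gravidity"].between(1, 3).astype(int)
    out["illiterate"] = (df["education"] == "illiterate").astype(int)
    out["low_zinc"] = (df["zinc"] < 10.7).astype(int)
    out["low_tfr"] = (df["tfr"] < 8.3).astype(int)
    out["low_agp"] = (df["agp"] <= 1.0).astype(int)
    return out


def score_cohort(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """HFIAS score/category, wealth quintiles and covariate recodes in one go.

    Returns the augmented frame and a JSON-serializable report (wealth
    loadings, explained variance, HFIAS category counts).
    """
    df = df.copy()
    freq_cols = [f"hfias{i}_freq" for i in range(1, 10)]
    freqs = df[freq_cols].to_numpy(dtype=int)
    df["hfias_score"] = freqs.sum(axis=1)
    codes = hfias_category_codes(freqs)
    df["hfias_category"] = np.array(HFIAS_CATEGORIES)[codes - 1]

    asset_cols = [c for c in df.columns if c.startswith("asset")]
    wealth = wealth_index(df[asset_cols])
    df["wealth_score"] = wealth.scores
    df["wealth_quintile"] = wealth.quintiles

    recodes = recode_covariates(df)
    for col in recodes.columns:
        df[col] = recodes[col]

    report = {
        "wealth_loadings": wealth.loadings,
        "wealth_explained_variance_fraction": wealth.explained_variance_fraction,
        "hfias_category_counts": {
            cat: int((df["hfias_category"] == cat).sum())
            for cat in HFIAS_CATEGORIES
        },
    }
    return df, report
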