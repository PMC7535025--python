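"""Seeded synthetic cohorts of lactating women for anemia-survey pipelines.

The raw data behind the survey this package models are not deposited, so every
downstream stage (inflammation adjustment, status classification, modeling) is
exercised against synthetic cohorts instead.  The generator is calibrated to
published summary statistics:

* each biomarker marginal is a monotone quantile function anchored at the
  printed median/IQR and at printed prevalence thresholds (e.g. 19.1% of
  women below the 120 g/L anemia cutoff);
* the joint distribution is a Gaussian copula whose latent correlation matrix
  is calibrated by stochastic root-finding so that empirical Pearson
  correlations on the analysis scale (natural log for right-skewed
  biomarkers) match the printed r values;
* socio-demographic fields (education, food-insecurity category, assets,
  anthropometry) are drawn independently from the printed category
  frequencies and mean/SD pairs.

Everything is deterministic given the top-level seed: each stage draws from a
named substream so the cohort is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr

from ._rng import substream

__all__ = [
    "QuantileAnchoredMarginal",
    "CopulaSpec",
    "CohortSpec",
    "WomanRecord",
    "EffectsHook",
    "build_anchors",
    "sample_marginal",
    "calibrate_copula",
    "generate_cohort",
    "default_cohort_spec",
    "write_cohort_csv",
    "read_cohort_csv",
    "BIOMARKER_COLUMNS",
    "HFIAS_CATEGORIES",
]

BIOMARKER_COLUMNS = (
    "hb",
    "ferritin",
    "tfr",
    "plasma_iron",
    "hepcidin",
    "crp",
    "agp",
    "zinc",
    "selenium",
)

HFIAS_CATEGORIES = ("food_secure", "mild", "moderate", "severe")


class CalibrationError(ValueError):
    """A marginal or copula specification cannot be calibrated."""


# ---------------------------------------------------------------------------
# Quantile-anchored marginals
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantileAnchoredMarginal:
    """A marginal distribution defined by monotone (probability, value) anchors.

    The quantile function interpolates the anchors piecewise-linearly, on the
    natural-log scale of the value when ``log_scale`` is set (appropriate for
    right-skewed biomarkers such as ferritin or CRP).  Beyond the extreme
    anchors the outermost segment's slope is continued (overridable via
    ``tail_slope_low``/``tail_slope_high``, in analysis-scale units per unit
    probability), capped at ``cap_factor`` times the outermost anchor value
    and floored at ``floor``.  Optional hard ``bounds`` clip the result.
    """

    name: str
    anchors: tuple[tuple[float, float], ...]
    log_scale: bool = False
    tail_slope_low: float | None = None
    tail_slope_high: float | None = None
    floor: float = 1e-6
    cap_factor: float = 5.0
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise CalibrationError(
                f"marginal {self.name!r}: need at least two anchors"
            )
        prev_p, prev_q = self.anchors[0]
        self._check_anchor(prev_p, prev_q)
        for p, q in self.anchors[1:]:
            self._check_anchor(p, q)
            if p <= prev_p or q <= prev_q:
                raise CalibrationError(
                    f"marginal {self.name!r}: anchors must be strictly "
                    f"increasing in both p and q; offending pair "
                    f"({prev_p}, {prev_q}) -> ({p}, {q})"
                )
            prev_p, prev_q = p, q

    def _check_anchor(self, p: float, q: float) -> None:
        if not 0.0 < p < 1.0:
            raise CalibrationError(
                f"marginal {self.name!r}: anchor probability {p} not in (0, 1)"
            )
        if self.log_scale and q <= 0:
            raise CalibrationError(
                f"marginal {self.name!r}: log-scale anchor value {q} <= 0"
            )

    # internal analysis-scale representation -------------------------------

    @property
    def _p(self) -> np.ndarray:
        return np.array([a[0] for a in self.anchors])

    @property
    def _y(self) -> np.ndarray:
        q = np.array([a[1] for a in self.anchors])
        return np.log(q) if self.log_scale else q

    def _slopes(self) -> tuple[float, float]:
        p, y = self._p, self._y
        lo = self.tail_slope_low
        hi = self.tail_slope_high
        if lo is None:
            lo = (y[1] - y[0]) / (p[1] - p[0])
        if hi is None:
            hi = (y[-1] - y[-2]) / (p[-1] - p[-2])
        return float(lo), float(hi)

    def ppf(self, u) -> np.ndarray:
        """Quantile function evaluated at uniform deviates ``u`` in (0, 1)."""
        u = np.asarray(u, dtype=float)
        if np.any((u <= 0.0) | (u >= 1.0)):
            raise ValueError(f"marginal {self.name!r}: u must lie in (0, 1)")
        p, y = self._p, self._y
        slo, shi = self._slopes()
        vals = np.interp(u, p, y)
        lo = u < p[0]
        hi = u > p[-1]
        vals = np.where(lo, y[0] + slo * (u - p[0]), vals)
        vals = np.where(hi, y[-1] + shi * (u - p[-1]), vals)
        if self.log_scale:
            out = np.exp(vals)
        else:
            out = vals
        q_last = self.anchors[-1][1]
        out = np.minimum(out, self.cap_factor * q_last)
        out = np.maximum(out, self.floor)
        if self.bounds is not None:
            out = np.clip(out, self.bounds[0], self.bounds[1])
        return out

    def analysis_ppf(self, u) -> np.ndarray:
        """Quantile on the analysis scale (log of value when log_scale)."""
        v = self.ppf(u)
        return np.log(v) if self.log_scale else v

    def cdf(self, x) -> np.ndarray:
        """Exact inverse of :meth:`ppf` (ignoring floor/cap/bounds clipping)."""
        x = np.asarray(x, dtype=float)
        y = np.log(x) if self.log_scale else x
        p, ya = self._p, self._y
        slo, shi = self._slopes()
        out = np.interp(y, ya, p)
        lo = y < ya[0]
        hi = y > ya[-1]
        out = np.where(lo, p[0] + (y - ya[0]) / slo, out)
        out = np.where(hi, p[-1] + (y - ya[-1]) / shi, out)
        return np.clip(out, 0.0, 1.0)


def build_anchors(
    name: str,
    median: float,
    iqr: tuple[float, float],
    thresholds: Sequence[tuple[float, float]] = (),
) -> tuple[tuple[float, float], ...]:
    """Merge median/IQR anchors with prevalence-threshold anchors.

    ``thresholds`` are (value, cumulative probability) pairs, e.g. a printed
    prevalence of 78% below a 10.7 cutoff gives (10.7, 0.78).  Threshold
    anchors take precedence: any IQR anchor that would break strict
    monotonicity against a threshold anchor is dropped with a warning.  The
    classification thresholds are the testable core of the pipeline, so their
    implied prevalences must be exact; the IQR is a rounded summary.
    """
    threshold_anchors = sorted((float(p), float(v)) for v, p in thresholds)
    iqr_anchors = [(0.25, float(iqr[0])), (0.5, float(median)), (0.75, float(iqr[1]))]

    kept: list[tuple[float, float]] = []
    for p, q in iqr_anchors:
        ok = all(
            (p < tp and q < tq) or (p > tp and q > tq)
            for tp, tq in threshold_anchors
        )
        if ok:
            kept.append((p, q))
        else:
            warnings.warn(
                f"marginal {name!r}: IQR anchor (p={p}, q={q}) conflicts with "
                f"a prevalence-threshold anchor and was dropped",
                stacklevel=2,
            )
    merged = sorted(kept + threshold_anchors)
    return tuple(merged)


def sample_marginal(m: QuantileAnchoredMarginal, u) -> np.ndarray:
    """Inverse-quantile sampling: evaluate the marginal at uniform deviates."""
    return m.ppf(u)


# ---------------------------------------------------------------------------
# Gaussian copula
# ---------------------------------------------------------------------------


@dataclass
class CopulaSpec:
    """Target and latent correlation structure for the Gaussian copula.

    ``target_corr`` holds Pearson correlations on the analysis scale; pairs
    not constrained by a published value are zero.  ``repaired_latent_corr``
    is filled in by :func:`calibrate_copula`.
    """

    variables: tuple[str, ...]
    target_corr: np.ndarray
    repaired_latent_corr: np.ndarray | None = None
    max_repair_perturbation: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.target_corr, dtype=float)
        k = len(self.variables)
        if t.shape != (k, k):
            raise CalibrationError("target_corr shape does not match variables")
        if not np.allclose(t, t.T, atol=1e-12):
            raise CalibrationError("target_corr must be symmetric")
        if not np.allclose(np.diag(t), 1.0, atol=1e-12):
            raise CalibrationError("target_corr must have unit diagonal")
        if np.any(np.abs(t) > 1.0):
            raise CalibrationError("target_corr entries must lie in [-1, 1]")
        self.target_corr = t

    @classmethod
    def from_pairs(
        cls,
        variables: Sequence[str],
        pairs: Sequence[tuple[str, str, float]],
    ) -> "CopulaSpec":
        variables = tuple(variables)
        idx = {v: i for i, v in enumerate(variables)}
        t = np.eye(len(variables))
        for a, b, r in pairs:
            i, j = idx[a], idx[b]
            t[i, j] = t[j, i] = float(r)
        return cls(variables=variables, target_corr=t)


def repair_correlation_matrix(
    corr: np.ndarray, min_eig: float = 1e-6
) -> tuple[np.ndarray, float]:
    """Clip eigenvalues to ``min_eig`` and renormalize to unit diagonal.

    Returns the repaired matrix and the maximum elementwise perturbation.
    """
    corr = np.asarray(corr, dtype=float)
    w, v = np.linalg.eigh(corr)
    if w.min() > min_eig:
        return corr.copy(), 0.0
    w_clipped = np.clip(w, min_eig, None)
    repaired = (v * w_clipped) @ v.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.max(np.abs(repaired - corr)))


def _empirical_r(
    rho: float,
    z: np.ndarray,
    ma: QuantileAnchoredMarginal,
    mb: QuantileAnchoredMarginal,
) -> float:
    """Pearson r on the analysis scale for latent correlation ``rho``.

    Uses common random numbers (the fixed standard-normal matrix ``z``) so
    the map rho -> r is smooth and monotone for the root finder.
    """
    z2 = rho * z[:, 0] + np.sqrt(max(0.0, 1.0 - rho * rho)) * z[:, 1]
    x = ma.analysis_ppf(ndtr(z[:, 0]))
    y = mb.analysis_ppf(ndtr(z2))
    return float(np.corrcoef(x, y)[0, 1])


def calibrate_copula(
    spec: CopulaSpec,
    marginals: Mapping[str, QuantileAnchoredMarginal],
    n_cal: int = 100_000,
    seed: int = 0,
    tol: float = 0.005,
    max_iter: int = 25,
) -> CopulaSpec:
    """Calibrate latent correlations so analysis-scale Pearson r hits targets.

    For each constrained pair a one-dimensional stochastic root-find (secant
    with common random numbers, ``n_cal`` draws) adjusts the latent Gaussian
    correlation until the empirical correlation of the transformed margins is
    within ``tol`` of the target.  Unconstrained pairs stay at latent zero.
    The assembled matrix is repaired to positive definiteness by eigenvalue
    clipping and renormalization.
    """
    k = len(spec.variables)
    latent = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            target = spec.target_corr[i, j]
            if target == 0.0:
                continue
            a, b = spec.variables[i], spec.variables[j]
            ma, mb = marginals[a], marginals[b]
            rng = substream(seed, f"copula-calibration:{a}:{b}")
            z = rng.standard_normal((int(n_cal), 2))
            hi = _empirical_r(0.999, z, ma, mb)
            lo = _empirical_r(-0.999, z, ma, mb)
            if not (lo - tol <= target <= hi + tol):
                raise CalibrationError(
                    f"target correlation r({a}, {b}) = {target} is "
                    f"unattainable for these margins (achievable range "
                    f"[{lo:.3f}, {hi:.3f}])"
                )
            # secant iteration; the map is close to linear, so few steps needed
            r0, r1 = float(np.clip(target, -0.99, 0.99)), None
            f0 = _empirical_r(r0, z, ma, mb) - target
            if abs(f0) <= tol:
                latent[i, j] = latent[j, i] = r0
                continue
            r1 = float(np.clip(r0 - np.sign(f0) * 0.05, -0.998, 0.998))
            f1 = _empirical_r(r1, z, ma, mb) - target
            for _ in range(max_iter):
                if abs(f1) <= tol or f1 == f0:
                    break
                r2 = r1 - f1 * (r1 - r0) / (f1 - f0)
                r2 = float(np.clip(r2, -0.998, 0.998))
                r0, f0 = r1, f1
                r1 = r2
                f1 = _empirical_r(r1, z, ma, mb) - target
            latent[i, j] = latent[j, i] = r1
    repaired, perturbation = repair_correlation_matrix(latent)
    return dataclasses.replace(
        spec,
        repaired_latent_corr=repaired,
        max_repair_perturbation=perturbation,
    )


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------


@dataclass
class EffectsHook:
    """Optional socio-demographic effects on hemoglobin.

    By default socio-demographic fields are independent of the biomarkers.
    Enabling the hook subtracts ``muac_effect`` g/L of hemoglobin from women
    with MUAC below 22 cm and ``education_effect`` g/L from illiterate women,
    giving the logistic modeling stage recoverable signal (multivariate odds
    ratios above 1 for both risk factors).
    """

    muac_effect: float = 6.0
    education_effect: float = 4.0


@dataclass
class CohortSpec:
    """Everything needed to generate one synthetic cohort."""

    n: int
    seed: int
    marginals: dict[str, QuantileAnchoredMarginal]
    copula: CopulaSpec
    categorical_probs: dict[str, dict[str, float]]
    asset_probs: tuple[float, ...]
    anthropometry: dict[str, dict[str, float]]
    demographics: dict[str, dict[str, float]]
    altitude_m: float = 1700.0
    effects: EffectsHook | None = None
    hb_pre_altitude: bool = False
    altitude_correction_term_g_dl: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        for name, probs in self.categorical_probs.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"categorical probabilities for {name!r} sum to {total}, "
                    f"not 1"
                )


@dataclass
class WomanRecord:
    """One participant: biomarkers, anthropometry and socio-economic fields."""

    id: int
    age: float
    household_size: int
    n_children: int
    gravidity: int
    muac: float
    bmi: float
    education: str
    hfias_items: tuple[tuple[int, int], ...]
    assets: tuple[int, ...]
    altitude: float
    hb_raw: float
    ferritin: float
    tfr: float
    plasma_iron: float
    hepcidin: float
    crp: float
    agp: float
    zinc: float
    selenium: float


# HFIAS severity lookup: category code (1..4) triggered by each item at each
# frequency level; the overall category is the worst triggered condition.
# Loaded from the packaged FANTA v3 decision table.


def _load_hfias_table() -> np.ndarray:
    ref = importlib.resources.files("anemiascope.data") / "hfias_categories.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path)
    lut = np.ones((10, 4), dtype=int)  # item 1..9, frequency 0..3
    for _, row in table.iterrows():
        lut[int(row["item"]), int(row["frequency"])] = int(row["category"])
    return lut


_HFIAS_LUT = _load_hfias_table()


def _sample_hfias_items(
    categories: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw a nine-item frequency pattern consistent with each HFIA category.

    For category c the admissible frequencies of item i are those whose
    severity code does not exceed c; one item is forced to a frequency whose
    code equals c exactly so the pattern maps back to c.
    """
    n = len(categories)
    freqs = np.zeros((n, 9), dtype=int)
    for c in (1, 2, 3, 4):
        mask = categories == c
        m = int(mask.sum())
        if m == 0:
            continue
        allowed = np.zeros(9, dtype=int)
        exact: list[tuple[int, int]] = []
        for item in range(1, 10):
            codes = _HFIAS_LUT[item]
            ok = np.nonzero(codes <= c)[0]
            allowed[item - 1] = ok.max()
            exact.extend((item, f) for f in range(1, 4) if codes[f] == c)
        block = np.zeros((m, 9), dtype=int)
        if c > 1:
            # background: each item at a random admissible frequency, mostly 0
            for item_ix in range(9):
                amax = allowed[item_ix]
                if amax == 0:
                    continue
                draw = rng.integers(0, amax + 1, size=m)
                keep = rng.random(m) < 0.4
                block[:, item_ix] = np.where(keep, draw, 0)
        if c == 1:
            # food secure: all zeros, or the worry item only rarely
            worried = rng.random(m) < 0.35
            block[worried, 0] = 1
        else:
            pick = rng.integers(0, len(exact), size=m)
            for e_ix, (item, f) in enumerate(exact):
                sel = pick == e_ix
                block[sel, item - 1] = f
        freqs[mask] = block
    return freqs


def hfias_items_to_columns(freqs: np.ndarray) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for i in range(9):
        cols[f"hfias{i + 1}_occ"] = (freqs[:, i] > 0).astype(int)
        cols[f"hfias{i + 1}_freq"] = freqs[:, i]
    return cols


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate the cohort as a tidy DataFrame, one row per woman.

    Biomarkers are drawn through the Gaussian copula and the quantile-anchored
    marginals; socio-demographic fields come from independent substreams.
    The hemoglobin column is on the altitude-adjusted scale by default (the
    published summaries are altitude-adjusted); set ``spec.hb_pre_altitude``
    to emit pre-adjustment values by adding the altitude correction term back.
    """
    if spec.copula.repaired_latent_corr is None:
        raise CalibrationError(
            "copula has not been calibrated; run calibrate_copula first"
        )
    n = spec.n
    variables = spec.copula.variables

    rng_latent = substream(spec.seed, "latent-biomarkers")
    z = rng_latent.standard_normal((n, len(variables)))
    chol = np.linalg.cholesky(spec.copula.repaired_latent_corr)
    u = ndtr(z @ chol.T)

    data: dict[str, np.ndarray] = {"id": np.arange(1, n + 1)}
    for j, name in enumerate(variables):
        data[name] = spec.marginals[name].ppf(u[:, j])

    rng_demo = substream(spec.seed, "demographics")
    demo = spec.demographics
    data["age"] = np.round(
        _truncated_normal(
            rng_demo, demo["age"]["mean"], demo["age"]["sd"],
            demo["age"]["min"], demo["age"]["max"], n,
        ),
        1,
    )
    hh = demo["household_size"]
    data["household_size"] = np.clip(
        np.round(rng_demo.normal(hh["mean"], hh["sd"], size=n)),
        hh["min"], hh["max"],
    ).astype(int)
    nc = demo["n_children"]
    n_children = np.clip(
        np.round(rng_demo.normal(nc["mean"], nc["sd"], size=n)),
        nc["min"], nc["max"],
    ).astype(int)
    data["n_children"] = n_children
    # gravidity >= parity: allow occasional pregnancies that did not end in a
    # living child
    extra = (rng_demo.random(n) < 0.25).astype(int)
    data["gravidity"] = np.clip(n_children + extra, 1, 8)

    rng_anthro = substream(spec.seed, "anthropometry")
    for col in ("muac", "bmi"):
        a = spec.anthropometry[col]
        data[col] = np.round(
            _truncated_normal(rng_anthro, a["mean"], a["sd"], a["min"], a["max"], n),
            1,
        )

    rng_cat = substream(spec.seed, "categorical")
    edu = spec.categorical_probs["education"]
    levels = sorted(edu)  # deterministic order
    p = np.array([edu[k] for k in levels])
    data["education"] = np.array(levels)[rng_cat.choice(len(levels), size=n, p=p)]

    hf = spec.categorical_probs["hfias_category"]
    hf_p = np.array([hf[c] for c in HFIAS_CATEGORIES])
    hf_codes = rng_cat.choice(4, size=n, p=hf_p) + 1  # 1..4
    rng_hfias = substream(spec.seed, "hfias-items")
    freqs = _sample_hfias_items(hf_codes, rng_hfias)
    data.update(hfias_items_to_columns(freqs))

    rng_assets = substream(spec.seed, "assets")
    for a_ix, prob in enumerate(spec.asset_probs):
        data[f"asset{a_ix + 1}"] = (rng_assets.random(n) < prob).astype(int)

    data["altitude"] = np.full(n, float(spec.altitude_m))

    hb = np.asarray(data["hb"], dtype=float)
    if spec.effects is not None:
        hb = hb - spec.effects.muac_effect * (data["muac"] < 22.0)
        hb = hb - spec.effects.education_effect * (data["education"] == "illiterate")
    if spec.hb_pre_altitude:
        # undo the altitude correction so the pipeline's own correction stage
        # recovers the adjusted scale
        hb = hb + 10.0 * spec.altitude_correction_term_g_dl
    data["hb"] = hb

    df = pd.DataFrame(data)
    ordered = (
        ["id", "age", "household_size", "n_children", "gravidity", "muac",
         "bmi", "education"]
        + [c for i in range(1, 10) for c in (f"hfias{i}_occ", f"hfias{i}_freq")]
        + [f"asset{i + 1}" for i in range(len(spec.asset_probs))]
        + ["altitude"]
        + list(variables)
    )
    return df[ordered]


def cohort_to_records(df: pd.DataFrame) -> list[WomanRecord]:
    """View a cohort frame as a list of :class:`WomanRecord`."""
    n_assets = len([c for c in df.columns if c.startswith("asset")])
    records = []
    for _, row in df.iterrows():
        records.append(
            WomanRecord(
                id=int(row["id"]),
                age=float(row["age"]),
                household_size=int(row["household_size"]),
                n_children=int(row["n_children"]),
                gravidity=int(row["gravidity"]),
                muac=float(row["muac"]),
                bmi=float(row["bmi"]),
                education=str(row["education"]),
                hfias_items=tuple(
                    (int(row[f"hfias{i}_occ"]), int(row[f"hfias{i}_freq"]))
                    for i in range(1, 10)
                ),
                assets=tuple(int(row[f"asset{i + 1}"]) for i in range(n_assets)),
                altitude=float(row["altitude"]),
                hb_raw=float(row["hb"]),
                ferritin=float(row["ferritin"]),
                tfr=float(row["tfr"]),
                plasma_iron=float(row["plasma_iron"]),
                hepcidin=float(row["hepcidin"]),
                crp=float(row["crp"]),
                agp=float(row["agp"]),
                zinc=float(row["zinc"]),
                selenium=float(row["selenium"]),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_UNITS = {
    "hb": "g/L", "ferritin": "ug/L", "tfr": "mg/L", "plasma_iron": "umol/L",
    "hepcidin": "ug/L", "crp": "mg/L", "agp": "g/L", "zinc": "umol/L",
    "selenium": "umol/L", "muac": "cm", "bmi": "kg/m^2", "altitude": "m",
    "age": "years",
}


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the cohort with a JSON sidecar documenting column units."""
    path = Path(path)
    df.to_csv(path, index=False)
    schema = {
        "columns": {
            c: {"units": _UNITS.get(c, "")} for c in df.columns
        }
    }
    path.with_suffix(".schema.json").write_text(json.dumps(schema, indent=1))


def read_cohort_csv(path: str | Path, required: Sequence[str] = BIOMARKER_COLUMNS) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Packaged default specification
# ---------------------------------------------------------------------------


def _load_default_config() -> dict:
    ref = importlib.resources.files("anemiascope.data") / "default_cohort.yaml"
    with importlib.resources.as_file(ref) as path:
        return yaml.safe_load(path.read_text())


def default_cohort_spec(
    n: int | None = None,
    seed: int = 0,
    calibrate: bool = False,
    n_cal: int = 100_000,
    effects: EffectsHook | None = None,
) -> CohortSpec:
    """The packaged default cohort specification.

    Encodes the published marginal summaries, prevalence thresholds,
    correlation targets and category frequencies.  With ``calibrate=True``
    the copula's latent matrix is calibrated immediately (needed before
    :func:`generate_cohort`).
    """
    cfg = _load_default_config()
    marginals: dict[str, QuantileAnchoredMarginal] = {}
    with warnings.catch_warnings():
        # the packaged spec knowingly carries one IQR/threshold conflict
        warnings.simplefilter("ignore")
        for name, m in cfg["marginals"].items():
            anchors = build_anchors(
                name,
                m["median"],
                tuple(m["iqr"]),
                [(t["value"], t["p"]) for t in m.get("thresholds", [])],
            )
            marginals[name] = QuantileAnchoredMarginal(
                name=name,
                anchors=anchors,
                log_scale=bool(m["log_scale"]),
                bounds=tuple(m["bounds"]) if "bounds" in m else None,
            )
    copula = CopulaSpec.from_pairs(
        variables=list(cfg["marginals"]),
        pairs=[tuple(p) for p in cfg["correlations"]],
    )
    categorical = {}
    for fieldname, probs in cfg["categorical"].items():
        total = sum(probs.values())
        categorical[fieldname] = {k: v / total for k, v in probs.items()}
    spec = CohortSpec(
        n=int(n if n is not None else cfg["n"]),
        seed=int(seed),
        marginals=marginals,
        copula=copula,
        categorical_probs=categorical,
        asset_probs=tuple(cfg["asset_probs"]),
        anthropometry=cfg["anthropometry"],
        demographics=cfg["demographics"],
        altitude_m=float(cfg["altitude_m"]),
        effects=effects,
    )
    if calibrate:
        spec.copula = calibrate_copula(
            spec.copula, spec.marginals, n_cal=n_cal, seed=seed
        )
    return spec
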