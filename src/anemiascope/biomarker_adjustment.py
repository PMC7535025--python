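"""Altitude, inflammation (BRINDA-style) and body-iron corrections.

Three standard corrections precede any interpretation of iron biomarkers in a
high-infection-burden setting:

1. **Altitude**: hemoglobin rises with altitude; a polynomial correction term
   (in g/dL, as the reference equation is written) is subtracted from the
   observed value before applying sea-level anemia cutoffs.
2. **Inflammation**: ferritin is an acute-phase reactant and the transferrin
   receptor is also inflammation-sensitive.  Following the BRINDA approach,
   the natural log of the biomarker is regressed on ln CRP and ln AGP in the
   sample itself; each record's log value is then reduced by the fitted
   slopes times the excess of its inflammation markers over a low-inflammation
   reference (the maximum of the lowest decile), and exponentiated back.
3. **Body iron**: Cook's index converts the transferrin-receptor/ferritin
   ratio into an estimate of total body iron in mg per kg of body weight;
   negative values indicate tissue iron deficiency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AltitudeCorrection",
    "CDC_SCALE_ALTITUDE",
    "AdjustmentModel",
    "altitude_correction_term",
    "adjust_hb_for_altitude",
    "fit_adjustment_model",
    "apply_adjustment",
    "body_iron",
    "adjust_cohort",
    "BODY_IRON_INTERCEPT",
    "BODY_IRON_SLOPE",
]

#: Constants of Cook's body-iron formula: body iron (mg/kg) =
#: -(log10(ratio) - 2.8229) / 0.1207 with ratio = sTfR(ug/L) / ferritin(ug/L).
BODY_IRON_INTERCEPT = 2.8229
BODY_IRON_SLOPE = 0.1207


@dataclass(frozen=True)
class AltitudeCorrection:
    """Coefficients of the altitude correction polynomial.

    The term is ``coeff_linear * x + coeff_quad * x**2`` in g/dL with
    ``x = altitude_m * altitude_factor``.  The defaults are the coefficients
    as printed in the source equation; note that the widely used CDC/WHO
    coefficients are tenfold smaller (``CDC_SCALE_ALTITUDE``) and give far
    more plausible corrections at highland altitudes.  Both are supported;
    which scale a given survey used must be decided by the analyst.
    """

    coeff_linear: float = -0.32
    coeff_quad: float = 0.22
    altitude_factor: float = 0.0033

    def __post_init__(self) -> None:
        if self.altitude_factor <= 0:
            raise ValueError("altitude_factor must be > 0")


CDC_SCALE_ALTITUDE = AltitudeCorrection(coeff_linear=-0.032, coeff_quad=0.022)


def altitude_correction_term(
    altitude_m, params: AltitudeCorrection = AltitudeCorrection()
) -> np.ndarray:
    """Correction term in g/dL to subtract from observed hemoglobin."""
    altitude_m = np.asarray(altitude_m, dtype=float)
    if np.any(altitude_m < 0):
        raise ValueError("altitude must be >= 0 m")
    x = altitude_m * params.altitude_factor
    return params.coeff_linear * x + params.coeff_quad * x**2


def adjust_hb_for_altitude(
    hb_g_l, altitude_m, params: AltitudeCorrection = AltitudeCorrection()
) -> np.ndarray:
    """Observed Hb (g/L) minus 10x the g/dL altitude correction term."""
    return np.asarray(hb_g_l, dtype=float) - 10.0 * altitude_correction_term(
        altitude_m, params
    )


@dataclass(frozen=True)
class AdjustmentModel:
    """Fitted inflammation-correction coefficients for one biomarker.

    ``beta_crp``/``beta_agp`` are OLS slopes of ln(biomarker) on ln(CRP) and
    ln(AGP) jointly (with intercept); ``ref_ln_crp``/``ref_ln_agp`` are the
    maxima of the lowest observed deciles on the ln scale.
    """

    biomarker: str
    beta_crp: float
    beta_agp: float
    ref_ln_crp: float
    ref_ln_agp: float
    n_fit: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ref_ln_crp) and np.isfinite(self.ref_ln_agp)):
            raise ValueError("reference values must be finite")
        if self.n_fit < 20:
            raise ValueError("refusing an adjustment model fitted on n < 20")


def _lowest_decile_max(values: np.ndarray) -> float:
    """Largest observed value among the bottom 10% of the sorted sample.

    The decile holds floor(n/10) observations (at least one); ties with the
    boundary value are included, which cannot change the returned maximum.
    """
    srt = np.sort(values)
    k = max(1, int(np.floor(len(srt) / 10)))
    return float(srt[k - 1])


def fit_adjustment_model(
    biomarker_values, crp, agp, biomarker: str = "ferritin"
) -> AdjustmentModel:
    """Fit the inflammation-correction regression on the sample itself.

    All three inputs must be positive and of equal length >= 20.  Returns the
    slopes of ln(biomarker) ~ ln(CRP) + ln(AGP) and the ln-scale reference
    values (maximum of each marker's lowest decile).
    """
    y = np.asarray(biomarker_values, dtype=float)
    c = np.asarray(crp, dtype=float)
    a = np.asarray(agp, dtype=float)
    if not (len(y) == len(c) == len(a)):
        raise ValueError("biomarker, CRP and AGP must have equal lengths")
    if len(y) < 20:
        raise ValueError(f"need at least 20 observations to fit; got {len(y)}")
    bad = np.nonzero((y <= 0) | (c <= 0) | (a <= 0))[0]
    if bad.size:
        raise ValueError(
            f"nonpositive values at rows {bad[:10].tolist()}; all biomarker, "
            f"CRP and AGP values must be > 0"
        )
    ln_y, ln_c, ln_a = np.log(y), np.log(c), np.log(a)
    if np.ptp(ln_c) == 0 or np.ptp(ln_a) == 0:
        raise ValueError("degenerate design: CRP or AGP is constant")
    X = np.column_stack([np.ones_like(ln_c), ln_c, ln_a])
    coef, *_ = np.linalg.lstsq(X, ln_y, rcond=None)
    return AdjustmentModel(
        biomarker=biomarker,
        beta_crp=float(coef[1]),
        beta_agp=float(coef[2]),
        ref_ln_crp=_lowest_decile_max(ln_c),
        ref_ln_agp=_lowest_decile_max(ln_a),
        n_fit=len(y),
    )


def apply_adjustment(
    value,
    crp,
    agp,
    model: AdjustmentModel,
    clamp_at_reference: bool = True,
    positive_betas_only: bool = True,
) -> np.ndarray:
    """Inflammation-adjust biomarker values, returning the same units.

    adjusted = exp(ln(value) - b1 * excess_crp - b2 * excess_agp) where the
    excesses are ln-scale distances above the reference deciles, clamped at
    zero (records at or below reference are untouched) unless
    ``clamp_at_reference`` is disabled.  With ``positive_betas_only`` (the
    default, matching BRINDA practice) a negative fitted slope disables that
    term rather than inflating the biomarker.
    """
    v = np.asarray(value, dtype=float)
    c = np.asarray(crp, dtype=float)
    a = np.asarray(agp, dtype=float)
    if np.any(v <= 0) or np.any(c <= 0) or np.any(a <= 0):
        raise ValueError("value, CRP and AGP must all be > 0")
    excess_c = np.log(c) - model.ref_ln_crp
    excess_a = np.log(a) - model.ref_ln_agp
    if clamp_at_reference:
        excess_c = np.maximum(0.0, excess_c)
        excess_a = np.maximum(0.0, excess_a)
    b1, b2 = model.beta_crp, model.beta_agp
    if positive_betas_only:
        b1 = max(0.0, b1)
        b2 = max(0.0, b2)
    return np.exp(np.log(v) - b1 * excess_c - b2 * excess_a)


def body_iron(tfr_mg_l, ferritin_ug_l) -> np.ndarray:
    """Cook's body-iron index in mg/kg.

    The transferrin receptor (assayed in mg/L) is converted to ug/L before
    forming the sTfR/ferritin ratio, per the convention of the original
    derivation.  Negative values denote tissue iron deficiency; the zero
    crossing sits at ratio 10**2.8229.
    """
    t = np.asarray(tfr_mg_l, dtype=float)
    f = np.asarray(ferritin_ug_l, dtype=float)
    if np.any(t <= 0) or np.any(f <= 0):
        raise ValueError("tfr and ferritin must be > 0")
    ratio = (t * 1000.0) / f
    return -(np.log10(ratio) - BODY_IRON_INTERCEPT) / BODY_IRON_SLOPE


def adjust_cohort(
    df: pd.DataFrame,
    altitude_params: AltitudeCorrection | None = None,
    apply_altitude: bool = False,
    clamp_at_reference: bool = True,
    positive_betas_only: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run all corrections over a cohort frame.

    Adds ``ferritin_adj``, ``tfr_adj``, ``body_iron`` and ``hb_adj`` columns
    and returns the augmented frame plus a JSON-serializable fit report.
    ``apply_altitude`` should be enabled only when the hemoglobin column is on
    the raw (pre-altitude-correction) scale.
    """
    df = df.copy()
    report: dict = {"n": int(len(df))}
    models = {}
    for biomarker in ("ferritin", "tfr"):
        model = fit_adjustment_model(
            df[biomarker], df["crp"], df["agp"], biomarker=biomarker
        )
        models[biomarker] = model
        df[f"{biomarker}_adj"] = apply_adjustment(
            df[biomarker], df["crp"], df["agp"], model,
            clamp_at_reference=clamp_at_reference,
            positive_betas_only=positive_betas_only,
        )
        report[biomarker] = {
            "beta_crp": model.beta_crp,
            "beta_agp": model.beta_agp,
            "ref_ln_crp": model.ref_ln_crp,
            "ref_ln_agp": model.ref_ln_agp,
            "n_fit": model.n_fit,
        }
    df["body_iron"] = body_iron(df["tfr_adj"], df["ferritin_adj"])
    if apply_altitude:
        params = altitude_params or AltitudeCorrection()
        df["hb_adj"] = adjust_hb_for_altitude(df["hb"], df["altitude"], params)
        report["altitude"] = {
            "coeff_linear": params.coeff_linear,
            "coeff_quad": params.coeff_quad,
            "altitude_factor": params.altitude_factor,
        }
    else:
        df["hb_adj"] = df["hb"].astype(float)
        report["altitude"] = None
    return df, report
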