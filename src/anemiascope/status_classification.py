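"""Anemia, iron, inflammation and zinc status flags plus cohort prevalences.

Cutoffs (non-pregnant women of reproductive age, WHO conventions):

===========================  =============================  ==============
flag                         rule                           boundary
===========================  =============================  ==============
anemia                       Hb < 120 g/L                   120 -> none
mild anemia                  110 <= Hb < 120 g/L            110 -> mild
moderate anemia              80 <= Hb < 110 g/L             80 -> moderate
severe anemia                Hb < 80 g/L
iron deficiency (ID)         adjusted ferritin < 15 ug/L    15 -> not ID
IDA                          ID and anemia
iron overload                adjusted ferritin > 150 ug/L   150 -> no
functional iron deficit      sTfR >= 8.3 mg/L               8.3 -> deficit
tissue iron deficiency       body iron < 0 mg/kg            0 -> no
acute inflammation           CRP > 5 mg/L (configurable >=) 5 -> no
chronic inflammation         AGP > 1 g/L                    1 -> no
zinc inadequacy              plasma zinc < 10.7 umol/L      10.7 -> no
===========================  =============================  ==============

The inflammation stage combines the fast marker (CRP, raised early in the
incubation stage of an infection) and the slow marker (AGP, raised in late
convalescence): neither -> reference, CRP only -> incubation, both -> early
convalescence, AGP only -> late convalescence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CUTOFFS",
    "SEVERITY_LEVELS",
    "INFLAMMATION_STAGES",
    "StatusProfile",
    "PrevalenceSummary",
    "classify_anemia",
    "classify_iron_status",
    "classify_inflammation",
    "classify_zinc",
    "classify_cohort",
    "summarize_prevalence",
]

#: Centralized cutoff table, so boundary audits can enumerate mechanically.
CUTOFFS = {
    "anemia_hb": 120.0,          # g/L, strict <
    "mild_hb": 110.0,            # g/L, lower bound of mild band (inclusive)
    "moderate_hb": 80.0,         # g/L, lower bound of moderate band (inclusive)
    "iron_deficiency_ferritin": 15.0,   # ug/L, strict < on adjusted ferritin
    "iron_overload_ferritin": 150.0,    # ug/L, strict > on adjusted ferritin
    "functional_deficit_tfr": 8.3,      # mg/L, inclusive >=
    "tissue_deficiency_body_iron": 0.0,  # mg/kg, strict <
    "acute_crp": 5.0,            # mg/L, strict > by default
    "chronic_agp": 1.0,          # g/L, strict >
    "zinc_inadequacy": 10.7,     # umol/L, strict <
}

SEVERITY_LEVELS = ("none", "mild", "moderate", "severe")
INFLAMMATION_STAGES = (
    "reference",
    "incubation",
    "early_convalescence",
    "late_convalescence",
)

BOOLEAN_FLAGS = (
    "anemic",
    "iron_deficient",
    "ida",
    "iron_overload",
    "functional_iron_deficit",
    "tissue_iron_deficient",
    "acute_inflammation",
    "chronic_inflammation",
    "zinc_inadequate",
)


@dataclass(frozen=True)
class StatusProfile:
    """The full set of status flags for one woman."""

    anemia_severity: str
    anemic: bool
    iron_deficient: bool
    ida: bool
    iron_overload: bool
    functional_iron_deficit: bool
    tissue_iron_deficient: bool
    acute_inflammation: bool
    chronic_inflammation: bool
    inflammation_stage: str
    zinc_inadequate: bool

    def __post_init__(self) -> None:
        if self.anemic != (self.anemia_severity != "none"):
            raise ValueError("anemic flag inconsistent with severity")
        if self.ida and not (self.anemic and self.iron_deficient):
            raise ValueError("IDA requires anemia and iron deficiency")
        if self.iron_overload and self.iron_deficient:
            raise ValueError("overload and deficiency are mutually exclusive")


def classify_anemia(hb_adj) -> np.ndarray:
    """Anemia severity from altitude-adjusted hemoglobin in g/L."""
    hb = np.asarray(hb_adj, dtype=float)
    if np.any(hb <= 0):
        raise ValueError("hemoglobin must be > 0 g/L")
    return np.select(
        [hb < CUTOFFS["moderate_hb"], hb < CUTOFFS["mild_hb"], hb < CUTOFFS["anemia_hb"]],
        ["severe", "moderate", "mild"],
        default="none",
    )


def classify_iron_status(
    ferritin_adj, tfr, body_iron_mg_kg, hb_adj
) -> dict[str, np.ndarray]:
    """Iron-status flags from adjusted ferritin, sTfR and the body-iron index."""
    f = np.asarray(ferritin_adj, dtype=float)
    t = np.asarray(tfr, dtype=float)
    bi = np.asarray(body_iron_mg_kg, dtype=float)
    severity = classify_anemia(hb_adj)
    anemic = severity != "none"
    iron_deficient = f < CUTOFFS["iron_deficiency_ferritin"]
    return {
        "iron_deficient": iron_deficient,
        "ida": iron_deficient & anemic,
        "iron_overload": f > CUTOFFS["iron_overload_ferritin"],
        "functional_iron_deficit": t >= CUTOFFS["functional_deficit_tfr"],
        "tissue_iron_deficient": bi < CUTOFFS["tissue_deficiency_body_iron"],
    }


def classify_inflammation(
    crp, agp, crp_inclusive: bool = False
) -> dict[str, np.ndarray]:
    """Acute/chronic inflammation flags and the four-stage classification.

    The acute cutoff is strict (CRP > 5 mg/L) by default; ``crp_inclusive``
    switches to >= 5 for surveys that used the inclusive convention.
    """
    c = np.asarray(crp, dtype=float)
    a = np.asarray(agp, dtype=float)
    if np.any(c <= 0) or np.any(a <= 0):
        raise ValueError("CRP and AGP must be > 0")
    acute = c >= CUTOFFS["acute_crp"] if crp_inclusive else c > CUTOFFS["acute_crp"]
    chronic = a > CUTOFFS["chronic_agp"]
    stage = np.select(
        [acute & chronic, acute, chronic],
        ["early_convalescence", "incubation", "late_convalescence"],
        default="reference",
    )
    return {"acute_inflammation": acute, "chronic_inflammation": chronic,
            "inflammation_stage": stage}


def classify_zinc(zinc_umol_l) -> np.ndarray:
    """Zinc inadequacy: plasma zinc strictly below 10.7 umol/L."""
    z = np.asarray(zinc_umol_l, dtype=float)
    if np.any(z <= 0):
        raise ValueError("plasma zinc must be > 0")
    return z < CUTOFFS["zinc_inadequacy"]


def classify_cohort(df: pd.DataFrame, crp_inclusive: bool = False) -> pd.DataFrame:
    """Append one column per status flag to an adjusted cohort frame.

    Requires the columns produced by ``biomarker_adjustment.adjust_cohort``
    (``hb_adj``, ``ferritin_adj``, ``body_iron``) plus raw ``tfr``, ``crp``,
    ``agp`` and ``zinc``.
    """
    df = df.copy()
    severity = classify_anemia(df["hb_adj"])
    df["anemia_severity"] = severity
    df["anemic"] = severity != "none"
    iron = classify_iron_status(
        df["ferritin_adj"], df["tfr"], df["body_iron"], df["hb_adj"]
    )
    for k, v in iron.items():
        df[k] = v
    inflam = classify_inflammation(df["crp"], df["agp"], crp_inclusive=crp_inclusive)
    for k, v in inflam.items():
        df[k] = v
    df["zinc_inadequate"] = classify_zinc(df["zinc"])
    return df


@dataclass(frozen=True)
class PrevalenceSummary:
    """Counts and percentages of every status flag over one cohort."""

    n: int
    counts: dict[str, int]
    percentages: dict[str, float]

    def to_dict(self) -> dict:
        return {"n": self.n, "counts": self.counts,
                "percentages": self.percentages}

    def to_text(self) -> str:
        lines = [f"Prevalence summary (n = {self.n})", "-" * 42]
        for flag, count in self.counts.items():
            lines.append(
                f"{flag:<28s} {count:>6d}  {self.percentages[flag]:6.1f}%"
            )
        return "\n".join(lines)


def summarize_prevalence(classified: pd.DataFrame) -> PrevalenceSummary:
    """Per-flag counts and percentages; severity bands partition the anemic."""
    if len(classified) == 0:
        raise ValueError("cannot summarize an empty cohort")
    n = len(classified)
    counts: dict[str, int] = {}
    for level in SEVERITY_LEVELS[1:]:
        counts[f"anemia_{level}"] = int(
            (classified["anemia_severity"] == level).sum()
        )
    for flag in BOOLEAN_FLAGS:
        counts[flag] = int(classified[flag].sum())
    for stage in INFLAMMATION_STAGES[1:]:
        counts[f"stage_{stage}"] = int(
            (classified["inflammation_stage"] == stage).sum()
        )
    percentages = {k: 100.0 * v / n for k, v in counts.items()}
    return PrevalenceSummary(n=n, counts=counts, percentages=percentages)
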