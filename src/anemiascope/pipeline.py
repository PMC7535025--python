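"""End-to-end orchestration: generate -> adjust -> classify -> score -> model.

A run is fully described by a :class:`RunConfig`; identical config + seed
produce byte-identical outputs.  Every output file records the seed and a
hash of the configuration so results remain traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association_models as am
from . import biomarker_adjustment as ba
from . import socioeconomic_scores as ses
from . import status_classification as sc
from .synthetic_cohort import (
    BIOMARKER_COLUMNS,
    CohortSpec,
    EffectsHook,
    calibrate_copula,
    default_cohort_spec,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)

logger = logging.getLogger("anemiascope")

REQUIRED_COLUMNS = list(BIOMARKER_COLUMNS) + [
    "altitude", "muac", "age", "gravidity", "education",
] + [f"hfias{i}_{s}" for i in range(1, 10) for s in ("occ", "freq")]

#: Biomarker predictors of the hemoglobin model, log10-transformed.
HB_MODEL_PREDICTORS = [
    "ferritin", "tfr", "hepcidin", "plasma_iron", "zinc", "selenium",
    "crp", "agp",
]

#: Candidate factors of the anemia determinant screen.
ANEMIA_FACTORS = [
    "low_tfr", "low_agp", "low_muac", "illiterate", "young_age",
    "low_zinc", "low_gravidity",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and partial-output manifest."""

    def __init__(self, stage: str, message: str, manifest: list[str]):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one cohort source: ``csv_path`` to read an existing cohort, else
    a synthetic cohort of size ``n`` is generated.
    """

    out_dir: str | Path = "anemiascope_run"
    seed: int = 0
    n: int | None = None
    csv_path: str | Path | None = None
    effects: bool = False
    n_cal: int = 100_000
    apply_altitude: bool = False
    altitude_coefficients: tuple[float, float] = (-0.32, 0.22)
    clamp_at_reference: bool = True
    crp_inclusive: bool = False
    alpha: float = 0.05
    vif_threshold: float = 2.5
    log_level: str = "INFO"

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Paths and summary of one finished run."""

    out_dir: Path
    config_hash: str
    seed: int
    outputs: dict[str, Path] = field(default_factory=dict)
    prevalence: dict = field(default_factory=dict)
    warnings_seen: list[str] = field(default_factory=list)


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = {"seed": config.seed, "config_hash": config.config_hash(),
               **payload}
    path.write_text(json.dumps(payload, indent=1, default=str))


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order, writing outputs under ``config.out_dir``."""
    logging.basicConfig(
        level=config.log_level,
        format="%(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=out, config_hash=config.config_hash(),
                       seed=config.seed)
    manifest: list[str] = []
    caught: list[str] = []

    def stage(name):
        logger.info("stage: %s", name)

    # -- cohort -----------------------------------------------------------
    stage("cohort")
    try:
        if config.csv_path is not None and config.n is not None:
            raise ValueError("give either csv_path or n, not both")
        if config.csv_path is not None:
            cohort = read_cohort_csv(config.csv_path, required=REQUIRED_COLUMNS)
        else:
            spec = default_cohort_spec(
                n=config.n,
                seed=config.seed,
                effects=EffectsHook() if config.effects else None,
            )
            spec.copula = calibrate_copula(
                spec.copula, spec.marginals, n_cal=config.n_cal,
                seed=config.seed,
            )
            cohort = generate_cohort(spec)
        if len(cohort) < 100:
            msg = f"small cohort (n = {len(cohort)}); estimates will be noisy"
            logger.warning(msg)
            caught.append(msg)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError("cohort", str(e), manifest) from e

    # -- adjust -----------------------------------------------------------
    stage("adjust")
    try:
        lin, quad = config.altitude_coefficients
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cohort, fit_report = ba.adjust_cohort(
                cohort,
                altitude_params=ba.AltitudeCorrection(lin, quad),
                apply_altitude=config.apply_altitude,
                clamp_at_reference=config.clamp_at_reference,
            )
        caught += [str(w.message) for w in wlist]
        path = out / "brinda_fit.json"
        _write_json(path, fit_report, config)
        report.outputs["brinda_fit"] = path
        manifest.append(str(path))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("adjust", str(e), manifest) from e

    # -- classify ---------------------------------------------------------
    stage("classify")
    try:
        cohort = sc.classify_cohort(cohort, crp_inclusive=config.crp_inclusive)
        prevalence = sc.summarize_prevalence(cohort)
        report.prevalence = prevalence.to_dict()
        path = out / "prevalence.json"
        _write_json(path, prevalence.to_dict(), config)
        report.outputs["prevalence"] = path
        manifest.append(str(path))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classify", str(e), manifest) from e

    # -- score ------------------------------------------------------------
    stage("score")
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            cohort, score_report = ses.score_cohort(cohort)
        caught += [str(w.message) for w in wlist]
        path = out / "scores.json"
        _write_json(path, score_report, config)
        report.outputs["scores"] = path
        manifest.append(str(path))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("score", str(e), manifest) from e

    # -- model ------------------------------------------------------------
    stage("model")
    try:
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            design = am.transform_predictors(
                cohort[HB_MODEL_PREDICTORS], skewed=HB_MODEL_PREDICTORS
            )
            design, vif_table = am.vif_screen(
                design, threshold=config.vif_threshold
            )
            hb_model = am.fit_hb_model(design, cohort["hb_adj"])
            hb_model.log10_predictors = tuple(design.columns)

            factors = cohort[ANEMIA_FACTORS]
            retained, screen_table = am.bivariate_screen(
                factors, cohort["anemic"], alpha=config.alpha
            )
            anemia_model = None
            if retained:
                anemia_model = am.fit_anemia_model(
                    factors[retained], cohort["anemic"]
                )
        caught += [str(w.message) for w in wlist]
        path = out / "hb_model.json"
        _write_json(path, hb_model.to_dict(), config)
        report.outputs["hb_model"] = path
        manifest.append(str(path))
        path = out / "anemia_model.json"
        _write_json(
            path,
            {
                "screen": screen_table.to_dict(orient="records"),
                "retained": retained,
                "multivariate": anemia_model.to_dict() if anemia_model else None,
            },
            config,
        )
        report.outputs["anemia_model"] = path
        manifest.append(str(path))
        path = out / "vif.json"
        _write_json(path, {"table": vif_table.to_dict(orient="records")}, config)
        report.outputs["vif"] = path
        manifest.append(str(path))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("model", str(e), manifest) from e

    # -- outputs ----------------------------------------------------------
    cohort_path = out / "cohort.csv"
    write_cohort_csv(cohort, cohort_path)
    report.outputs["cohort"] = cohort_path

    text = [
        f"anemiascope run (seed = {config.seed}, "
        f"config = {config.config_hash()})",
        "",
        sc.summarize_prevalence(cohort).to_text(),
        "",
        hb_model.to_text(),
        "",
    ]
    if anemia_model is not None:
        text.append(anemia_model.to_text())
    if caught:
        text += ["", "warnings:"] + [f"  - {m}" for m in caught]
    report_path = out / "report.txt"
    report_path.write_text("\n".join(text) + "\n")
    report.outputs["report"] = report_path
    report.warnings_seen = caught
    return report
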