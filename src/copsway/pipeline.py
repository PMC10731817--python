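"""End-to-end analysis of one force-plate recording.

read → (COP from forces if needed) → preprocess → feature battery →
anthropometric normalization → fidgety-movements classification + MOS-R
estimate → machine-readable report.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from .errors import PredictorDomainError
from .features import (ApEnConfig, CopParameterSet, NormalizationScheme,
                       compute_parameters, normalize_parameters)
from .io import (CopRecording, RawForceRecording, SubjectMeta, cop_from_forces,
                 read_forceplate_csv)
from .models import (FmLogisticModel, MosrLinearModel, fm_classify, mosr_predict)
from .preprocess import PreprocessConfig, preprocess

__all__ = ["AnalysisConfig", "AnalysisReport", "analyze_recording", "run_analysis"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a single analysis needs; defaults reproduce the published
    protocol (50 Hz, 10 Hz fourth-order low-pass, 10 s lead, 170 s window,
    height+weight normalization, classification threshold 0.15)."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    apen: ApEnConfig = field(default_factory=ApEnConfig)
    normalization: NormalizationScheme = field(default_factory=NormalizationScheme)
    fm_model: FmLogisticModel = field(default_factory=FmLogisticModel)
    mosr_model: MosrLinearModel = field(default_factory=MosrLinearModel)
    dialect: str = "cop"
    plate_offset_z: float = 0.0
    fz_min: float = 1.0

    @classmethod
    def from_dict(cls, payload: dict) -> "AnalysisConfig":
        """Build from a nested dict (e.g. parsed YAML/JSON config file)."""
        kwargs: dict[str, Any] = {}
        if "preprocess" in payload:
            kwargs["preprocess"] = PreprocessConfig(**payload["preprocess"])
        if "apen" in payload:
            kwargs["apen"] = ApEnConfig(**payload["apen"])
        if "normalization" in payload:
            kwargs["normalization"] = NormalizationScheme(**payload["normalization"])
        if "fm_model" in payload:
            kwargs["fm_model"] = FmLogisticModel(**payload["fm_model"])
        if "mosr_model" in payload:
            kwargs["mosr_model"] = MosrLinearModel(**payload["mosr_model"])
        for key in ("dialect", "plate_offset_z", "fz_min"):
            if key in payload:
                kwargs[key] = payload[key]
        return cls(**kwargs)


@dataclass
class AnalysisReport:
    """Structured result for one recording, with enough provenance (scheme,
    coefficients, software version) to re-derive every number."""

    subject: dict
    preprocessing: dict
    parameters_raw: dict
    parameters_normalized: dict
    normalization_scheme: str
    classification: dict
    mosr: dict
    model_coefficients: dict
    software_version: str
    model_hash: str
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _flat(params: CopParameterSet) -> dict:
    return {f"{name}_{d}": v for (name, d), v in params.values.items()}


def _model_hash(cfg: AnalysisConfig) -> str:
    blob = repr((cfg.fm_model, cfg.mosr_model)).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def analyze_recording(
    rec: CopRecording, cfg: AnalysisConfig | None = None
) -> AnalysisReport:
    """Analyze an in-memory COP recording (see :func:`run_analysis` for the
    file-based entry point)."""
    cfg = cfg or AnalysisConfig()
    flags: list[str] = []
    processed = preprocess(rec, cfg.preprocess)
    raw_params = compute_parameters(processed, cfg.apen)
    norm_params = normalize_parameters(raw_params, cfg.normalization)
    outcome = fm_classify(norm_params, cfg.fm_model)
    flags.extend(outcome.warnings)

    try:
        mosr = mosr_predict(
            norm_params.get("instantaneous_velocity_std", "R"),
            norm_params.get("instantaneous_velocity_skewness", "R"),
            norm_params.get("approximate_entropy", "R"),
            cfg.mosr_model,
        )
        if mosr["clamp_applied"]:
            flags.append("mosr_estimate clamped to the legal score range")
    except PredictorDomainError as exc:
        # a negative skewness makes the log-linear estimate undefined; the
        # classification is still reported
        mosr = {"mosr_estimate": None, "log_prediction": None,
                "domain_error": str(exc)}
        flags.append(f"mosr_estimate unavailable: predictor {exc.name} out of domain")
    if raw_params.degenerate_ellipse:
        flags.append("degenerate planar covariance: ellipse area reported as 0")

    return AnalysisReport(
        subject={
            "id": rec.subject.id,
            "height_cm": rec.subject.height,
            "weight_g": rec.subject.weight,
            "post_term_age_weeks": rec.subject.post_term_age,
            "group_label": rec.subject.group_label,
        },
        preprocessing={
            "samples_analyzed": len(processed),
            "fs": processed.fs,
            "cutoff_hz": cfg.preprocess.cutoff,
            "filter_order": cfg.preprocess.order,
            "zero_phase": cfg.preprocess.zero_phase,
            "trim_lead_s": cfg.preprocess.trim_lead,
            "analysis_window_s": cfg.preprocess.analysis_window,
            "valid_fraction": rec.valid_fraction,
        },
        parameters_raw=_flat(raw_params),
        parameters_normalized=_flat(norm_params),
        normalization_scheme=cfg.normalization.kind,
        classification={
            "probability_absent_fm": outcome.probability,
            "label": outcome.label,
            "threshold": cfg.fm_model.threshold,
            "predictors_used": outcome.predictors_used,
        },
        mosr=mosr,
        model_coefficients={
            "fm": asdict(cfg.fm_model),
            "mosr": asdict(cfg.mosr_model),
        },
        software_version=__version__,
        model_hash=_model_hash(cfg),
        flags=flags,
    )


def run_analysis(
    input_path: str | Path,
    cfg: AnalysisConfig | None = None,
    subject: SubjectMeta | None = None,
) -> AnalysisReport:
    """File-based pipeline entry: read one recording and analyze it."""
    cfg = cfg or AnalysisConfig()
    rec = read_forceplate_csv(
        input_path, dialect=cfg.dialect,
        fs_declared=cfg.preprocess.expected_fs, subject=subject,
    )
    if isinstance(rec, RawForceRecording):
        rec = cop_from_forces(rec, cfg.plate_offset_z, cfg.fz_min)
    return analyze_recording(rec, cfg)
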