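"""End-to-end pipeline: QC -> segmentation -> purity/ploidy fit -> scars -> call.

Mirrors the result page a reporting platform would show for one sample:
QC metrics, the fitted purity/ploidy, the three scar counts with the total
GIS score both raw and calibrated, and the HRD call.  The report is
self-contained and deterministic: re-running with the same inputs and
configuration reproduces it bit-identically (no timestamps inside).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .ascn import FitConfig, PloidyFit, fit_profile, grid_search
from .calibration import (
    CalibrationModel,
    ClassificationConfig,
    apply_calibration,
    classify_hrd,
    display_score,
)
from .genome import GenomeBuild, load_genome
from .scars import ScarConfig, gis_score
from .segmentation import SegmentationConfig, segment_track
from .tracks import (
    ProbeTrack,
    QCMetrics,
    QCThresholds,
    SegmentProfile,
    mapd,
    qc_gate,
    read_probe_track,
)

__all__ = ["RunReport", "QCFailure", "NonIdentifiableFit", "run_pipeline"]


class QCFailure(RuntimeError):
    """Track failed the QC gate and scoring was not forced."""

    def __init__(self, qc: QCMetrics):
        super().__init__("; ".join(qc.reasons) or "QC failed")
        self.qc = qc


class NonIdentifiableFit(RuntimeError):
    """Purity/ploidy surface has no usable minimum and none was fixed."""


@dataclass
class RunReport:
    sample: str
    qc: dict
    fit: dict
    scars: dict
    raw_gis: int
    corrected_gis: float | None = None
    corrected_gis_display: int | None = None
    hrd_call: str | None = None
    version: str = __version__
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "qc": self.qc,
            "fit": self.fit,
            "scars": self.scars,
            "gis": {
                "raw": self.raw_gis,
                "corrected": self.corrected_gis,
                "corrected_display": self.corrected_gis_display,
                "hrd_call": self.hrd_call,
            },
            "version": self.version,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def run_pipeline(
    probes: ProbeTrack | str | Path,
    sex: str = "XX",
    tumor_content: float | None = None,
    model: CalibrationModel | None = None,
    genome: GenomeBuild | None = None,
    nd_snp_qc: float | None = None,
    sample: str = "sample",
    seg_config: SegmentationConfig | None = None,
    fit_config: FitConfig | None = None,
    scar_config: ScarConfig | None = None,
    qc_thresholds: QCThresholds | None = None,
    class_config: ClassificationConfig | None = None,
    fix_rho: float | None = None,
    fix_psi: float | None = None,
    force: bool = False,
) -> tuple[RunReport, "SegmentProfile"]:
    """Score one sample from its probe track.

    QC is evaluated first and aborts scoring on failure unless ``force``;
    a non-identifiable purity/ploidy fit aborts unless (rho, psi) are
    user-fixed.  When a calibration model is supplied the corrected score
    and the HRD call (>= 42) are included.
    """
    if not isinstance(probes, ProbeTrack):
        probes = read_probe_track(probes, sex=sex)
    if genome is None:
        genome = load_genome("hg19")
    seg_config = seg_config or SegmentationConfig()
    fit_config = fit_config or FitConfig(pathology_tumor_content=tumor_content)
    scar_config = scar_config or ScarConfig()
    class_config = class_config or ClassificationConfig()

    qc = qc_gate(QCMetrics(mapd=mapd(probes), nd_snp_qc=nd_snp_qc),
                 qc_thresholds or QCThresholds())
    if not qc.passed and not force:
        raise QCFailure(qc)

    raw = segment_track(probes, seg_config)
    if fix_rho is not None and fix_psi is not None:
        fit = PloidyFit.fixed(fix_rho, fix_psi, fit_config.gamma)
    else:
        fit = grid_search(raw, fit_config)
        if not fit.identifiable:
            raise NonIdentifiableFit(
                "purity/ploidy not identifiable; re-run with fixed rho/psi"
            )
    profile = fit_profile(raw, fit, genome)
    scars = gis_score(profile, genome, scar_config)

    corrected = corrected_disp = call = None
    if model is not None:
        corrected = apply_calibration(scars.gis, model)
        corrected_disp = display_score(corrected)
        call = classify_hrd(corrected, class_config)

    return RunReport(
        sample=sample,
        qc=qc.to_dict(),
        fit=fit.to_dict(),
        scars=scars.to_dict(),
        raw_gis=scars.gis,
        corrected_gis=corrected,
        corrected_gis_display=corrected_disp,
        hrd_call=call,
        config={
            "segmentation": {
                "penalty": seg_config.penalty,
                "min_probes_per_segment": seg_config.min_probes_per_segment,
            },
            "fit": {
                "gamma": fit_config.gamma,
                "pathology_tumor_content": fit_config.pathology_tumor_content,
            },
            "scars": {
                "loh_min_len": scar_config.loh_min_len,
                "lst_min_seg": scar_config.lst_min_seg,
                "lst_smooth": scar_config.lst_smooth,
                "tai_min_len": scar_config.tai_min_len,
            },
            "threshold": class_config.threshold,
            "sex": sex,
        },
    ), profile


# run_pipeline returns (report, profile); keep a simple alias for report-only use
def score_sample(*args, **kwargs) -> RunReport:
    report, _ = run_pipeline(*args, **kwargs)
    return report
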