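"""Probe tracks, allele-specific segment profiles, and array QC.

The two substrates of the pipeline live here: the per-probe LogR/BAF track
(what a SNP array measures) and the allele-specific copy-number segment
profile (what scar scoring consumes).  Both are thin, validated wrappers
around pandas DataFrames with TSV readers/writers; the QC metric MAPD and
the pass/fail gate that decides whether a track may be scored are also
implemented here.

Disk convention: all TSV coordinates are 1-based inclusive; in memory they
are 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import CHROM_ORDER

__all__ = [
    "ProbeTrack",
    "SegmentProfile",
    "QCMetrics",
    "QCThresholds",
    "read_probe_track",
    "write_probe_track",
    "read_segment_profile",
    "write_segment_profile",
    "mapd",
    "qc_gate",
]

PROBE_COLUMNS = ["probe_id", "chrom", "pos", "logr", "baf", "informative"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "n_major", "n_minor"]


def _chrom_sort_key(chroms: pd.Series) -> pd.Series:
    order = {c: i for i, c in enumerate(CHROM_ORDER)}
    return chroms.map(lambda c: order.get(c, len(order)))


@dataclass
class ProbeTrack:
    """Per-probe LogR and B-allele-frequency observations.

    ``informative`` flags germline-heterozygous SNP probes: only those carry
    allelic-imbalance information, homozygous probes have BAF pinned near
    0 or 1 regardless of tumor copy state.
    """

    probes: pd.DataFrame
    sex: str = "XX"

    def __post_init__(self) -> None:
        df = self.probes
        missing = set(PROBE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"probe track missing columns {sorted(missing)}")
        if self.sex not in ("XX", "XY"):
            raise ValueError(f"sex must be 'XX' or 'XY', got {self.sex!r}")
        df = df[PROBE_COLUMNS].copy()
        for col in ("pos", "logr", "baf"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        df["pos"] = df["pos"].astype(np.int64)
        df["informative"] = df["informative"].astype(bool)
        if not np.isfinite(df["logr"]).all():
            raise ValueError("non-finite logr values")
        if ((df["baf"] < 0) | (df["baf"] > 1)).any():
            raise ValueError("baf values outside [0, 1]")
        df = df.sort_values(
            ["chrom", "pos"], key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (np.diff(sub["pos"].to_numpy()) <= 0).any():
                raise ValueError(f"duplicate or non-increasing positions on {chrom}")
        self.probes = df

    def __len__(self) -> int:
        return len(self.probes)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.probes["chrom"]))


@dataclass
class SegmentProfile:
    """Ordered allele-specific copy-number segments (n_major >= n_minor >= 0)."""

    segments: pd.DataFrame
    sample_sex: str = "XX"

    def __post_init__(self) -> None:
        df = self.segments
        missing = set(SEGMENT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"segment profile missing columns {sorted(missing)}")
        if self.sample_sex not in ("XX", "XY"):
            raise ValueError(f"sex must be 'XX' or 'XY', got {self.sample_sex!r}")
        df = df[SEGMENT_COLUMNS].copy()
        for col in ("start", "end", "n_major", "n_minor"):
            df[col] = pd.to_numeric(df[col], errors="raise").astype(np.int64)
        if (df["n_minor"] < 0).any():
            raise ValueError("negative copy number")
        if (df["n_major"] < df["n_minor"]).any():
            raise ValueError("n_minor > n_major")
        if (df["start"] >= df["end"]).any():
            raise ValueError("segment with start >= end")
        df = df.sort_values(
            ["chrom", "start"], key=lambda s: _chrom_sort_key(s) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom", sort=False):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments on {chrom}")
        self.segments = df

    def __len__(self) -> int:
        return len(self.segments)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.segments["chrom"]))


def read_probe_track(path: str | Path, sex: str = "XX") -> ProbeTrack:
    df = pd.read_csv(path, sep="\t")
    return ProbeTrack(probes=df, sex=sex)


def write_probe_track(track: ProbeTrack, path: str | Path) -> None:
    track.probes.to_csv(path, sep="\t", index=False)


def read_segment_profile(path: str | Path, sex: str = "XX") -> SegmentProfile:
    df = pd.read_csv(path, sep="\t")
    if {"start", "end"} <= set(df.columns):
        df = df.copy()
        df["start"] = pd.to_numeric(df["start"]) - 1  # 1-based inclusive -> 0-based half-open
    return SegmentProfile(segments=df, sample_sex=sex)


def write_segment_profile(
    profile: SegmentProfile,
    path: str | Path,
    seg_path: str | Path | None = None,
    sample: str = "sample",
) -> None:
    """Write the native allele-specific table and, optionally, a SEG file.

    The SEG file carries total copy number as ``seg.mean = log2(total/2)``;
    homozygous deletions (total 0) are floored at total 0.01 to keep the
    value finite.
    """
    out = profile.segments.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)
    if seg_path is not None:
        total = (profile.segments["n_major"] + profile.segments["n_minor"]).astype(float)
        seg = pd.DataFrame(
            {
                "sample": sample,
                "chrom": profile.segments["chrom"],
                "loc.start": profile.segments["start"] + 1,
                "loc.end": profile.segments["end"],
                "num.mark": 0,
                "seg.mean": np.log2(np.maximum(total, 0.01) / 2.0),
            }
        )
        seg.to_csv(seg_path, sep="\t", index=False)


def mapd(track: ProbeTrack) -> float:
    """Median of |LogR[i+1] - LogR[i]| over consecutive same-chromosome pairs.

    The standard array noise metric: chromosome boundaries contribute no
    pair, so real copy-number jumps between chromosomes are not counted as
    noise.  Invariant under adding a constant to all LogR values and scales
    linearly with the LogR scale.
    """
    diffs: list[np.ndarray] = []
    for _, sub in track.probes.groupby("chrom", sort=False):
        v = sub["logr"].to_numpy()
        if len(v) >= 2:
            diffs.append(np.abs(np.diff(v)))
    if not diffs:
        raise ValueError("MAPD needs at least one chromosome with >= 2 probes")
    return float(np.median(np.concatenate(diffs)))


@dataclass(frozen=True)
class QCThresholds:
    """Gate thresholds; comparisons are inclusive (pass at the boundary)."""

    mapd_max: float = 0.30
    nd_snp_qc_min: float = 26.0


@dataclass
class QCMetrics:
    """Array QC metrics and the gate outcome.

    ``nd_snp_qc`` (the vendor's normal-diploid-marker SNP quality metric) is
    a pass-through value supplied externally; when absent the gate judges
    MAPD alone.
    """

    mapd: float
    nd_snp_qc: float | None = None
    passed: bool | None = None
    reasons: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mapd": self.mapd,
            "nd_snp_qc": self.nd_snp_qc,
            "pass": self.passed,
            "reasons": list(self.reasons),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def qc_gate(metrics: QCMetrics, thresholds: QCThresholds = QCThresholds()) -> QCMetrics:
    """Apply the pass/fail gate: MAPD <= 0.30 and (if supplied) ndSNPQC >= 26.

    Returns a new QCMetrics with ``passed`` set and every violated rule
    listed in ``reasons``.
    """
    if metrics.mapd < 0:
        raise ValueError("mapd must be >= 0")
    reasons = []
    if metrics.mapd > thresholds.mapd_max:
        reasons.append(f"MAPD {metrics.mapd:g} > {thresholds.mapd_max:g}")
    if metrics.nd_snp_qc is not None and metrics.nd_snp_qc < thresholds.nd_snp_qc_min:
        reasons.append(f"ndSNPQC {metrics.nd_snp_qc:g} < {thresholds.nd_snp_qc_min:g}")
    return QCMetrics(
        mapd=metrics.mapd,
        nd_snp_qc=metrics.nd_snp_qc,
        passed=not reasons,
        reasons=reasons,
    )
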