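"""Genomic-instability scar counting: LOH, LST, TAI, and the GIS score.

Three classes of structural scar are counted on an integer allele-specific
copy-number profile; their sum is the genomic instability score (GIS), and
a sample is HRD-positive when its (calibrated) GIS reaches 42.

LOH  — loss of heterozygosity: maximal runs with minor copy number 0 (and
       at least one remaining copy) longer than 15 Mb that do not span the
       whole chromosome.  Homozygous deletions do not interrupt a run but
       add no length; probe-coverage gaps under 3 Mb are bridged.
LST  — large-scale state transition: per chromosome arm, after iteratively
       removing segments shorter than 3 Mb (merging flanks that share a
       state), a change of allele-specific state between two segments each
       at least 10 Mb long with under 3 Mb between them.
TAI  — telomeric allelic imbalance: a maximal allelic-imbalance run
       (n_major != n_minor) that reaches a chromosome end, does not cross
       the centromere, and does not span the whole chromosome.

Whole-chromosome events are excluded from LOH and TAI (config-switchable),
and LST never crosses the centromere by construction — both conventions
come from the scar literature the score is built on.  Chromosome X is
scored for every sample; Y only for XY samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeBuild
from .tracks import SegmentProfile

__all__ = ["ScarConfig", "ScarResult", "count_loh", "count_lst", "count_tai", "gis_score"]

MB = 1_000_000


@dataclass(frozen=True)
class ScarConfig:
    loh_min_len: int = 15 * MB      # strict ">" per the LOH definition
    lst_min_seg: int = 10 * MB      # inclusive ">=" (minimum size)
    lst_smooth: int = 3 * MB        # also the LOH gap-bridging threshold
    tai_min_len: int = 0
    exclude_whole_chromosome: bool = True
    score_x: bool = True

    def __post_init__(self) -> None:
        if min(self.loh_min_len, self.lst_min_seg, self.lst_smooth, self.tai_min_len) < 0:
            raise ValueError("scar length thresholds must be >= 0")
        if self.lst_smooth >= self.lst_min_seg:
            raise ValueError("lst_smooth must be < lst_min_seg")


@dataclass
class ScarResult:
    loh: int
    lst: int
    tai: int
    loh_events: list[dict] = field(default_factory=list)
    lst_events: list[dict] = field(default_factory=list)
    tai_events: list[dict] = field(default_factory=list)

    @property
    def gis(self) -> int:
        return self.loh + self.lst + self.tai

    def to_dict(self) -> dict:
        return {
            "loh": self.loh,
            "lst": self.lst,
            "tai": self.tai,
            "gis": self.gis,
            "events": {
                "loh": self.loh_events,
                "lst": self.lst_events,
                "tai": self.tai_events,
            },
        }


def _scored_chromosomes(profile: SegmentProfile, config: ScarConfig) -> list[str]:
    out = []
    for chrom in profile.chromosomes():
        if chrom == "chrY" and profile.sample_sex != "XY":
            continue
        if chrom == "chrX" and not config.score_x:
            continue
        out.append(chrom)
    return out


def _chrom_rows(profile: SegmentProfile, chrom: str) -> pd.DataFrame:
    return profile.segments[profile.segments["chrom"] == chrom].reset_index(drop=True)


def count_loh(
    profile: SegmentProfile, genome: GenomeBuild, config: ScarConfig = ScarConfig()
) -> tuple[int, list[dict]]:
    """Count qualifying loss-of-heterozygosity regions (> loh_min_len)."""
    events: list[dict] = []
    for chrom in _scored_chromosomes(profile, config):
        rows = _chrom_rows(profile, chrom)
        covered_lo = int(rows["start"].min())
        covered_hi = int(rows["end"].max())
        runs: list[dict] = []
        cur: dict | None = None
        prev_end: int | None = None
        for seg in rows.itertuples(index=False):
            gap = seg.start - prev_end if prev_end is not None else 0
            is_loh = seg.n_minor == 0 and seg.n_major >= 1
            is_homdel = seg.n_major == 0 and seg.n_minor == 0
            breaks = gap >= config.lst_smooth  # unbridgeable coverage gap
            if is_loh:
                if cur is None or breaks:
                    cur = {"chrom": chrom, "start": int(seg.start), "end": int(seg.end),
                           "length": 0}
                    runs.append(cur)
                cur["end"] = int(seg.end)
                cur["length"] += int(seg.end - seg.start)
            elif is_homdel and not breaks:
                pass  # does not interrupt, contributes no length
            else:
                cur = None
            prev_end = int(seg.end)
        for run in runs:
            whole = run["start"] <= covered_lo and run["end"] >= covered_hi
            if run["length"] > config.loh_min_len and not (
                whole and config.exclude_whole_chromosome
            ):
                events.append(run)
    return len(events), events


def _clip_to_arm(rows: pd.DataFrame, lo: int, hi: int) -> list[dict]:
    out = []
    for seg in rows.itertuples(index=False):
        s, e = max(seg.start, lo), min(seg.end, hi)
        if s < e:
            out.append({"start": int(s), "end": int(e),
                        "state": (int(seg.n_major), int(seg.n_minor))})
    return out


def _smooth_arm(segs: list[dict], min_len: int) -> list[dict]:
    """Iteratively drop sub-min_len segments, merging equal-state flanks."""
    segs = [dict(s) for s in segs]
    while True:
        short = [i for i, s in enumerate(segs) if s["end"] - s["start"] < min_len]
        if not short:
            return segs
        # drop the shortest first for a deterministic, order-free result
        i = min(short, key=lambda k: (segs[k]["end"] - segs[k]["start"], k))
        del segs[i]
        if 0 < i < len(segs) and segs[i - 1]["state"] == segs[i]["state"]:
            segs[i - 1]["end"] = segs[i]["end"]
            del segs[i]


def count_lst(
    profile: SegmentProfile, genome: GenomeBuild, config: ScarConfig = ScarConfig()
) -> tuple[int, list[dict]]:
    """Count large-scale state transitions per chromosome arm."""
    events: list[dict] = []
    for chrom in _scored_chromosomes(profile, config):
        rows = _chrom_rows(profile, chrom)
        c = genome.chromosome(chrom)
        for arm, (lo, hi) in (("p", c.p_arm), ("q", c.q_arm)):
            segs = _smooth_arm(_clip_to_arm(rows, lo, hi), config.lst_smooth)
            for a, b in zip(segs[:-1], segs[1:]):
                if (
                    a["state"] != b["state"]
                    and a["end"] - a["start"] >= config.lst_min_seg
                    and b["end"] - b["start"] >= config.lst_min_seg
                    and b["start"] - a["end"] < config.lst_smooth
                ):
                    events.append({"chrom": chrom, "arm": arm, "pos": int(a["end"]),
                                   "left_state": list(a["state"]),
                                   "right_state": list(b["state"])})
    return len(events), events


def count_tai(
    profile: SegmentProfile, genome: GenomeBuild, config: ScarConfig = ScarConfig()
) -> tuple[int, list[dict]]:
    """Count telomeric allelic-imbalance regions."""
    events: list[dict] = []
    for chrom in _scored_chromosomes(profile, config):
        rows = _chrom_rows(profile, chrom)
        c = genome.chromosome(chrom)
        covered_lo = int(rows["start"].min())
        covered_hi = int(rows["end"].max())
        # maximal runs of equal imbalance status over consecutive segments
        runs: list[dict] = []
        for seg in rows.itertuples(index=False):
            imb = seg.n_major != seg.n_minor
            if runs and runs[-1]["imbalanced"] == imb:
                runs[-1]["end"] = int(seg.end)
            else:
                runs.append({"chrom": chrom, "start": int(seg.start),
                             "end": int(seg.end), "imbalanced": imb})
        for run in runs:
            if not run["imbalanced"]:
                continue
            touches_start = run["start"] <= covered_lo
            touches_end = run["end"] >= covered_hi
            whole = touches_start and touches_end
            crosses_cen = run["start"] < c.centromere_start and run["end"] > c.centromere_end
            if (
                (touches_start or touches_end)
                and not crosses_cen
                and run["end"] - run["start"] >= config.tai_min_len
                and not (whole and config.exclude_whole_chromosome)
            ):
                events.append({k: run[k] for k in ("chrom", "start", "end")})
    return len(events), events


def gis_score(
    profile: SegmentProfile, genome: GenomeBuild, config: ScarConfig = ScarConfig()
) -> ScarResult:
    """The genomic instability score: GIS = LOH + LST + TAI."""
    n_loh, loh_ev = count_loh(profile, genome, config)
    n_lst, lst_ev = count_lst(profile, genome, config)
    n_tai, tai_ev = count_tai(profile, genome, config)
    return ScarResult(
        loh=n_loh, lst=n_lst, tai=n_tai,
        loh_events=loh_ev, lst_events=lst_ev, tai_events=tai_ev,
    )
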