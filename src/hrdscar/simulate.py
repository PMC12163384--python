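"""Synthetic tumor genomes with known purity, ploidy, and scar counts.

Real input to the scoring pipeline is a proprietary SNP-array export; this
module replaces it with a forward model that is the exact algebraic inverse
of the copy-number equations the fit stage inverts, so every downstream
stage can be tested against ground truth.

A simulated sample is a clonal tumor: a constant-ploidy baseline with a
chosen number of qualifying LOH, LST and TAI events injected, then rendered
to a per-probe LogR/BAF track at fixed probe spacing with Gaussian noise.

Event geometry is constructed so each injected event scores as exactly one
event of its own type and nothing else:

* every event owns a whole chromosome (so events are far apart and never
  share an arm across types);
* LOH runs sit in an arm interior, >= 3.5 Mb probe-coverage gaps on both
  sides — a state change across a >= 3 Mb gap is not an LST, and an
  interior run is not telomeric;
* LST events are a single contiguous state transition with both flanks
  >= 11 Mb, terminated on the telomere side by a coverage gap before a
  baseline tail (so the altered block never reaches the telomere);
* TAI events are telomere-touching imbalance blocks separated from the arm
  body by a coverage gap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild
from .tracks import ProbeTrack, SegmentProfile

__all__ = ["SimConfig", "SimTruth", "inject_scars", "render_probes", "simulate_sample"]

MB = 1_000_000
_GAP = int(3.5 * MB)      # coverage gap isolating events from the LST rule
_MARGIN = 5 * MB          # clearance kept between events and arm boundaries


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults describe a typical FFPE ovarian specimen on a whole-genome SNP
    array: 60% tumor content (above the 20% acceptance minimum), diploid
    baseline, ~100 kb probe spacing, LogR noise 0.12 (safely inside the
    MAPD <= 0.30 gate), BAF noise 0.03, a quarter of probes
    germline-heterozygous.
    """

    seed: int = 0
    sex: str = "XX"
    rho: float = 0.6
    psi_base: float = 2.0
    n_loh: int = 3
    n_lst: int = 5
    n_tai: int = 2
    probe_spacing: int = 100_000
    sigma_logr: float = 0.12
    sigma_baf: float = 0.03
    het_fraction: float = 0.25
    gamma: float = 0.55

    def __post_init__(self) -> None:
        if not 0 < self.rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        if min(self.n_loh, self.n_lst, self.n_tai) < 0:
            raise ValueError("event counts must be >= 0")
        if self.probe_spacing <= 0:
            raise ValueError("probe_spacing must be > 0")
        if self.sigma_logr < 0 or self.sigma_baf < 0:
            raise ValueError("noise sds must be >= 0")
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be 'XX' or 'XY'")


@dataclass
class SimTruth:
    """Ground truth: the profile, the mixture parameters, the event table."""

    profile: SegmentProfile
    rho: float
    psi: float
    gamma: float
    events: dict[str, list[dict]] = field(default_factory=dict)


def _base_state(psi_base: float) -> tuple[int, int]:
    total = int(round(psi_base))
    if total < 1 or abs(psi_base - total) > 1e-9:
        raise ValueError("psi_base must be a positive integer ploidy (1, 2 or 4)")
    return ((total + 1) // 2, total // 2)


# minimum arm length needed to host one event of each type
_MIN_ARM = {"loh": 60 * MB, "lst": 40 * MB, "tai": 45 * MB}


def _carve(pieces: list[tuple[int, int, tuple[int, int]]],
           cut_lo: int, cut_hi: int,
           insert: tuple[int, int, tuple[int, int]] | None):
    """Remove [cut_lo, cut_hi) from coverage, optionally inserting a piece."""
    out = []
    for s, e, st in pieces:
        if e <= cut_lo or s >= cut_hi:
            out.append((s, e, st))
            continue
        if s < cut_lo:
            out.append((s, cut_lo, st))
        if e > cut_hi:
            out.append((cut_hi, e, st))
    if insert is not None:
        out.append(insert)
    out.sort()
    return out


def inject_scars(genome: GenomeBuild, config: SimConfig) -> SimTruth:
    """Build a truth profile with exactly the requested scar counts."""
    rng = np.random.default_rng([config.seed, 0])
    base = _base_state(config.psi_base)

    chrom_tables = {c.chrom: c for c in genome.chromosomes}
    chroms = [c for c in chrom_tables if c != "chrY" or config.sex == "XY"]
    # sex chromosomes of an XY sample are haploid and host no events
    haploid = {"chrX", "chrY"} if config.sex == "XY" else set()
    # one event per chromosome arm; arm-boundary margins keep events on
    # opposite arms of one chromosome > 20 Mb apart
    arm_pool = [
        (c, lo, hi)
        for c in chroms
        if c not in haploid
        for lo, hi in (chrom_tables[c].p_arm, chrom_tables[c].q_arm)
    ]
    arm_pool = [arm_pool[i] for i in rng.permutation(len(arm_pool))]

    pieces: dict[str, list] = {}
    for c in chroms:
        st = (1, 0) if c in haploid else base
        pieces[c] = [(0, chrom_tables[c].length, st)]

    events: dict[str, list[dict]] = {"loh": [], "lst": [], "tai": []}
    plan = [("loh", config.n_loh), ("lst", config.n_lst), ("tai", config.n_tai)]
    used: set[tuple[str, int, int]] = set()

    def _take_arm(kind: str) -> tuple[str, int, int]:
        need = _MIN_ARM[kind]
        for key in arm_pool:
            c, lo, hi = key
            if key in used or hi - lo < need:
                continue
            used.add(key)
            return c, lo, hi
        raise ValueError(
            f"cannot place requested events: no free chromosome arm >= "
            f"{need // MB} Mb for a {kind} event"
        )

    def _alt_state(kind: str) -> tuple[int, int]:
        ma, mi = base
        if kind == "loh":
            return (int(rng.integers(1, 3)), 0) if base == (1, 1) else (ma, 0)
        return (ma + 1, mi)  # unbalanced gain, minor copy retained

    for kind, count in plan:
        for _ in range(count):
            chrom, lo, hi = _take_arm(kind)
            L = chrom_tables[chrom].length
            telo_is_hi = hi == L  # q arm reaches the chromosome's right end
            state = _alt_state(kind)
            if kind == "loh":
                length = int(rng.integers(16 * MB, 40 * MB + 1))
                margin = int(6.5 * MB)  # keeps arm-boundary clearance > 20 Mb pairwise
                x = int(rng.integers(lo + margin + _GAP, hi - margin - _GAP - length + 1))
                pieces[chrom] = _carve(
                    pieces[chrom], x - _GAP, x + length + _GAP, (x, x + length, state)
                )
                events["loh"].append({"chrom": chrom, "start": x, "end": x + length})
            elif kind == "lst":
                blen = int(rng.integers(11 * MB, 20 * MB + 1))
                if telo_is_hi:  # flank on centromere side, gap+tail toward telomere
                    x = int(rng.integers(lo + 11 * MB, hi - _MARGIN - _GAP - blen + 1))
                    pieces[chrom] = _carve(
                        pieces[chrom], x, x + blen + _GAP, (x, x + blen, state)
                    )
                    bp = x
                else:
                    x = int(rng.integers(lo + _MARGIN + _GAP, hi - 11 * MB - blen + 1))
                    pieces[chrom] = _carve(
                        pieces[chrom], x - _GAP, x + blen, (x, x + blen, state)
                    )
                    bp = x + blen
                events["lst"].append({"chrom": chrom, "pos": bp})
            else:  # tai
                length = int(rng.integers(5 * MB, 30 * MB + 1))
                if telo_is_hi:
                    s, e = L - length, L
                    pieces[chrom] = _carve(pieces[chrom], s - _GAP, e, (s, e, state))
                else:
                    s, e = 0, length
                    pieces[chrom] = _carve(pieces[chrom], s, e + _GAP, (s, e, state))
                events["tai"].append({"chrom": chrom, "start": s, "end": e})

    rows = [
        {"chrom": c, "start": s, "end": e, "n_major": st[0], "n_minor": st[1]}
        for c in chroms
        for s, e, st in pieces[c]
    ]
    profile = SegmentProfile(segments=pd.DataFrame(rows), sample_sex=config.sex)
    return SimTruth(
        profile=profile, rho=config.rho, psi=config.psi_base,
        gamma=config.gamma, events=events,
    )


def render_probes(truth: SimTruth, config: SimConfig) -> ProbeTrack:
    """Render the truth profile to a noisy per-probe LogR/BAF track.

    Expected values follow the clonal mixture model (see the purity/ploidy
    module); Gaussian noise is added with the configured sds and BAF is
    clipped to [0, 1].  Non-informative probes are homozygous germline
    genotypes (BAF near 0 or 1).
    """
    rng = np.random.default_rng([config.seed, 1])
    rho, psi, gamma = truth.rho, truth.psi, truth.gamma
    d_ref = 2.0 * (1.0 - rho) + rho * psi

    frames = []
    for seg in truth.profile.segments.itertuples(index=False):
        half = config.probe_spacing // 2
        k0 = math.ceil((seg.start - half) / config.probe_spacing)
        k1 = math.floor((seg.end - 1 - half) / config.probe_spacing)
        if k1 < k0:
            continue
        pos = np.arange(k0, k1 + 1, dtype=np.int64) * config.probe_spacing + half
        n = len(pos)
        if n == 0:
            continue
        total = max(2.0 * (1.0 - rho) + rho * (seg.n_major + seg.n_minor), 0.05)
        logr = gamma * np.log2(total / d_ref) + rng.normal(0.0, config.sigma_logr, n)
        informative = rng.random(n) < config.het_fraction
        b_is_major = rng.random(n) < 0.5
        n_b = np.where(b_is_major, seg.n_major, seg.n_minor)
        baf_het = ((1.0 - rho) + rho * n_b) / total
        baf_hom = (rng.random(n) < 0.5).astype(float)  # germline AA or BB
        baf = np.where(informative, baf_het, baf_hom)
        baf = np.clip(baf + rng.normal(0.0, config.sigma_baf, n), 0.0, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{seg.chrom}_{p}" for p in pos],
                    "chrom": seg.chrom,
                    "pos": pos,
                    "logr": logr,
                    "baf": baf,
                    "informative": informative,
                }
            )
        )
    return ProbeTrack(probes=pd.concat(frames, ignore_index=True), sex=config.sex)


def simulate_sample(genome: GenomeBuild, config: SimConfig) -> tuple[SimTruth, ProbeTrack]:
    """Convenience wrapper: truth profile plus its rendered probe track."""
    truth = inject_scars(genome, config)
    return truth, render_probes(truth, config)
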