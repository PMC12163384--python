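"""Joint piecewise-constant segmentation of LogR and mirrored BAF.

Allele-specific segmentation sits between the raw probe track and the
purity/ploidy fit: it partitions each chromosome into runs of probes over
which both the total-intensity signal (LogR) and the allelic-imbalance
signal (mirrored BAF) are constant.  The model is penalised least squares:

    cost = sum_segments [ SSE_logr / sigma_r^2 + SSE_mbaf / sigma_b^2 ]
           + penalty * (number of breakpoints)

minimised exactly, per chromosome, by dynamic programming over breakpoint
positions.  Residuals are normalised by robust per-track noise estimates
(median absolute successive difference, floored) so that the penalty lives
on a BIC-like scale independent of array noise; the default penalty is 70.

BAF is folded around 0.5 before segmentation (``|baf - 0.5| + 0.5``), which
removes the arbitrary A/B genotype labelling: a heterozygous probe under
allelic balance sits at 0.5, under imbalance above it.  Non-informative
(homozygous) probes contribute only LogR residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import ProbeTrack

__all__ = [
    "SegmentationConfig",
    "RawSegmentation",
    "mirror_baf",
    "segment_track",
    "estimate_noise",
]

log = logging.getLogger(__name__)

#: median of |N(0, 2 sigma^2)| = sigma * sqrt(2) * Phi^-1(0.75)
_MAD_DIFF_TO_SIGMA = float(np.sqrt(2.0) * 0.6744897501960817)


@dataclass(frozen=True)
class SegmentationConfig:
    penalty: float = 70.0
    min_probes_per_segment: int = 5
    logr_weight: float = 1.0
    baf_weight: float = 1.0
    #: lower bound on the noise estimates, keeps zero-noise input well posed
    sigma_floor: float = 1e-3
    #: probe-coverage gaps at least this wide (bp) force a segment boundary;
    #: keeps centromere-scale gaps out of segments and stops breakpoint
    #: jitter from bridging uncovered sequence
    max_probe_gap: int = 3_000_000

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty must be > 0")
        if self.min_probes_per_segment < 2:
            raise ValueError("min_probes_per_segment must be >= 2")


@dataclass
class RawSegmentation:
    """Per-chromosome breakpoints plus per-segment means.

    ``segments`` columns: chrom, start, end (0-based half-open, from probe
    positions), n_probes, mean_logr, mean_mbaf (NaN when the segment holds
    no informative probe).  ``breakpoints`` maps chromosome -> probe-index
    breakpoints (indices within that chromosome's probe array).
    """

    segments: pd.DataFrame
    breakpoints: dict[str, list[int]] = field(default_factory=dict)
    sigma_logr: float = float("nan")
    sigma_baf: float = float("nan")
    sex: str = "XX"


def mirror_baf(baf: np.ndarray | ProbeTrack) -> np.ndarray:
    """Fold BAF of informative probes around 0.5: ``|baf - 0.5| + 0.5``.

    Values land in [0.5, 1]; 0.5 is balanced heterozygosity, larger is more
    imbalanced.  Accepts a raw array or a ProbeTrack (then only informative
    probes are used).
    """
    if isinstance(baf, ProbeTrack):
        inf = baf.probes["informative"].to_numpy()
        if not inf.any():
            raise ValueError("track has no informative probes")
        baf = baf.probes.loc[inf, "baf"].to_numpy()
    baf = np.asarray(baf, dtype=float)
    return np.abs(baf - 0.5) + 0.5


def estimate_noise(track: ProbeTrack, config: SegmentationConfig) -> tuple[float, float]:
    """Robust (sigma_logr, sigma_baf) from successive differences per chromosome.

    BAF noise is estimated on folded values, which removes the arbitrary
    A/B band assignment of heterozygous probes: within any constant copy
    state the folded successive differences are pure noise.  The estimate
    only weights the segmentation objective; segment-level allelic
    imbalance is re-estimated bias-free afterwards (see
    ``mbaf_from_moments``).
    """
    dr, db = [], []
    for _, sub in track.probes.groupby("chrom", sort=False):
        v = sub["logr"].to_numpy()
        if len(v) >= 2:
            dr.append(np.abs(np.diff(v)))
        m = sub.loc[sub["informative"], "baf"].to_numpy()
        if len(m) >= 2:
            db.append(np.abs(np.diff(np.abs(m - 0.5) + 0.5)))
    sr = np.median(np.concatenate(dr)) / _MAD_DIFF_TO_SIGMA if dr else 0.0
    sb = np.median(np.concatenate(db)) / _MAD_DIFF_TO_SIGMA if db else 0.0
    return max(float(sr), config.sigma_floor), max(float(sb), config.sigma_floor)


def _folded_mean(delta: np.ndarray | float, sigma: float) -> np.ndarray | float:
    """E|X| for X ~ N(delta, sigma^2): mean of the folded normal."""
    delta = np.asarray(delta, dtype=float)
    from scipy.special import erf

    return sigma * np.sqrt(2.0 / np.pi) * np.exp(-(delta**2) / (2 * sigma**2)) + delta * erf(
        delta / (sigma * np.sqrt(2.0))
    )


def unfold_mean_mbaf(folded_mean: float, sigma: float) -> float:
    """Deconvolve the folding bias from a segment's mean mirrored BAF.

    Folding BAF around 0.5 turns noise into a positive offset: a perfectly
    balanced segment's folded mean sits at 0.5 + sigma*sqrt(2/pi), not 0.5.
    Given the BAF noise, invert the folded-normal mean to recover the
    underlying displacement ``delta`` and return ``0.5 + delta`` — the
    unbiased segment mirrored-BAF the copy-number fit needs.
    """
    from scipy.optimize import brentq

    d = folded_mean - 0.5
    if d <= _folded_mean(0.0, sigma):
        return 0.5
    hi = d + 5.0 * sigma
    delta = brentq(lambda t: _folded_mean(t, sigma) - d, 0.0, hi, xtol=1e-12)
    return 0.5 + float(delta)


def mbaf_from_moments(abs_dev_mean: float, sq_dev_mean: float, n: int) -> float:
    """Segment mirrored BAF from two moments of |BAF - 0.5| over n probes.

    Within one segment the unfolded BAF of heterozygous probes sits in two
    symmetric bands 0.5 +/- delta with noise sigma, so
    ``E|BAF - 0.5| = folded-normal mean(delta, sigma)`` and
    ``E (BAF - 0.5)^2 = delta^2 + sigma^2``.  Solving the pair for delta
    needs no external noise estimate and is therefore robust on genomes
    whose baseline copy state is itself imbalanced.

    Near delta = 0 the system is ill-conditioned (the folded mean is flat
    in delta), and the naive root is positively biased by sampling noise —
    enough to drag the purity fit off by several grid steps.  A one-sided
    balance test therefore snaps the estimate to 0.5 unless the folded
    mean exceeds its balanced-case expectation by three standard errors;
    displacements below about one noise-sd are deliberately reported as
    balance (see the methods note for the consequences at low purity).
    Returns ``0.5 + delta``.
    """
    from scipy.optimize import brentq

    d, v = abs_dev_mean, sq_dev_mean
    if v <= 0 or d <= 0:
        return 0.5
    rms = np.sqrt(v)
    if d >= rms * (1.0 - 1e-9):  # zero-noise limit: all mass at the bands
        return 0.5 + d
    # balanced null: d/rms -> sqrt(2/pi) with sd ~= 0.212/sqrt(n)
    # (delta method on the correlated first and second absolute moments)
    threshold = min(np.sqrt(2.0 / np.pi) + 3.0 * 0.212 / np.sqrt(max(n, 1)), 0.98)
    if d <= rms * threshold:
        return 0.5

    def f(delta: float) -> float:
        sigma = np.sqrt(max(v - delta**2, 1e-18))
        return _folded_mean(delta, sigma) - d

    delta = brentq(f, 0.0, rms, xtol=1e-12)
    return 0.5 + float(delta)


def _segment_cost_terms(y: np.ndarray, present: np.ndarray):
    """Prefix sums for O(1) SSE of y over any probe interval (present mask)."""
    yp = np.where(present, y, 0.0)
    s1 = np.concatenate([[0.0], np.cumsum(yp)])
    s2 = np.concatenate([[0.0], np.cumsum(yp * yp)])
    cnt = np.concatenate([[0], np.cumsum(present.astype(np.int64))])
    return s1, s2, cnt


def _interval_sse(s1, s2, cnt, i, j):
    """SSE around the mean over probes [i, j) (vectorised in i)."""
    n = cnt[j] - cnt[i]
    s = s1[j] - s1[i]
    q = s2[j] - s2[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        sse = q - np.where(n > 0, s * s / np.maximum(n, 1), 0.0)
    return np.maximum(sse, 0.0)


def _dp_chromosome(
    logr: np.ndarray,
    mbaf: np.ndarray,
    informative: np.ndarray,
    config: SegmentationConfig,
    wr: float,
    wb: float,
) -> list[int]:
    """Exact penalised least-squares DP; returns interior breakpoint indices."""
    n = len(logr)
    m = config.min_probes_per_segment
    if n < 2 * m:  # no admissible breakpoint
        return []
    r1, r2, rc = _segment_cost_terms(logr, np.ones(n, dtype=bool))
    b1, b2, bc = _segment_cost_terms(mbaf, informative)

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=np.int64)
    best[0] = 0.0
    idx = np.arange(n + 1)
    for j in range(m, n + 1):
        # candidate segment starts: 0 or any i with i >= m and j - i >= m
        i_hi = j - m
        cand = idx[: i_hi + 1]
        cost = (
            wr * _interval_sse(r1, r2, rc, cand, j)
            + wb * _interval_sse(b1, b2, bc, cand, j)
        )
        total = best[cand] + cost + np.where(cand > 0, config.penalty, 0.0)
        k = int(np.argmin(total))
        best[j] = total[k]
        prev[j] = cand[k]
    # backtrack
    bps: list[int] = []
    j = n
    while j > 0:
        i = int(prev[j])
        if i > 0:
            bps.append(i)
        j = i
    return sorted(bps)


def segment_track(track: ProbeTrack, config: SegmentationConfig | None = None) -> RawSegmentation:
    """Segment a probe track chromosome by chromosome.

    Chromosomes with fewer probes than ``min_probes_per_segment`` are
    emitted as a single segment with a warning.  Segment genomic
    coordinates run from the first probe's position to the last probe's
    position + 1 (0-based half-open), so probe-coverage gaps between
    segments are preserved in the output.
    """
    if config is None:
        config = SegmentationConfig()
    sr, sb = estimate_noise(track, config)
    wr = config.logr_weight / sr**2
    wb = config.baf_weight / sb**2

    rows = []
    breakpoints: dict[str, list[int]] = {}
    for chrom, sub in track.probes.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        logr = sub["logr"].to_numpy()
        inf = sub["informative"].to_numpy()
        mb = np.where(inf, np.abs(sub["baf"].to_numpy() - 0.5) + 0.5, 0.0)
        n = len(pos)
        # coverage blocks: runs of probes with no gap >= max_probe_gap between
        forced = (np.flatnonzero(np.diff(pos) >= config.max_probe_gap) + 1).tolist()
        blocks = list(zip([0, *forced], [*forced, n]))
        bps: list[int] = []
        for lo, hi in blocks:
            if hi - lo < config.min_probes_per_segment:
                if hi - lo == n:
                    log.warning(
                        "%s has %d probes (< %d); emitted as a single segment",
                        chrom, n, config.min_probes_per_segment,
                    )
                continue
            bps.extend(
                lo + b
                for b in _dp_chromosome(logr[lo:hi], mb[lo:hi], inf[lo:hi], config, wr, wb)
            )
        breakpoints[chrom] = sorted(set(bps) | set(forced))
        bounds = [0, *breakpoints[chrom], n]
        for i, j in zip(bounds[:-1], bounds[1:]):
            seg_inf = inf[i:j]
            if seg_inf.any():
                dev = mb[i:j][seg_inf] - 0.5  # = |baf - 0.5| of het probes
                mbaf = mbaf_from_moments(
                    float(np.mean(dev)), float(np.mean(dev**2)), int(seg_inf.sum())
                )
            else:
                mbaf = np.nan
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(pos[i]),
                    "end": int(pos[j - 1]) + 1,
                    "n_probes": j - i,
                    "mean_logr": float(np.mean(logr[i:j])),
                    "mean_mbaf": mbaf,
                }
            )
    return RawSegmentation(
        segments=pd.DataFrame(rows),
        breakpoints=breakpoints,
        sigma_logr=sr,
        sigma_baf=sb,
        sex=track.sex,
    )
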