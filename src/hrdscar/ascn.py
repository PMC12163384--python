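"""Allele-specific copy number: purity/ploidy grid search and integer calling.

A tumor sample is a mixture of tumor cells (fraction rho, the purity) and
normal diploid cells.  For a segment with allele-specific tumor copy
numbers (n_a, n_b), the expected total intensity and B-allele fraction are

    T   = 2 (1 - rho) + rho (n_a + n_b)
    r   = gamma * log2(T / (2 (1 - rho) + rho * psi))
    baf = ((1 - rho) + rho * n_b) / T

where psi is the reference (average) tumor ploidy and gamma the platform
compression factor (array LogR under-responds to copy number; 0.55 is the
customary value for SNP arrays).  Inverting these equations for candidate
(rho, psi) on a grid and asking how close the implied (n_a, n_b) fall to
non-negative integers yields the goodness-of-fit surface ("sunrise plot");
its arg-min is the purity/ploidy call, and rounding at the arg-min yields
the integer allele-specific segment profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeBuild
from .segmentation import RawSegmentation
from .tracks import SegmentProfile

__all__ = [
    "FitConfig",
    "PloidyFit",
    "segment_copy_numbers",
    "grid_search",
    "fit_profile",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Grid bounds and soft constraints for the purity/ploidy search.

    The purity grid starts at 0.10, below the 20% minimum tumor content
    required of specimens, so the pathology estimate always lies inside the
    searched range with margin.  ``pathology_tumor_content``, when given,
    down-ranks (never excludes) solutions whose purity falls outside the
    tolerance band around the pathologist's estimate.
    """

    rho_min: float = 0.10
    rho_max: float = 1.00
    rho_step: float = 0.01
    psi_min: float = 1.0
    psi_max: float = 5.4
    psi_step: float = 0.05
    gamma: float = 0.55
    pathology_tumor_content: float | None = None
    tumor_content_tol: float = 0.15
    tumor_content_penalty: float = 2.0
    #: small linear penalty on ploidy that resolves the whole-genome-doubling
    #: degeneracy (states 2x, purity rho/(2-rho) fits almost as well) toward
    #: the more parsimonious solution; far below within-basin curvature
    ploidy_parsimony: float = 0.002

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.rho_min <= 0 or self.rho_max > 1 or self.rho_min > self.rho_max:
            raise ValueError("invalid rho grid")
        if self.psi_min <= 0 or self.psi_min > self.psi_max:
            raise ValueError("invalid psi grid")

    def rho_grid(self) -> np.ndarray:
        n = int(round((self.rho_max - self.rho_min) / self.rho_step)) + 1
        return np.round(self.rho_min + self.rho_step * np.arange(n), 10)

    def psi_grid(self) -> np.ndarray:
        n = int(round((self.psi_max - self.psi_min) / self.psi_step)) + 1
        return np.round(self.psi_min + self.psi_step * np.arange(n), 10)


@dataclass
class PloidyFit:
    """Result of the grid search: purity, ploidy, and the fit surface."""

    rho: float
    psi: float
    gamma: float
    fit_surface: np.ndarray | None = None
    rho_grid: np.ndarray | None = None
    psi_grid: np.ndarray | None = None
    identifiable: bool = True
    fixed_by_user: bool = False

    @classmethod
    def fixed(cls, rho: float, psi: float, gamma: float = 0.55) -> "PloidyFit":
        """Manual purity/ploidy, the re-fit path after user review."""
        if not 0 < rho <= 1:
            raise ValueError("rho must be in (0, 1]")
        return cls(rho=rho, psi=psi, gamma=gamma, fixed_by_user=True)

    def to_dict(self) -> dict:
        return {
            "rho": self.rho,
            "psi": self.psi,
            "gamma": self.gamma,
            "identifiable": self.identifiable,
            "fixed_by_user": self.fixed_by_user,
        }


def segment_copy_numbers(
    seg_mean_logr: float | np.ndarray,
    seg_mean_baf: float | np.ndarray,
    rho: float,
    psi: float,
    gamma: float = 0.55,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the mixture model: segment means -> real-valued (n_a, n_b).

    ``seg_mean_baf`` may be a mirrored BAF (then n_b is the major allele)
    or a raw BAF; the algebra is symmetric.  rho = 0 is rejected (a sample
    with no tumor cells carries no tumor copy-number signal).
    """
    if rho <= 0:
        raise ValueError("rho must be > 0")
    r = np.asarray(seg_mean_logr, dtype=float)
    b = np.asarray(seg_mean_baf, dtype=float)
    total = 2.0 ** (r / gamma) * (2.0 * (1.0 - rho) + rho * psi)
    n_b = (total * b - (1.0 - rho)) / rho
    n_a = (total * (1.0 - b) - (1.0 - rho)) / rho
    return n_a, n_b


def _informative(raw: RawSegmentation) -> pd.DataFrame:
    seg = raw.segments
    return seg[np.isfinite(seg["mean_mbaf"])].reset_index(drop=True)


def grid_search(raw: RawSegmentation, config: FitConfig | None = None) -> PloidyFit:
    """Exhaustive (rho, psi) grid search minimising distance to integer states.

    For each grid point the implied (n_a, n_b) of every informative segment
    (one that carries a mirrored-BAF mean) is compared to its nearest
    non-negative integers; the length-weighted mean squared distance is the
    goodness of fit.  Ties are broken toward lower ploidy, then higher
    purity (the parsimony convention that avoids genome-doubled duplicate
    solutions).  A profile whose informative segments are all balanced and
    flat has no purity information along the grid ridge and is flagged
    non-identifiable; the surface is still returned.
    """
    if config is None:
        config = FitConfig()
    seg = _informative(raw)
    if len(seg) == 0:
        raise ValueError("no informative segments (no mirrored-BAF means)")
    r = seg["mean_logr"].to_numpy()
    b = seg["mean_mbaf"].to_numpy()
    w = (seg["end"] - seg["start"]).to_numpy().astype(float)
    w = w / w.sum()

    rhos = config.rho_grid()
    psis = config.psi_grid()
    surface = np.empty((len(rhos), len(psis)))
    for i, rho in enumerate(rhos):
        # vectorised over psi x segments
        total = 2.0 ** (r[None, :] / config.gamma) * (
            2.0 * (1.0 - rho) + rho * psis[:, None]
        )
        n_b = (total * b[None, :] - (1.0 - rho)) / rho
        n_a = (total * (1.0 - b[None, :]) - (1.0 - rho)) / rho
        d = (n_a - np.maximum(np.round(n_a), 0)) ** 2 + (
            n_b - np.maximum(np.round(n_b), 0)
        ) ** 2
        surface[i, :] = d @ w + config.ploidy_parsimony * psis

    if config.pathology_tumor_content is not None:
        excess = np.maximum(
            np.abs(rhos - config.pathology_tumor_content) - config.tumor_content_tol, 0.0
        )
        surface = surface + config.tumor_content_penalty * excess[:, None] ** 2

    # arg-min with (distance, psi, -rho) lexicographic tie-break
    tol = 1e-12
    mins = surface.min()
    ii, jj = np.where(surface <= mins + tol)
    order = np.lexsort((-rhos[ii], psis[jj]))
    best_i, best_j = int(ii[order[0]]), int(jj[order[0]])

    balanced = np.all(np.abs(b - 0.5) < 0.02)
    flat = np.sqrt(np.sum(w * (r - np.sum(w * r)) ** 2)) < 0.03
    identifiable = not (balanced and flat)
    if not identifiable:
        log.warning("fit is non-identifiable: all segments balanced and flat")

    return PloidyFit(
        rho=float(rhos[best_i]),
        psi=float(psis[best_j]),
        gamma=config.gamma,
        fit_surface=surface,
        rho_grid=rhos,
        psi_grid=psis,
        identifiable=identifiable,
    )


def fit_profile(
    raw: RawSegmentation,
    fit: PloidyFit,
    genome: GenomeBuild | None = None,
) -> SegmentProfile:
    """Round implied copy numbers to an integer allele-specific profile.

    Segments without informative probes carry no allelic information; their
    total copy number is taken from LogR and split as evenly as possible
    (major = ceil(total/2)).  Negative implied values are clamped to zero
    (counted and logged); adjacent same-state segments are merged, closing
    any probe-coverage gap between them.
    """
    seg = raw.segments
    r = seg["mean_logr"].to_numpy()
    b = seg["mean_mbaf"].to_numpy()
    has_baf = np.isfinite(b)
    n_a, n_b = segment_copy_numbers(r, np.where(has_baf, b, 0.5), fit.rho, fit.psi, fit.gamma)

    major = np.maximum(np.round(np.maximum(n_a, n_b)), 0).astype(np.int64)
    minor = np.maximum(np.round(np.minimum(n_a, n_b)), 0).astype(np.int64)
    # allelically blind segments: split rounded total as evenly as possible
    total = np.maximum(np.round(n_a + n_b), 0).astype(np.int64)
    major = np.where(has_baf, major, (total + 1) // 2)
    minor = np.where(has_baf, minor, total // 2)

    n_clamped = int(((n_a < -0.5) | (n_b < -0.5)).sum())
    if n_clamped:
        log.warning("%d segments had negative implied copy number (clamped to 0)", n_clamped)

    rows = []
    for (chrom, start, end), ma, mi in zip(
        seg[["chrom", "start", "end"]].itertuples(index=False), major, minor
    ):
        if rows and rows[-1]["chrom"] == chrom and (rows[-1]["n_major"], rows[-1]["n_minor"]) == (ma, mi):
            rows[-1]["end"] = int(end)
        else:
            rows.append(
                {"chrom": chrom, "start": int(start), "end": int(end),
                 "n_major": int(ma), "n_minor": int(mi)}
            )
    return SegmentProfile(segments=pd.DataFrame(rows), sample_sex=raw.sex)
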