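"""Diagnostic plots: allele-specific CN track, BAF scatter, sunrise heatmap.

Artifacts only — nothing downstream reads numbers off these figures.  The
allele-specific plot follows the field convention of major copy number in
red and minor copy number in green.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ascn import PloidyFit
from .genome import GenomeBuild
from .tracks import ProbeTrack, SegmentProfile

__all__ = ["plot_ascn_profile", "plot_baf", "plot_sunrise"]


def _chrom_offsets(genome: GenomeBuild) -> dict[str, int]:
    off, cum = {}, 0
    for c in genome.chromosomes:
        off[c.chrom] = cum
        cum += c.length
    return off


def plot_ascn_profile(
    profile: SegmentProfile, genome: GenomeBuild, path: str | Path
) -> None:
    """Major (red, upper) / minor (green, lower) copy-number step plot."""
    off = _chrom_offsets(genome)
    fig, ax = plt.subplots(figsize=(14, 3.5))
    for seg in profile.segments.itertuples(index=False):
        x0 = off[seg.chrom] + seg.start
        x1 = off[seg.chrom] + seg.end
        ax.hlines(seg.n_major + 0.07, x0, x1, color="red", lw=2.5)
        ax.hlines(seg.n_minor - 0.07, x0, x1, color="green", lw=2.5)
    for chrom, o in off.items():
        ax.axvline(o, color="0.85", lw=0.5)
    ax.set_ylabel("allele-specific copy number")
    ax.set_xlabel("genome position (hg19)")
    ax.set_ylim(-0.5, max(5, profile.segments["n_major"].max() + 1))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_baf(track: ProbeTrack, genome: GenomeBuild, path: str | Path) -> None:
    """B-allele-frequency scatter: 0 and 1 are the homozygous genotypes."""
    off = _chrom_offsets(genome)
    df = track.probes
    x = df["chrom"].map(off).to_numpy() + df["pos"].to_numpy()
    fig, ax = plt.subplots(figsize=(14, 2.5))
    ax.plot(x, df["baf"], ".", ms=1, color="0.3", alpha=0.5)
    ax.axhline(0.5, color="steelblue", lw=0.8)
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel("BAF")
    ax.set_xlabel("genome position (hg19)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_sunrise(fit: PloidyFit, path: str | Path) -> None:
    """Purity/ploidy goodness-of-fit surface with the chosen optimum marked."""
    if fit.fit_surface is None:
        raise ValueError("fit has no surface (user-fixed parameters?)")
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        np.log10(fit.fit_surface + 1e-6),
        origin="lower",
        aspect="auto",
        extent=[fit.psi_grid[0], fit.psi_grid[-1], fit.rho_grid[0], fit.rho_grid[-1]],
        cmap="hot",
    )
    ax.plot(fit.psi, fit.rho, "wo", mec="black", ms=8)
    ax.set_xlabel("ploidy ψ")
    ax.set_ylabel("purity ρ")
    fig.colorbar(im, ax=ax, label="log10 distance to integer states")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
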