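"""Reference-genome coordinate model.

Every scar rule needs to know where chromosomes end and where their
centromeres sit: loss-of-heterozygosity regions are disqualified when they
span a whole chromosome, large-scale state transitions are counted per
chromosome arm, and telomeric allelic imbalance must reach a chromosome end
without crossing the centromere.  This module provides that coordinate
model for hg19, the build the scoring pipeline is defined on.

Internally all coordinates are 0-based half-open; the bundled table (and
every TSV this package reads or writes) is 1-based inclusive, following the
SEG convention.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = ["ChromosomeArmTable", "GenomeBuild", "load_genome", "arm_of"]

#: canonical chromosome ordering used throughout the package
CHROM_ORDER = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]


@dataclass(frozen=True)
class ChromosomeArmTable:
    """One chromosome: its length and centromere span (0-based half-open).

    The p arm is ``[0, centromere_start)``, the q arm
    ``[centromere_end, length)``; telomeres are the first and last base.
    """

    chrom: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValueError(
                f"{self.chrom}: centromere span "
                f"[{self.centromere_start}, {self.centromere_end}) must lie "
                f"strictly inside (0, {self.length})"
            )

    @property
    def p_arm(self) -> tuple[int, int]:
        return (0, self.centromere_start)

    @property
    def q_arm(self) -> tuple[int, int]:
        return (self.centromere_end, self.length)


@dataclass(frozen=True)
class GenomeBuild:
    """A validated set of chromosome/arm/centromere coordinates."""

    name: str
    chromosomes: tuple[ChromosomeArmTable, ...]

    def __post_init__(self) -> None:
        seen = [c.chrom for c in self.chromosomes]
        if len(set(seen)) != len(seen):
            raise ValueError("duplicate chromosome in genome table")

    def chromosome(self, chrom: str) -> ChromosomeArmTable:
        for c in self.chromosomes:
            if c.chrom == chrom:
                return c
        raise KeyError(f"unknown chromosome {chrom!r} in build {self.name!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(c.chrom == chrom for c in self.chromosomes)

    def arms(self, sex: str = "XY") -> list[tuple[str, str, int, int]]:
        """All (chrom, arm, start, end) intervals, chrY only for XY samples."""
        out = []
        for c in self.chromosomes:
            if c.chrom == "chrY" and sex != "XY":
                continue
            out.append((c.chrom, "p", *c.p_arm))
            out.append((c.chrom, "q", *c.q_arm))
        return out


def load_genome(build_name: str | Path = "hg19") -> GenomeBuild:
    """Load a genome coordinate table.

    ``build_name`` is either the bundled build identifier ``"hg19"`` or a
    path to a user TSV with columns ``chrom, length, centromere_start,
    centromere_end`` (1-based inclusive on disk).
    """
    if build_name == "hg19":
        ref = importlib.resources.files("hrdscar") / "data" / "hg19_genome.tsv"
        with importlib.resources.as_file(ref) as p:
            return _read_genome_table(p, "hg19")
    p = Path(build_name)
    if p.exists():
        return _read_genome_table(p, p.stem)
    raise ValueError(f"unknown build {build_name!r} (only 'hg19' is bundled)")


def _read_genome_table(path: Path, name: str) -> GenomeBuild:
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "centromere_start", "centromere_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genome table {path}: missing columns {sorted(missing)}")
    chroms = []
    for row in df.itertuples(index=False):
        # disk is 1-based inclusive -> internal 0-based half-open
        chroms.append(
            ChromosomeArmTable(
                chrom=str(row.chrom),
                length=int(row.length),
                centromere_start=int(row.centromere_start) - 1,
                centromere_end=int(row.centromere_end),
            )
        )
    if name == "hg19" and len(chroms) != 24:
        raise ValueError(f"hg19 table must have 24 chromosomes, got {len(chroms)}")
    return GenomeBuild(name=name, chromosomes=tuple(chroms))


def arm_of(genome: GenomeBuild, chrom: str, pos: int) -> str:
    """Classify a position as ``"p"``, ``"q"`` or ``"centromeric"``.

    Total over ``[0, length)``: the three classes partition the chromosome.
    """
    c = genome.chromosome(chrom)
    if not 0 <= pos < c.length:
        raise ValueError(f"position {pos} out of range for {chrom} [0, {c.length})")
    if pos < c.centromere_start:
        return "p"
    if pos >= c.centromere_end:
        return "q"
    return "centromeric"
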