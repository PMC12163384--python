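import pandas as pd
import pytest

import hrdscar as h
from hrdscar.genome import ChromosomeArmTable, GenomeBuild


@pytest.fixture(scope="session")
def genome():
    return h.load_genome("hg19")


@pytest.fixture(scope="session")
def toy_genome():
    """Five 200-Mb chromosomes with a 95–105 Mb centromere each."""
    chroms = tuple(
        ChromosomeArmTable(
            chrom=f"chr{i}",
            length=200_000_000,
            centromere_start=95_000_000,
            centromere_end=105_000_000,
        )
        for i in range(1, 6)
    )
    return GenomeBuild(name="toy", chromosomes=chroms)


def make_profile(rows, sex="XX"):
    """rows: (chrom, start, end, n_major, n_minor) tuples."""
    return h.SegmentProfile(
        segments=pd.DataFrame(
            rows, columns=["chrom", "start", "end", "n_major", "n_minor"]
        ),
        sample_sex=sex,
    )


def make_track(chrom_arrays, sex="XX"):
    """chrom_arrays: {chrom: (pos, logr, baf, informative)} -> ProbeTrack."""
    frames = []
    for chrom, (pos, logr, baf, informative) in chrom_arrays.items():
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{chrom}_{p}" for p in pos],
                    "chrom": chrom,
                    "pos": pos,
                    "logr": logr,
                    "baf": baf,
                    "informative": informative,
                }
            )
        )
    return h.ProbeTrack(probes=pd.concat(frames, ignore_index=True), sex=sex)
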