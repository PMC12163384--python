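import numpy as np
import pytest

import hrdscar as h
from conftest import make_profile
from oracles import oracle_scar_counts

MB = 1_000_000

# toy genome (conftest): 5 chromosomes of 200 Mb, centromere 95–105 Mb


def _diploid(toy_genome):
    return [(c.chrom, 0, c.length, 1, 1) for c in toy_genome.chromosomes]


class TestLOH:
    def test_diploid_profile_has_no_loh(self, toy_genome):
        assert h.count_loh(make_profile(_diploid(toy_genome)), toy_genome)[0] == 0

    def test_whole_chromosome_loh_excluded(self, toy_genome):
        rows = _diploid(toy_genome)[1:] + [("chr1", 0, 200 * MB, 2, 0)]
        assert h.count_loh(make_profile(rows), toy_genome)[0] == 0

    def test_length_threshold_is_strict(self, toy_genome):
        # runs of 20, 16, 10 Mb -> only the first two pass "> 15 Mb"
        rows = []
        for chrom, length in [("chr1", 20), ("chr2", 16), ("chr3", 10)]:
            rows += [
                (chrom, 0, 30 * MB, 1, 1),
                (chrom, 30 * MB, (30 + length) * MB, 1, 0),
                (chrom, (30 + length) * MB, 200 * MB, 1, 1),
            ]
        rows += [(c, 0, 200 * MB, 1, 1) for c in ("chr4", "chr5")]
        count, events = h.count_loh(make_profile(rows), toy_genome)
        assert count == 2
        assert {e["chrom"] for e in events} == {"chr1", "chr2"}

    def test_homdel_does_not_interrupt_but_adds_no_length(self, toy_genome):
        # 10 Mb LOH | 2 Mb (0,0) | 10 Mb LOH: one run of length 20 Mb
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 30 * MB, 1, 1),
            ("chr1", 30 * MB, 40 * MB, 2, 0),
            ("chr1", 40 * MB, 42 * MB, 0, 0),
            ("chr1", 42 * MB, 52 * MB, 2, 0),
            ("chr1", 52 * MB, 200 * MB, 1, 1),
        ]
        count, events = h.count_loh(make_profile(rows), toy_genome)
        assert count == 1
        assert events[0]["length"] == 20 * MB

    def test_small_coverage_gap_bridged_large_gap_interrupts(self, toy_genome):
        def rows_with_gap(gap_mb):
            return _diploid(toy_genome)[1:] + [
                ("chr1", 0, 30 * MB, 1, 1),
                ("chr1", 30 * MB, 40 * MB, 2, 0),
                ("chr1", (40 + gap_mb) * MB, 50 * MB, 2, 0),
                ("chr1", 50 * MB, 200 * MB, 1, 1),
            ]
        # 2 Mb gap bridged -> one 18-Mb run (> 15 Mb)
        assert h.count_loh(make_profile(rows_with_gap(2)), toy_genome)[0] == 1
        # 4 Mb gap interrupts -> two sub-threshold runs
        assert h.count_loh(make_profile(rows_with_gap(4)), toy_genome)[0] == 0


class TestLST:
    def test_diploid_profile_has_no_lst(self, toy_genome):
        assert h.count_lst(make_profile(_diploid(toy_genome)), toy_genome)[0] == 0

    def test_simple_transition_counts_once(self, toy_genome):
        # q arm: 30 Mb (1,1) | 30 Mb (2,1)
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 135 * MB, 1, 1),
            ("chr1", 135 * MB, 200 * MB, 2, 1),
        ]
        count, events = h.count_lst(make_profile(rows), toy_genome)
        assert count == 1
        assert events[0]["arm"] == "q"

    def test_short_interloper_removed_flanks_merge(self, toy_genome):
        # 30 Mb (1,1) | 2 Mb (3,1) | 30 Mb (1,1): no transition after smoothing
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 135 * MB, 1, 1),
            ("chr1", 135 * MB, 137 * MB, 3, 1),
            ("chr1", 137 * MB, 200 * MB, 1, 1),
        ]
        assert h.count_lst(make_profile(rows), toy_genome)[0] == 0

    def test_flank_below_10mb_not_counted(self, toy_genome):
        # telomere-side flank of 5 Mb is below the minimum segment size
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 195 * MB, 1, 1),
            ("chr1", 195 * MB, 200 * MB, 2, 1),
        ]
        assert h.count_lst(make_profile(rows), toy_genome)[0] == 0

    def test_transition_across_large_gap_not_counted(self, toy_genome):
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 150 * MB, 1, 1),
            ("chr1", 154 * MB, 200 * MB, 2, 1),  # 4 Mb coverage gap
        ]
        assert h.count_lst(make_profile(rows), toy_genome)[0] == 0

    def test_centromere_spanning_transition_not_counted(self, toy_genome):
        # state change hidden inside the centromere: neither arm sees it
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 100 * MB, 1, 1),
            ("chr1", 100 * MB, 200 * MB, 2, 1),
        ]
        assert h.count_lst(make_profile(rows), toy_genome)[0] == 0


class TestTAI:
    def test_diploid_profile_has_no_tai(self, toy_genome):
        assert h.count_tai(make_profile(_diploid(toy_genome)), toy_genome)[0] == 0

    def test_terminal_imbalance_counts(self, toy_genome):
        # q-terminal 40 Mb at (2,1)
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 160 * MB, 1, 1),
            ("chr1", 160 * MB, 200 * MB, 2, 1),
        ]
        count, events = h.count_tai(make_profile(rows), toy_genome)
        assert count == 1
        assert events[0]["end"] == 200 * MB

    def test_whole_chromosome_imbalance_excluded(self, toy_genome):
        rows = _diploid(toy_genome)[1:] + [("chr1", 0, 200 * MB, 2, 1)]
        assert h.count_tai(make_profile(rows), toy_genome)[0] == 0

    def test_centromere_crossing_run_excluded(self, toy_genome):
        # imbalance from p telomere across the centromere into q
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 120 * MB, 2, 1),
            ("chr1", 120 * MB, 200 * MB, 1, 1),
        ]
        assert h.count_tai(make_profile(rows), toy_genome)[0] == 0

    def test_interior_imbalance_not_counted(self, toy_genome):
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 30 * MB, 1, 1),
            ("chr1", 30 * MB, 60 * MB, 2, 1),
            ("chr1", 60 * MB, 200 * MB, 1, 1),
        ]
        assert h.count_tai(make_profile(rows), toy_genome)[0] == 0


class TestGISScore:
    def test_diploid_scores_zero(self, toy_genome):
        res = h.gis_score(make_profile(_diploid(toy_genome)), toy_genome)
        assert (res.loh, res.lst, res.tai, res.gis) == (0, 0, 0, 0)

    def test_sum_conservation_on_simulated_truth(self, genome):
        truth = h.inject_scars(genome, h.SimConfig(seed=9, n_loh=3, n_lst=5, n_tai=2))
        res = h.gis_score(truth.profile, genome)
        assert (res.loh, res.lst, res.tai) == (3, 5, 2)
        assert res.gis == res.loh + res.lst + res.tai == 10

    def test_row_order_invariance(self, toy_genome):
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 160 * MB, 1, 1),
            ("chr1", 160 * MB, 200 * MB, 2, 1),
        ]
        a = h.gis_score(make_profile(rows), toy_genome)
        b = h.gis_score(make_profile(rows[::-1]), toy_genome)
        assert a.to_dict() == b.to_dict()

    def test_split_segment_invariance(self, toy_genome):
        """Splitting any segment into equal-state halves changes nothing."""
        rows = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 30 * MB, 1, 1),
            ("chr1", 30 * MB, 60 * MB, 2, 0),
            ("chr1", 60 * MB, 200 * MB, 1, 1),
        ]
        split = _diploid(toy_genome)[1:] + [
            ("chr1", 0, 30 * MB, 1, 1),
            ("chr1", 30 * MB, 45 * MB, 2, 0),
            ("chr1", 45 * MB, 60 * MB, 2, 0),
            ("chr1", 60 * MB, 130 * MB, 1, 1),
            ("chr1", 130 * MB, 200 * MB, 1, 1),
        ]
        a = h.gis_score(make_profile(rows), toy_genome)
        b = h.gis_score(make_profile(split), toy_genome)
        assert (a.loh, a.lst, a.tai) == (b.loh, b.lst, b.tai)

    def test_chry_scored_only_for_xy(self, toy_genome, genome):
        rows = [(c.chrom, 0, c.length, 1, 1) for c in genome.chromosomes
                if c.chrom != "chrY"]
        loh_run = [("chrY", 0, 20 * MB, 1, 0), ("chrY", 20 * MB, 59_373_566, 1, 1)]
        xy = h.gis_score(make_profile(rows + loh_run, sex="XY"), genome)
        xx = h.gis_score(make_profile(rows + loh_run, sex="XX"), genome)
        assert xy.loh == 1 and xx.loh == 0

    def test_injecting_one_more_loh_increments_only_loh(self, genome):
        a = h.gis_score(
            h.inject_scars(genome, h.SimConfig(seed=21, n_loh=2, n_lst=3, n_tai=2)).profile,
            genome,
        )
        b = h.gis_score(
            h.inject_scars(genome, h.SimConfig(seed=21, n_loh=3, n_lst=3, n_tai=2)).profile,
            genome,
        )
        assert (b.lst, b.tai) == (a.lst, a.tai)
        assert b.loh == a.loh + 1


class TestOracleEquivalence:
    """Counts must equal a brute-force maximal-run enumeration on random
    toy profiles."""

    @pytest.mark.parametrize("batch", range(4))
    def test_random_profiles_match_bruteforce(self, toy_genome, batch):
        rng = np.random.default_rng(100 + batch)
        for _ in range(50):
            rows = []
            for c in toy_genome.chromosomes:
                n_seg = int(rng.integers(1, 13))
                cuts = np.sort(rng.choice(np.arange(1, 200), size=n_seg - 1, replace=False)) * MB
                bounds = [0, *cuts.tolist(), c.length]
                pos = 0
                for s, e in zip(bounds[:-1], bounds[1:]):
                    # occasionally drop coverage to create gaps
                    if rng.random() < 0.1:
                        continue
                    ma = int(rng.integers(0, 4))
                    mi = int(rng.integers(0, ma + 1))
                    rows.append((c.chrom, s, e, ma, mi))
            if not rows:
                continue
            profile = make_profile(rows)
            res = h.gis_score(profile, toy_genome)
            exp = oracle_scar_counts(
                profile.segments.itertuples(index=False), toy_genome
            )
            assert (res.loh, res.lst, res.tai) == exp
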