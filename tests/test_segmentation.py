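import numpy as np
import pytest

import hrdscar as h
from hrdscar.segmentation import estimate_noise, mbaf_from_moments, unfold_mean_mbaf
from conftest import make_track
from oracles import enumerate_breakpoints, _seg_cost


@pytest.mark.parametrize("baf, expected", [(0.5, 0.5), (0.2, 0.8), (1.0, 1.0), (0.0, 1.0)])
def test_mirror_baf_folding(baf, expected):
    assert h.mirror_baf(np.array([baf]))[0] == pytest.approx(expected)


def test_mirror_baf_requires_informative_probes():
    track = make_track({"chr1": ([1, 2, 3, 4, 5], [0.0] * 5, [0.5] * 5, [False] * 5)})
    with pytest.raises(ValueError, match="informative"):
        h.mirror_baf(track)


def _noisefree_track(logr, baf=None, informative=None, spacing=1000):
    n = len(logr)
    pos = np.arange(n) * spacing
    baf = np.full(n, 0.5) if baf is None else np.asarray(baf)
    inf = np.ones(n, bool) if informative is None else np.asarray(informative)
    return make_track({"chr1": (pos, np.asarray(logr, float), baf, inf)})


class TestSegmentTrack:
    def test_single_true_breakpoint_found_exactly(self):
        logr = np.concatenate([np.zeros(100), np.full(100, 0.58)])
        raw = h.segment_track(_noisefree_track(logr))
        assert raw.breakpoints["chr1"] == [100]
        seg = raw.segments
        assert len(seg) == 2
        assert seg["mean_logr"].tolist() == pytest.approx([0.0, 0.58])

    def test_constant_track_has_no_breakpoints(self):
        raw = h.segment_track(_noisefree_track(np.zeros(200)))
        assert raw.breakpoints["chr1"] == []

    def test_huge_penalty_suppresses_all_breakpoints(self):
        rng = np.random.default_rng(0)
        logr = np.concatenate([np.zeros(100), np.full(100, 0.58)]) + rng.normal(0, 0.1, 200)
        raw = h.segment_track(
            _noisefree_track(logr), h.SegmentationConfig(penalty=1e9)
        )
        assert raw.breakpoints["chr1"] == []

    def test_baf_only_change_is_detected(self):
        # logr flat; imbalance appears in BAF alone (copy-neutral event)
        baf = np.concatenate([np.full(100, 0.5), np.full(100, 0.8)])
        raw = h.segment_track(_noisefree_track(np.zeros(200), baf=baf))
        assert raw.breakpoints["chr1"] == [100]

    def test_genotype_relabeling_invariance(self):
        """Flipping baf -> 1 - baf must not change the segmentation."""
        rng = np.random.default_rng(1)
        baf = np.concatenate([np.full(80, 0.35), np.full(80, 0.5)]) + rng.normal(0, 0.02, 160)
        baf = np.clip(baf, 0, 1)
        logr = rng.normal(0, 0.05, 160)
        a = h.segment_track(_noisefree_track(logr, baf=baf))
        b = h.segment_track(_noisefree_track(logr, baf=1 - baf))
        assert a.breakpoints == b.breakpoints

    def test_short_chromosome_single_segment(self, caplog):
        track = make_track({"chr1": ([0, 1000, 2000], [0.0, 5.0, 0.0], [0.5] * 3, [True] * 3)})
        raw = h.segment_track(track)
        assert raw.breakpoints["chr1"] == []
        assert len(raw.segments) == 1

    def test_coverage_gap_forces_boundary(self):
        pos = np.concatenate([np.arange(20) * 100_000, 10_000_000 + np.arange(20) * 100_000])
        logr = np.zeros(40)
        track = make_track({"chr1": (pos, logr, np.full(40, 0.5), np.ones(40, bool))})
        raw = h.segment_track(track)
        assert len(raw.segments) == 2  # split at the 8-Mb probe gap, same state


class TestDPAgainstEnumeration:
    """The DP must equal brute-force enumeration over all admissible
    breakpoint subsets on small tracks."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_small_tracks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 17))
        k_true = int(rng.integers(0, 3))
        means = rng.uniform(-1, 1, k_true + 1)
        bounds = np.sort(rng.choice(np.arange(2, n - 2), size=k_true, replace=False))
        logr = np.empty(n)
        for i, (a, b) in enumerate(zip([0, *bounds], [*bounds, n])):
            logr[a:b] = means[i]
        logr += rng.normal(0, 0.3, n)
        baf = np.clip(rng.normal(0.6, 0.1, n), 0, 1)
        inf = rng.random(n) < 0.6

        cfg = h.SegmentationConfig(penalty=5.0, min_probes_per_segment=2)
        track = make_track({"chr1": (np.arange(n) * 1000, logr, baf, inf)})
        raw = h.segment_track(track, cfg)

        sr, sb = estimate_noise(track, cfg)
        wr, wb = 1 / sr**2, 1 / sb**2
        mbaf = np.where(inf, np.abs(baf - 0.5) + 0.5, 0.0)
        best_cost, best_bps = enumerate_breakpoints(
            logr, mbaf, inf, cfg.penalty, cfg.min_probes_per_segment, wr, wb
        )
        dp_bps = raw.breakpoints["chr1"]
        dp_bounds = [0, *dp_bps, n]
        dp_cost = cfg.penalty * len(dp_bps) + sum(
            _seg_cost(logr, mbaf, inf, a, b, wr, wb)
            for a, b in zip(dp_bounds, dp_bounds[1:])
        )
        # the DP must achieve the global optimum (placements may tie)
        assert dp_cost == pytest.approx(best_cost, rel=1e-9, abs=1e-9)
        assert dp_bps == best_bps or dp_cost == pytest.approx(best_cost)


class TestFoldedBafDeconvolution:
    def test_balanced_segment_unbiased(self):
        # folded mean of a balanced segment sits near 0.5 + sigma*sqrt(2/pi)
        sigma = 0.03
        folded_mean = 0.5 + sigma * np.sqrt(2 / np.pi)
        assert unfold_mean_mbaf(folded_mean, sigma) == pytest.approx(0.5)

    def test_far_from_fold_identity(self):
        assert unfold_mean_mbaf(0.8, 0.03) == pytest.approx(0.8, abs=1e-4)

    @pytest.mark.parametrize(
        "delta, sigma",
        [(0.0, 0.01), (0.0, 0.03), (0.0, 0.08), (0.05, 0.01),
         (0.12, 0.03), (0.12, 0.08), (0.3, 0.03)],
    )
    def test_moment_estimator_recovers_band_displacement(self, delta, sigma):
        # well-separated bands (delta >= 2 sigma) are recovered; balanced
        # segments are snapped to exactly 0.5
        rng = np.random.default_rng(17)
        n = 40_000
        side = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        baf = 0.5 + side * delta + rng.normal(0, sigma, n)
        dev = np.abs(baf - 0.5)
        got = mbaf_from_moments(float(dev.mean()), float((dev**2).mean()), n)
        if delta == 0.0:
            assert got == 0.5
        else:
            assert got == pytest.approx(0.5 + delta, abs=4 * sigma / np.sqrt(n) + 2e-3)

    def test_moment_estimator_zero_noise_exact(self):
        dev = np.full(100, 0.23)
        got = mbaf_from_moments(float(dev.mean()), float((dev**2).mean()), 100)
        assert got == pytest.approx(0.73, abs=1e-9)
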