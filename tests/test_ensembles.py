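"""Binarization, the shuffle null, ensemble detection and core extraction."""

from itertools import combinations

import numpy as np
import pytest

from calnet import (
    BinaryRaster,
    Ensemble,
    analyze_raster,
    binarize,
    detect_ensembles,
    find_core_ensembles,
    shuffle_null,
    summarize_ensembles,
)
from calnet.ensembles import _shuffled_coactivity


def _raster(active):
    return BinaryRaster(active=np.asarray(active, dtype=np.uint8),
                        threshold_value=0.0, sd_multiplier=3.0)


class TestBinarize:
    def test_threshold_is_multiplier_times_pooled_rms(self):
        values = np.full((10, 10), 0.1)
        out = binarize(values, sd_multiplier=3.0)
        assert out.threshold_value == pytest.approx(0.3)
        assert np.all(out.active == 0)  # 0.1 < 0.3

    def test_strict_inequality_on_all_zero_matrix(self):
        out = binarize(np.zeros((5, 4)))
        assert out.threshold_value == 0.0
        assert np.all(out.active == 0)

    def test_values_above_and_below(self):
        values = np.zeros((10, 10))
        values[0, 0], values[1, 1] = 0.35, 0.2
        rms = np.sqrt(np.mean(values**2))
        out = binarize(values, sd_multiplier=0.35 / (3 * rms) * 3 - 1e-9)
        # hand check against elementwise comparison
        np.testing.assert_array_equal(out.active, values > out.threshold_value)
        assert out.active[0, 0] == 1 and out.active[1, 1] == 0

    def test_matches_brute_force_elementwise(self, rng):
        values = rng.random((30, 20))
        out = binarize(values, sd_multiplier=1.0)
        brute = np.array(
            [[1 if values[i, j] > out.threshold_value else 0 for j in range(20)]
             for i in range(30)]
        )
        np.testing.assert_array_equal(out.active, brute)

    def test_sd_about_mean_mode(self, rng):
        values = rng.random((30, 20))
        out = binarize(values, sd_multiplier=2.0, sd_mode="mean")
        assert out.threshold_value == pytest.approx(2.0 * values.std())

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.array([[1.5]]))


class TestShuffleNull:
    def test_per_cell_totals_conserved(self, rng):
        active = np.zeros((30, 100), dtype=np.uint8)
        active[rng.integers(0, 30, 100), np.arange(100)] = 1  # one spike per cell
        for mode in ("permute", "circular"):
            counts = _shuffled_coactivity(active, 50, np.random.default_rng(0), mode)
            assert counts.shape == (50, 30)
            np.testing.assert_array_equal(counts.sum(axis=1), 100)

    def test_exhaustive_enumeration_on_toy_raster(self):
        """1000-shuffle tail probabilities match exact enumeration on 3x4."""
        active = np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 0, 0]], dtype=np.uint8).reshape(4, 3)
        # exact pooled distribution: enumerate all per-cell frame placements
        T = 4
        totals = active.sum(axis=0)
        placements = [list(combinations(range(T), k)) for k in totals]
        frame_counts = []
        for p0 in placements[0]:
            for p1 in placements[1]:
                for p2 in placements[2]:
                    occ = np.zeros(T, dtype=int)
                    for p in (p0, p1, p2):
                        for f in p:
                            occ[f] += 1
                    frame_counts.extend(occ.tolist())
        frame_counts = np.array(frame_counts)
        n_shuffles = 1000
        null = shuffle_null(_raster(active), n_shuffles=n_shuffles, seed=11,
                            null_mode="pooled")
        for c in (2, 3):
            exact = np.mean(frame_counts >= c)
            se = np.sqrt(exact * (1 - exact) / n_shuffles)
            assert abs(null.tail_p[c] - exact) <= 3 * se

    def test_no_activity_marker(self):
        null = shuffle_null(_raster(np.zeros((6, 3))), n_shuffles=10, seed=0)
        assert null.no_activity and null.coactivity_threshold is None

    def test_deterministic_under_seed(self, rng):
        active = (rng.random((40, 30)) < 0.1).astype(np.uint8)
        a = shuffle_null(_raster(active), n_shuffles=200, seed=5)
        b = shuffle_null(_raster(active), n_shuffles=200, seed=5)
        assert a.tail_p == b.tail_p
        assert a.coactivity_threshold == b.coactivity_threshold

    def test_threshold_nonincreasing_in_alpha(self, rng):
        active = (rng.random((60, 50)) < 0.08).astype(np.uint8)
        thresholds = [
            shuffle_null(_raster(active), n_shuffles=300, alpha=a, seed=7,
                         null_mode="pooled").coactivity_threshold
            for a in (0.01, 0.05, 0.2)
        ]
        assert thresholds[0] >= thresholds[1] >= thresholds[2]

    def test_threshold_nondecreasing_in_activity_rate(self):
        rng = np.random.default_rng(8)
        sparse = (rng.random((60, 50)) < 0.03).astype(np.uint8)
        dense = sparse | (rng.random((60, 50)) < 0.15).astype(np.uint8)
        t_sparse = shuffle_null(_raster(sparse), n_shuffles=300, seed=9).coactivity_threshold
        t_dense = shuffle_null(_raster(dense), n_shuffles=300, seed=9).coactivity_threshold
        assert t_dense >= t_sparse


class TestDetect:
    def test_two_isolated_high_activity_frames(self):
        active = np.zeros((60, 10), dtype=np.uint8)
        active[10, :8] = 1
        active[50, :8] = 1
        result = detect_ensembles(_raster(active), coactivity_threshold=3)
        assert len(result.ensembles) == 2
        assert all(len(e.members) == 8 for e in result.ensembles)
        assert [e.frames for e in result.ensembles] == [(10,), (50,)]

    def test_empty_when_no_frame_reaches_threshold(self):
        active = np.zeros((20, 5), dtype=np.uint8)
        active[3, 0] = 1
        result = detect_ensembles(_raster(active), coactivity_threshold=3)
        assert result.ensembles == []
        assert summarize_ensembles(result)["n_ensembles"] == 0

    def test_consecutive_identical_frames_merge(self):
        active = np.zeros((20, 6), dtype=np.uint8)
        active[[5, 6], :4] = 1        # same member set, adjacent -> one event
        active[8, 1:5] = 1            # different set -> separate
        result = detect_ensembles(_raster(active), coactivity_threshold=3)
        assert len(result.ensembles) == 2
        assert result.ensembles[0].frames == (5, 6)

    def test_threshold_floor_of_two(self):
        active = np.zeros((10, 4), dtype=np.uint8)
        active[2, 0] = 1  # single active cell is never an ensemble
        result = detect_ensembles(_raster(active), coactivity_threshold=1)
        assert result.ensembles == []


class TestCores:
    def test_shared_pair_across_two_ensembles(self):
        ens = [Ensemble(frames=(1,), members=(0, 1, 2, 3)),
               Ensemble(frames=(5,), members=(2, 3, 4))]
        cores = find_core_ensembles(ens)
        assert len(cores) == 1
        assert cores[0].cells == (2, 3)
        assert cores[0].parents == (0, 1)

    def test_disjoint_ensembles_have_no_core(self):
        ens = [Ensemble(frames=(1,), members=(0, 1)),
               Ensemble(frames=(2,), members=(2, 3))]
        assert find_core_ensembles(ens) == []

    def test_matches_brute_force_enumeration(self, rng):
        """Cores = maximal >=2-cell intersections over all ensemble pairs."""
        for trial in range(5):
            r = np.random.default_rng(trial)
            ens = [
                Ensemble(frames=(i,), members=tuple(
                    sorted(r.choice(30, size=r.integers(3, 9), replace=False).tolist())
                ))
                for i in range(5)
            ]
            got = {c.cells for c in find_core_ensembles(ens)}
            sets = [frozenset(e.members) for e in ens]
            cands = {sets[a] & sets[b] for a, b in combinations(range(5), 2)}
            cands = {c for c in cands if len(c) >= 2}
            want = {tuple(sorted(c)) for c in cands
                    if not any(c < other for other in cands)}
            assert got == want

    def test_every_core_has_at_least_two_parents_and_two_cells(self, rng):
        active = (rng.random((80, 25) ) < 0.12).astype(np.uint8)
        result = detect_ensembles(_raster(active), coactivity_threshold=3)
        for core in result.core_ensembles:
            assert len(core.cells) >= 2
            assert len(core.parents) >= 2
            for p in core.parents:
                assert set(core.cells) <= set(result.ensembles[p].members)


def test_summarize_counts_and_means():
    ens = [Ensemble(frames=(0,), members=tuple(range(8))),
           Ensemble(frames=(9,), members=tuple(range(4)))]
    from calnet import EnsembleSet
    s = summarize_ensembles(EnsembleSet(ensembles=ens, core_ensembles=[],
                                        coactivity_threshold=2, null=None))
    assert s["n_ensembles"] == 2
    assert s["mean_cells_per_ensemble"] == 6.0


def test_analyze_raster_deterministic(rng):
    active = (rng.random((60, 40)) < 0.06).astype(np.uint8)
    active[[10, 30], :9] = 1
    a = analyze_raster(_raster(active), n_shuffles=300, seed=3)
    b = analyze_raster(_raster(active), n_shuffles=300, seed=3)
    assert [e.members for e in a.ensembles] == [e.members for e in b.ensembles]
    assert a.coactivity_threshold == b.coactivity_threshold
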