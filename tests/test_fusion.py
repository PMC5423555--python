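import numpy as np
import pytest

from atlasfusion.fusion import (
    beta_schedule,
    categorical_from_prob,
    fuse_intensity,
    fuse_labels,
    rank_atlases,
    votes_from_seg,
    weights_from_ranks,
)
from atlasfusion.image_model import ImageGrid, ProbSegVolume, ScalarVolume
from atlasfusion.similarity import SimilarityVolume

from conftest import make_volume, random_simplex_seg

GRID = ImageGrid((8, 8, 8), (1.0, 1.0, 1.0))


def sim_from_array(vals, valid=None):
    vals = np.asarray(vals, dtype=float)
    if valid is None:
        valid = np.isfinite(vals)
    return SimilarityVolume(GRID, vals, valid)


def random_stack(rng, n, invalid_frac=0.0):
    sims = []
    for _ in range(n):
        v = rng.normal(0, 1, GRID.shape)
        valid = rng.random(GRID.shape) >= invalid_frac
        sims.append(sim_from_array(np.where(valid, v, -np.inf), valid))
    return sims


class TestBetaSchedule:
    @pytest.mark.parametrize("t,expected", [(1, 1.0), (2, 0.875), (4, 0.625), (7, 0.25), (8, 0.125), (20, 0.125)])
    def test_linear_decay_with_floor(self, t, expected):
        assert beta_schedule(t) == pytest.approx(expected)

    def test_invalid_iteration(self):
        with pytest.raises(ValueError):
            beta_schedule(0)


class TestRanking:
    def test_simple_ordering(self):
        sims = [sim_from_array(np.full(GRID.shape, v)) for v in (0.9, 0.2, 0.5)]
        rf = rank_atlases(sims)
        assert np.all(rf.ranks[0] == 0) and np.all(rf.ranks[1] == 2) and np.all(rf.ranks[2] == 1)

    def test_all_invalid_voxel_flagged_unfusable(self, rng):
        sims = random_stack(rng, 3)
        for s in sims:
            s.valid[0, 0, 0] = False
            s.values[0, 0, 0] = -np.inf
        rf = rank_atlases(sims)
        assert not rf.fusable[0, 0, 0]
        assert rf.fusable[1:].all()

    def test_matches_argsort_oracle(self, rng):
        sims = random_stack(rng, 8, invalid_frac=0.1)
        rf = rank_atlases(sims)
        stack = np.stack([s.values for s in sims])
        for _ in range(50):
            i, j, k = rng.integers(0, 8, 3)
            vals = stack[:, i, j, k]
            finite = np.isfinite(vals)
            order = np.argsort(-vals[finite], kind="stable")
            expect = np.full(8, -1)
            expect[np.flatnonzero(finite)[order]] = np.arange(finite.sum())
            assert np.array_equal(rf.ranks[:, i, j, k], expect)

    def test_ranks_are_permutation(self, rng):
        sims = random_stack(rng, 5, invalid_frac=0.2)
        rf = rank_atlases(sims)
        m = rf.valid.sum(axis=0)
        for i, j, k in [(0, 0, 0), (3, 4, 5), (7, 7, 7)]:
            r = rf.ranks[:, i, j, k]
            assert sorted(r[r >= 0]) == list(range(m[i, j, k]))


class TestWeights:
    def test_closed_form(self, rng):
        sims = random_stack(rng, 8)
        rf = rank_atlases(sims)
        for beta in (1.0, 0.625):
            wf = weights_from_ranks(rf, beta)
            assert np.allclose(wf.weights, np.exp(-beta * rf.ranks), atol=1e-12)
        assert np.all(weights_from_ranks(rf, 1.0).weights.max(axis=0) == 1.0)

    def test_excluded_atlas_gets_zero(self, rng):
        sims = random_stack(rng, 3, invalid_frac=0.3)
        rf = rank_atlases(sims)
        wf = weights_from_ranks(rf, 1.0)
        assert np.all(wf.weights[~rf.valid] == 0.0)

    def test_positive_beta_required(self, rng):
        rf = rank_atlases(random_stack(rng, 2))
        with pytest.raises(ValueError):
            weights_from_ranks(rf, 0.0)


def brute_fuse(weights, values):
    num = sum(w * v for w, v in zip(weights, values))
    den = sum(weights)
    return num / den


class TestIntensityFusion:
    def test_single_atlas_identity(self, rng):
        ct = make_volume(GRID, rng.normal(0, 100, GRID.shape), modality="CT")
        wf = weights_from_ranks(rank_atlases([sim_from_array(np.ones(GRID.shape))]), 1.0)
        out = fuse_intensity(wf, [ct])
        assert np.array_equal(out.values, ct.values)

    def test_equal_weight_mean(self):
        sims = [sim_from_array(np.full(GRID.shape, 0.5)) for _ in range(2)]
        rf = rank_atlases(sims)
        wf = weights_from_ranks(rf, 1e-9)  # beta -> 0: weights ~ equal
        a = make_volume(GRID, np.full(GRID.shape, 100.0), modality="CT")
        b = make_volume(GRID, np.full(GRID.shape, 200.0), modality="CT")
        out = fuse_intensity(wf, [a, b])
        assert np.allclose(out.values, 150.0, atol=1e-4)

    def test_matches_brute_force_oracle(self, rng):
        n = 8
        sims = random_stack(rng, n, invalid_frac=0.05)
        wf = weights_from_ranks(rank_atlases(sims), 0.7)
        cts = [make_volume(GRID, rng.normal(0, 300, GRID.shape), modality="CT") for _ in range(n)]
        out = fuse_intensity(wf, cts)
        expect = brute_fuse([wf.weights[k] for k in range(n)], [c.values for c in cts])
        fusable = wf.fusable
        assert np.allclose(out.values[fusable], expect[fusable], atol=1e-6, rtol=1e-9)

    def test_convex_combination_bounds(self, rng):
        n = 5
        sims = random_stack(rng, n)
        wf = weights_from_ranks(rank_atlases(sims), 0.5)
        cts = [make_volume(GRID, rng.normal(0, 300, GRID.shape), modality="CT") for _ in range(n)]
        out = fuse_intensity(wf, cts)
        lo = np.min([c.values for c in cts], axis=0)
        hi = np.max([c.values for c in cts], axis=0)
        assert np.all(out.values >= lo - 1e-4) and np.all(out.values <= hi + 1e-4)

    def test_beta_limits(self, rng):
        n = 4
        sims = random_stack(rng, n)
        rf = rank_atlases(sims)
        cts = [make_volume(GRID, rng.normal(0, 300, GRID.shape), modality="CT") for _ in range(n)]
        stack = np.stack([s.values for s in sims])
        best = np.argmax(stack, axis=0)
        best_vals = np.take_along_axis(np.stack([c.values for c in cts]), best[None], axis=0)[0]
        out_inf = fuse_intensity(weights_from_ranks(rf, 50.0), cts)
        assert np.allclose(out_inf.values, best_vals, atol=1e-6)
        out_zero = fuse_intensity(weights_from_ranks(rf, 1e-6), cts)
        assert np.allclose(out_zero.values, np.mean([c.values for c in cts], axis=0), atol=1e-3)

    def test_permutation_invariance(self, rng):
        n = 4
        sims = random_stack(rng, n)  # continuous values: ties have measure zero
        cts = [make_volume(GRID, rng.normal(0, 300, GRID.shape), modality="CT") for _ in range(n)]
        wf = weights_from_ranks(rank_atlases(sims), 0.8)
        out = fuse_intensity(wf, cts)
        perm = [2, 0, 3, 1]
        wf_p = weights_from_ranks(rank_atlases([sims[i] for i in perm]), 0.8)
        out_p = fuse_intensity(wf_p, [cts[i] for i in perm])
        assert np.allclose(out.values, out_p.values, atol=1e-5)

    def test_length_mismatch(self, rng):
        wf = weights_from_ranks(rank_atlases(random_stack(rng, 2)), 1.0)
        with pytest.raises(ValueError):
            fuse_intensity(wf, [make_volume(GRID, np.zeros(GRID.shape), modality="CT")])


class TestLabelFusion:
    def test_single_atlas_identity(self, rng):
        lab = rng.integers(0, 3, GRID.shape)
        seg = ProbSegVolume.from_labels(GRID, lab, 3)
        wf = weights_from_ranks(rank_atlases([sim_from_array(np.ones(GRID.shape))]), 1.0)
        out = fuse_labels(wf, [votes_from_seg(seg)])
        assert np.array_equal(out.probabilities, seg.probabilities)

    def test_two_way_tie_splits_half(self):
        a = ProbSegVolume.from_labels(GRID, np.full(GRID.shape, 1), 3)
        b = ProbSegVolume.from_labels(GRID, np.full(GRID.shape, 2), 3)
        sims = [sim_from_array(np.full(GRID.shape, 0.5)) for _ in range(2)]
        wf = weights_from_ranks(rank_atlases(sims), 1e-9)
        out = fuse_labels(wf, [votes_from_seg(a), votes_from_seg(b)])
        assert np.allclose(out.probabilities[..., 1], 0.5, atol=1e-6)
        assert np.allclose(out.probabilities[..., 2], 0.5, atol=1e-6)

    def test_matches_brute_force_oracle(self, rng):
        n, L = 6, 4
        sims = random_stack(rng, n, invalid_frac=0.05)
        wf = weights_from_ranks(rank_atlases(sims), 0.7)
        segs = [ProbSegVolume.from_labels(GRID, rng.integers(0, L, GRID.shape), L) for _ in range(n)]
        votes = [votes_from_seg(s) for s in segs]
        out = fuse_labels(wf, votes)
        num = sum(wf.weights[k][..., None] * votes[k] for k in range(n))
        den = num.sum(axis=-1, keepdims=True)
        fusable = wf.fusable
        expect = num / np.where(den > 0, den, 1.0)
        assert np.allclose(out.probabilities[fusable], expect[fusable], atol=1e-6)

    def test_output_is_simplex(self, rng):
        n = 4
        sims = random_stack(rng, n, invalid_frac=0.3)
        wf = weights_from_ranks(rank_atlases(sims), 1.0)
        segs = [ProbSegVolume.from_labels(GRID, rng.integers(0, 3, GRID.shape), 3) for _ in range(n)]
        out = fuse_labels(wf, [votes_from_seg(s) for s in segs])
        assert np.allclose(out.probabilities.sum(axis=-1), 1.0, atol=1e-6)

    def test_unfusable_becomes_background(self, rng):
        sims = random_stack(rng, 2)
        for s in sims:
            s.valid[0] = False
            s.values[0] = -np.inf
        wf = weights_from_ranks(rank_atlases(sims), 1.0)
        segs = [ProbSegVolume.from_labels(GRID, np.full(GRID.shape, 1), 3) for _ in range(2)]
        out = fuse_labels(wf, [votes_from_seg(s) for s in segs])
        assert np.all(out.probabilities[0, ..., 0] == 1.0)

    def test_non_one_hot_votes_rejected_in_strict_mode(self, rng):
        wf = weights_from_ranks(rank_atlases(random_stack(rng, 1)), 1.0)
        fuzzy = random_simplex_seg(GRID, rng, 3)
        with pytest.raises(ValueError):
            fuse_labels(wf, [votes_from_seg(fuzzy, one_hot=False)], require_one_hot=True)


class TestCategorical:
    def test_one_hot_round_trip(self, rng):
        lab = rng.integers(0, 4, GRID.shape)
        seg = ProbSegVolume.from_labels(GRID, lab, 4)
        assert np.array_equal(categorical_from_prob(seg).labels, lab)

    def test_tie_breaks_to_lower_label(self):
        p = np.zeros(GRID.shape + (3,), dtype=np.float32)
        p[..., 1] = 0.5
        p[..., 2] = 0.5
        seg = ProbSegVolume(GRID, p)
        assert np.all(categorical_from_prob(seg).labels == 1)

    def test_matches_argmax_oracle(self, rng):
        seg = random_simplex_seg(GRID, rng, 5)
        assert np.array_equal(categorical_from_prob(seg).labels, np.argmax(seg.probabilities, axis=-1))
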