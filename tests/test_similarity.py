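import numpy as np
import pytest

from atlasfusion.image_model import ImageGrid, ProbSegVolume
from atlasfusion.similarity import (
    EmptyFOVError,
    local_fuzzy_dice,
    lsim,
    normalized_moments,
    roi_ssim,
)

from conftest import brute_gaussian_conv, make_volume, random_simplex_seg, random_volume

SIGMA = 2.0


def oracle_moments(values, fov, sigma=SIGMA):
    om = fov.astype(float)
    den = brute_gaussian_conv(om, sigma)
    valid = den > 1e-12
    safe = np.where(valid, den, 1.0)
    mu = brute_gaussian_conv(np.where(fov, values, 0.0), sigma) / safe
    mu2 = brute_gaussian_conv(np.where(fov, values**2, 0.0), sigma) / safe
    return mu, np.maximum(mu2 - mu**2, 0.0), valid


class TestNormalizedMoments:
    def test_constant_full_fov(self, unit_grid):
        m = normalized_moments(make_volume(unit_grid, np.full(unit_grid.shape, 3.25)), SIGMA)
        assert np.allclose(m.mean, 3.25, atol=1e-9)
        assert np.allclose(m.variance, 0.0, atol=1e-9)

    def test_half_masked_constant(self, unit_grid):
        fov = np.zeros(unit_grid.shape, dtype=bool)
        fov[:6] = True
        m = normalized_moments(make_volume(unit_grid, np.full(unit_grid.shape, 2.0), fov), SIGMA)
        # density normalisation cancels the mask wherever any mass remains
        assert np.allclose(m.mean[m.valid], 2.0, atol=1e-9)

    def test_matches_brute_force_oracle(self, unit_grid, rng):
        fov = rng.random(unit_grid.shape) > 0.3
        vol = random_volume(unit_grid, rng, fov=fov)
        m = normalized_moments(vol, SIGMA)
        mu_o, var_o, valid_o = oracle_moments(vol.values, fov)
        assert np.array_equal(m.valid, valid_o)
        assert np.allclose(m.mean[m.valid], mu_o[valid_o], atol=1e-6)
        assert np.allclose(m.variance[m.valid], var_o[valid_o], atol=1e-6)

    def test_empty_fov_raises(self, unit_grid, rng):
        vol = random_volume(unit_grid, rng, fov=np.zeros(unit_grid.shape, dtype=bool))
        with pytest.raises(EmptyFOVError):
            normalized_moments(vol, SIGMA)


def oracle_roi_ssim(I, J, fovI, fovJ, C1, C2, sigma=SIGMA):
    omega = fovI & fovJ
    muI, varI, valid = oracle_moments(I, omega, sigma)
    muJ, varJ, _ = oracle_moments(J, omega, sigma)
    den = brute_gaussian_conv(omega.astype(float), sigma)
    safe = np.where(valid, den, 1.0)
    cov = brute_gaussian_conv(np.where(omega, I * J, 0.0), sigma) / safe - muI * muJ
    lum = (2 * muI * muJ + C1) / (muI**2 + muJ**2 + C1)
    struct = (2 * cov + C2) / (varI + varJ + C2)
    score = np.where(omega & valid, np.clip(lum * struct, -1, 1), -np.inf)
    return score, omega & valid


class TestRoiSsim:
    def test_self_similarity_is_one(self, unit_grid, rng):
        vol = random_volume(unit_grid, rng)
        s = roi_ssim(vol, vol, SIGMA, C1=1.0, C2=1.0)
        assert np.allclose(s.values[s.valid], 1.0, atol=1e-9)

    def test_constant_pair_closed_form(self, unit_grid):
        I = make_volume(unit_grid, np.ones(unit_grid.shape))
        J = make_volume(unit_grid, np.zeros(unit_grid.shape))
        s = roi_ssim(I, J, SIGMA, C1=0.5, C2=0.5)
        # structure term 1 (no variance), luminance C1/(1+C1)
        assert np.allclose(s.values[s.valid], 0.5 / 1.5, atol=1e-9)

    def test_matches_brute_force_oracle_with_fov(self, unit_grid, rng):
        fovI = rng.random(unit_grid.shape) > 0.2
        fovJ = rng.random(unit_grid.shape) > 0.2
        I = random_volume(unit_grid, rng, fov=fovI)
        J = random_volume(unit_grid, rng, fov=fovJ)
        s = roi_ssim(I, J, SIGMA, C1=2.0, C2=3.0)
        expect, valid = oracle_roi_ssim(I.values, J.values, fovI, fovJ, 2.0, 3.0)
        assert np.array_equal(s.valid, valid)
        assert np.all(s.values[~s.valid] == -np.inf)
        assert np.allclose(s.values[valid], expect[valid], atol=1e-6)

    def test_symmetry(self, unit_grid, rng):
        I = random_volume(unit_grid, rng)
        J = random_volume(unit_grid, rng)
        a = roi_ssim(I, J, SIGMA, C1=1.0, C2=1.0)
        b = roi_ssim(J, I, SIGMA, C1=1.0, C2=1.0)
        assert np.allclose(a.values[a.valid], b.values[b.valid], atol=1e-12)

    def test_far_voxel_has_no_influence(self, unit_grid, rng):
        # beyond the truncation radius a perturbation cannot reach the score
        I = random_volume(unit_grid, rng)
        J = random_volume(unit_grid, rng)
        base = roi_ssim(I, J, SIGMA, C1=1.0, C2=1.0).values[0, 0, 0]
        J2 = J.copy()
        J2.values[11, 11, 11] += 1000.0
        assert abs(roi_ssim(I, J2, SIGMA, C1=1.0, C2=1.0).values[0, 0, 0] - base) < 1e-9

    def test_bad_constants_rejected(self, unit_grid, rng):
        vol = random_volume(unit_grid, rng)
        with pytest.raises(ValueError):
            roi_ssim(vol, vol, SIGMA, C1=0.0, C2=1.0)


def oracle_ldsc(P, Q, sigma=SIGMA, start=1):
    score = np.zeros(P.shape[:3])
    for l in range(start, P.shape[-1]):
        a = brute_gaussian_conv(P[..., l], sigma)
        b = brute_gaussian_conv(Q[..., l], sigma)
        den = a + b
        score += np.where(den > 0, 2 * np.minimum(a, b) / np.where(den > 0, den, 1.0), 0.0)
    return score


class TestLocalFuzzyDice:
    def test_identical_segmentations_count_labels(self, unit_grid, rng):
        seg = random_simplex_seg(unit_grid, rng, 4)
        s = local_fuzzy_dice(seg, seg, SIGMA)
        # every non-background label has smoothed mass everywhere -> score = 3
        assert np.allclose(s.values, 3.0, atol=1e-9)

    def test_disjoint_labels_score_zero(self):
        g = ImageGrid((16, 8, 8), (1.0, 1.0, 1.0))
        a = np.zeros(g.shape, dtype=int)
        b = np.zeros(g.shape, dtype=int)
        a[:2, :2, :2] = 1
        b[14:, 6:, 6:] = 2
        sa = ProbSegVolume.from_labels(g, a, 3)
        sb = ProbSegVolume.from_labels(g, b, 3)
        s = local_fuzzy_dice(sa, sb, 1.0)
        # no shared label mass anywhere within the kernel support
        assert np.allclose(s.values, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, unit_grid, rng):
        a = random_simplex_seg(unit_grid, rng, 3)
        b = random_simplex_seg(unit_grid, rng, 3)
        s = local_fuzzy_dice(a, b, SIGMA)
        expect = oracle_ldsc(a.probabilities.astype(np.float64), b.probabilities.astype(np.float64))
        assert np.allclose(s.values, expect, atol=1e-6)

    def test_symmetry_and_range(self, unit_grid, rng):
        a = random_simplex_seg(unit_grid, rng, 5)
        b = random_simplex_seg(unit_grid, rng, 5)
        s1 = local_fuzzy_dice(a, b, SIGMA)
        s2 = local_fuzzy_dice(b, a, SIGMA)
        assert np.allclose(s1.values, s2.values, atol=1e-12)
        assert np.all(s1.values >= 0) and np.all(s1.values <= 4 + 1e-9)

    def test_label_count_mismatch(self, unit_grid, rng):
        with pytest.raises(ValueError):
            local_fuzzy_dice(random_simplex_seg(unit_grid, rng, 3), random_simplex_seg(unit_grid, rng, 4), SIGMA)


class TestLsim:
    def _channels(self, unit_grid, rng):
        t2 = random_volume(unit_grid, rng)
        t1 = random_volume(unit_grid, rng)
        pct = random_volume(unit_grid, rng, modality="pCT")
        seg = random_simplex_seg(unit_grid, rng, 3)
        j_t2 = random_volume(unit_grid, rng)
        j_t1 = random_volume(unit_grid, rng)
        j_ct = random_volume(unit_grid, rng, modality="CT")
        j_seg = random_simplex_seg(unit_grid, rng, 3)
        return t2, t1, pct, seg, j_t2, j_t1, j_ct, j_seg

    def test_first_iteration_ignores_ct_and_seg_channels(self, unit_grid, rng):
        t2, t1, pct, seg, j_t2, j_t1, j_ct, j_seg = self._channels(unit_grid, rng)
        with_extras = lsim(t2, t1, j_t2, j_t1, 1, target_pct=pct, target_seg=seg, j_ct=j_ct, j_seg=j_seg, sigma_g=SIGMA)
        without = lsim(t2, t1, j_t2, j_t1, 1, sigma_g=SIGMA)
        assert np.array_equal(with_extras.values, without.values)

    def test_compositional_oracle(self, unit_grid, rng):
        t2, t1, pct, seg, j_t2, j_t1, j_ct, j_seg = self._channels(unit_grid, rng)
        total = lsim(t2, t1, j_t2, j_t1, 2, target_pct=pct, target_seg=seg, j_ct=j_ct, j_seg=j_seg, sigma_g=SIGMA)
        parts = (
            roi_ssim(t2, j_t2, SIGMA).values
            + roi_ssim(t1, j_t1, SIGMA).values
            + roi_ssim(pct, j_ct, SIGMA).values
            + local_fuzzy_dice(seg, j_seg, SIGMA).values
        )
        assert np.allclose(total.values[total.valid], parts[total.valid], atol=1e-9)

    def test_self_similar_atlas_scores_three_plus_labels(self, unit_grid, rng):
        t2 = random_volume(unit_grid, rng)
        t1 = random_volume(unit_grid, rng)
        pct = random_volume(unit_grid, rng, modality="pCT")
        seg = random_simplex_seg(unit_grid, rng, 3)
        s = lsim(t2, t1, t2, t1, 2, target_pct=pct, target_seg=seg, j_ct=pct, j_seg=seg, sigma_g=SIGMA)
        # three unit self-similarities plus the 2 non-background label terms
        assert np.allclose(s.values[s.valid], 5.0, atol=1e-6)

    def test_invalid_channel_propagates_sentinel(self, unit_grid, rng):
        fov = np.ones(unit_grid.shape, dtype=bool)
        fov[:4] = False
        t2 = random_volume(unit_grid, rng, fov=fov)
        t1 = random_volume(unit_grid, rng)
        s = lsim(t2, t1, random_volume(unit_grid, rng), random_volume(unit_grid, rng), 1, sigma_g=SIGMA)
        assert np.all(s.values[:4] == -np.inf)
        assert np.all(~s.valid[:4])

    def test_missing_channels_at_t2_rejected(self, unit_grid, rng):
        t2 = random_volume(unit_grid, rng)
        with pytest.raises(ValueError):
            lsim(t2, t2, t2, t2, 2, sigma_g=SIGMA)
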