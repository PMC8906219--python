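import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from hybridreg.image_model import BinaryMask, Image3D
from hybridreg.similarity import (
    ForceField,
    joint_histogram,
    mean_abs_diff,
    mi,
    mi_force,
    mutual_information,
    ncc,
    ssd_force,
)


def brute_mi_nats(f, m, bins):
    """Independent oracle: explicit double loop over the joint histogram."""
    f, m = np.asarray(f, float).ravel(), np.asarray(m, float).ravel()
    ef = np.linspace(f.min(), f.max() if f.max() > f.min() else f.min() + 1, bins + 1)
    em = np.linspace(m.min(), m.max() if m.max() > m.min() else m.min() + 1, bins + 1)
    counts = np.zeros((bins, bins))
    for fv, mv in zip(f, m):
        i = min(np.searchsorted(ef, fv, side="right") - 1, bins - 1)
        j = min(np.searchsorted(em, mv, side="right") - 1, bins - 1)
        counts[i, j] += 1
    n = counts.sum()
    total = 0.0
    for i in range(bins):
        for j in range(bins):
            pij = counts[i, j] / n
            if pij > 0:
                total += pij * np.log(pij / (counts[i].sum() / n * counts[:, j].sum() / n))
    return total


def img(arr, **kw):
    return Image3D(np.asarray(arr, dtype=float), **kw)


class TestJointHistogram:
    def test_two_valued_diagonal(self):
        a = img([[[0.0, 1.0], [1.0, 0.0]]]).with_voxels(
            np.array([[[0.0, 1.0], [1.0, 0.0]]]))
        h = joint_histogram(a, a, bins=2)
        np.testing.assert_array_equal(h.counts, [[2, 0], [0, 2]])

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        a, b = img(rng.random((4, 5, 6))), img(rng.random((4, 5, 6)))
        h = joint_histogram(a, b, bins=8)
        assert h.n == 4 * 5 * 6
        assert h.marginal_fixed().sum() == h.n
        assert h.marginal_moving().sum() == h.n

    def test_masked_count(self):
        rng = np.random.default_rng(1)
        a, b = img(rng.random((4, 4, 4))), img(rng.random((4, 4, 4)))
        mvox = np.zeros((4, 4, 4), dtype=np.uint8)
        mvox[:2] = 1
        h = joint_histogram(a, b, bins=4, mask=BinaryMask(mvox))
        assert h.n == 32

    def test_empty_mask_rejected(self):
        a = img(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError, match="empty"):
            joint_histogram(a, a, bins=4, mask=BinaryMask(np.zeros((3, 3, 3), np.uint8)))

    def test_constant_image_degenerate_bin(self):
        a = img(np.full((3, 3, 3), 5.0))
        h = joint_histogram(a, a, bins=4)
        assert h.n == 27  # widened range keeps every sample binned

    def test_bins_minimum(self):
        a = img(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            joint_histogram(a, a, bins=1)


class TestMutualInformation:
    def test_constant_images_zero(self):
        a = img(np.full((3, 3, 3), 2.0))
        assert mi(a, a, bins=8) == pytest.approx(0.0, abs=1e-12)

    def test_identical_equiprobable_ln_b(self):
        # 4 equiprobable values, 4 bins -> MI = H = ln 4; cross-checked with
        # the brute-force oracle
        vals = np.repeat(np.arange(4.0), 4).reshape(4, 2, 2)
        a = img(vals)
        expected = brute_mi_nats(vals, vals, 4)
        assert expected == pytest.approx(np.log(4))
        assert mi(a, a, bins=4) == pytest.approx(expected, abs=1e-12)

    def test_independent_patterns_zero(self):
        # checkerboard vs stripes on 4x4x1: marginals balanced, joint uniform
        x, y = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        checker = ((x + y) % 2).astype(float)[..., None]
        stripes = (x % 2).astype(float)[..., None]
        assert brute_mi_nats(checker, stripes, 2) == pytest.approx(0.0, abs=1e-12)
        assert mi(img(checker), img(stripes), bins=2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random(self, rng):
        a = rng.random((5, 4, 3))
        b = rng.random((5, 4, 3))
        assert mi(img(a), img(b), bins=6) == pytest.approx(brute_mi_nats(a, b, 6), abs=1e-12)

    def test_symmetry_exact(self, rng):
        a, b = img(rng.random((4, 4, 4))), img(rng.random((4, 4, 4)))
        ha = joint_histogram(a, b, bins=8)
        assert mutual_information(ha) == mutual_information(ha.transposed())

    @given(hnp.arrays(np.float64, (3, 3, 3), elements=st.floats(0, 10)),
           hnp.arrays(np.float64, (3, 3, 3), elements=st.floats(0, 10)))
    @settings(max_examples=30, deadline=None)
    def test_nonnegative_and_bounded_by_entropies(self, a, b):
        from hybridreg.similarity import entropy_marginal
        h = joint_histogram(img(a), img(b), bins=4)
        v = mutual_information(h)
        assert v >= -1e-9
        assert v <= min(entropy_marginal(h, "fixed"), entropy_marginal(h, "moving")) + 1e-9

    def test_noise_never_increases_mi(self, rng):
        a = img(np.repeat(np.arange(8.0), 8).reshape(8, 4, 2))
        noisy = img(a.voxels + rng.normal(0, 1.0, a.shape))
        assert mi(a, noisy, bins=8) <= mi(a, a, bins=8) + 1e-9


class TestNCC:
    def test_self_correlation(self, rng):
        a = img(rng.random((4, 4, 4)))
        assert ncc(a, a) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        a = img(rng.random((4, 4, 4)))
        b = img(2.5 * a.voxels + 7.0)
        assert ncc(a, b) == pytest.approx(1.0)

    def test_negation(self, rng):
        a = img(rng.random((4, 4, 4)))
        assert ncc(a, img(-a.voxels)) == pytest.approx(-1.0)

    def test_constant_image_signalled(self):
        a = img(np.zeros((3, 3, 3)))
        b = img(np.arange(27.0).reshape(3, 3, 3))
        with pytest.raises(ValueError, match="constant"):
            ncc(a, b)


class TestMeanAbsDiff:
    def test_identical(self, rng):
        a = img(rng.random((4, 4, 4)))
        assert mean_abs_diff(a, a) == 0.0

    def test_constant_offset(self, rng):
        a = img(rng.random((4, 4, 4)))
        assert mean_abs_diff(a, img(a.voxels - 3.0)) == pytest.approx(3.0)

    def test_hand_computed_toy(self):
        a = img([[[1.0, 2.0], [3.0, 4.0]]])
        b = img([[[2.0, 2.0], [0.0, 8.0]]])
        assert mean_abs_diff(a, b) == pytest.approx((1 + 0 + 3 + 4) / 4)

    @given(hnp.arrays(np.float64, (2, 2, 2), elements=st.floats(-5, 5)),
           hnp.arrays(np.float64, (2, 2, 2), elements=st.floats(-5, 5)),
           hnp.arrays(np.float64, (2, 2, 2), elements=st.floats(-5, 5)))
    @settings(max_examples=30, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        assert mean_abs_diff(img(a), img(c)) <= (
            mean_abs_diff(img(a), img(b)) + mean_abs_diff(img(b), img(c)) + 1e-9)


class TestMIForce:
    def test_constant_moving_zero_force(self, phantom):
        fixed = phantom[0]
        flat = Image3D(np.full(fixed.shape, 3.0), fixed.spacing)
        f = mi_force(fixed, flat, bins=16)
        np.testing.assert_allclose(f.vectors, 0.0, atol=1e-12)

    def test_registered_force_statistically_centred_on_zero(self, phantom):
        # at perfect registration individual boundary forces are antisymmetric
        # and cancel: the net (vector-mean) force must be < 1% of the typical
        # per-voxel force after a 2-voxel shift
        fixed = phantom[0]
        shifted = Image3D(np.roll(fixed.voxels, 2, axis=0), fixed.spacing)
        net_reg = np.linalg.norm(
            mi_force(fixed, fixed, bins=32).vectors.reshape(-1, 3).mean(axis=0))
        typical_shift = mi_force(fixed, shifted, bins=32).magnitude().mean()
        assert net_reg < 0.01 * typical_shift

    def test_finite_difference_sign_agreement(self):
        # oracle: move one voxel's sampling position by +/-eps along an axis
        # and recompute total MI of the Parzen-smoothed joint density, with
        # the probed sample entering as a continuous Gaussian bump (the same
        # density model the analytic force differentiates); the sign of the
        # central-difference MI change must match the force component
        from scipy.ndimage import gaussian_filter, map_coordinates

        rng = np.random.default_rng(3)
        n = 32
        moving = gaussian_filter(rng.random((n, n, n)), 3.0)
        moving = (moving - moving.min()) / np.ptp(moving)
        fixed_arr = moving ** 2.0  # monotone remap: MI-friendly, SSD-hostile
        fixed, mimg = Image3D(fixed_arr), Image3D(moving)
        bins, sigma = 16, 1.0
        F = mi_force(fixed, mimg, bins=bins, parzen_sigma_bins=sigma)

        mag = F.magnitude()
        sel = np.argwhere(mag > np.median(mag))
        sel = sel[rng.choice(len(sel), size=60, replace=False)]

        lo_f, hi_f = fixed_arr.min(), fixed_arr.max()
        lo_m, hi_m = moving.min(), moving.max()
        bw_f, bw_m = (hi_f - lo_f) / bins, (hi_m - lo_m) / bins
        counts, _ = np.histogramdd(
            np.stack([fixed_arr.ravel(), moving.ravel()], 1), bins=bins,
            range=[(lo_f, hi_f), (lo_m, hi_m)])
        centres = np.arange(bins) + 0.5

        def bump(cf, cm):
            gf = np.exp(-0.5 * ((centres - cf) / sigma) ** 2)
            gm = np.exp(-0.5 * ((centres - cm) / sigma) ** 2)
            out = np.outer(gf, gm)
            return out / out.sum()

        def total_mi(dens):
            p = dens / dens.sum()
            pf = p.sum(1, keepdims=True)
            pm = p.sum(0, keepdims=True)
            nz = p > 0
            return np.sum(p[nz] * np.log(p[nz] / (pf * pm)[nz]))

        eps = 0.25  # voxels
        agree = total = 0
        for axis in range(3):
            for vox in sel:
                x, y, z = vox
                comp = F.vectors[x, y, z, axis]
                if comp == 0:
                    continue
                cf = (fixed_arr[x, y, z] - lo_f) / bw_f
                hard = counts.copy()
                i = min(int(cf), bins - 1)
                j = min(int((moving[x, y, z] - lo_m) / bw_m), bins - 1)
                hard[i, j] -= 1  # probe sample leaves the hard histogram
                base = gaussian_filter(hard, sigma, mode="constant")
                deltas = []
                for sgn in (+1, -1):
                    pos = np.array([[x], [y], [z]], float)
                    pos[axis] += sgn * eps
                    newval = map_coordinates(moving, pos, order=1, mode="nearest")[0]
                    cm = (newval - lo_m) / bw_m
                    deltas.append(total_mi(base + bump(cf, cm)))
                dmi = deltas[0] - deltas[1]  # central difference along +axis
                if dmi != 0:
                    total += 1
                    agree += (np.sign(dmi) == np.sign(comp))
        assert total > 100
        assert agree / total >= 0.95

    def test_rejects_few_bins(self, phantom):
        with pytest.raises(ValueError):
            mi_force(phantom[0], phantom[0], bins=4)


class TestSSDForce:
    def test_identical_images_zero(self, rng):
        a = img(rng.random((6, 6, 6)))
        np.testing.assert_allclose(ssd_force(a, a).vectors, 0.0, atol=1e-12)

    def test_points_downhill_on_ramp(self):
        # fixed is the moving shifted towards +x: force must point -x where
        # fixed < moving (so sampling moves towards larger moving values)
        base = np.linspace(0, 1, 10)[:, None, None] * np.ones((10, 4, 4))
        fixed, moving = img(base), img(base + 0.2)
        f = ssd_force(fixed, moving)
        assert np.all(f.vectors[1:-1, :, :, 0] < 0)
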