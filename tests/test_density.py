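"""Image quantification chain: closed forms, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from octa_density import (
    DensityParams,
    EnFaceAngiogram,
    QCRejectionError,
    SkeletonMask,
    VesselMask,
    binarize,
    clean_mask,
    compute_densities,
    equalize_histogram,
    estimate_noise_floor,
    generate_vessel_network,
    hessian_vesselness,
    perfusion_density,
    qc_admit,
    remove_projection_tails,
    resample_canonical,
    skeletonize_mask,
    vessel_density,
)

FAST = DensityParams(canonical_size=256)


def _angio(pixels, **kw):
    return EnFaceAngiogram(pixels=np.asarray(pixels, float), **kw)


def _rng_image(seed, n=64):
    return np.random.default_rng(seed).uniform(size=(n, n))


class TestQC:
    @pytest.mark.parametrize(
        "strength,admitted", [(8, True), (10, True), (7, False), (0, False), (None, True)]
    )
    def test_signal_strength_gate(self, strength, admitted):
        img = _angio(np.zeros((64, 64)), signal_strength=strength)
        assert qc_admit(img) is admitted


class TestEqualization:
    def test_constant_image_stays_constant(self):
        out = equalize_histogram(_angio(np.full((64, 64), 0.3)))
        assert np.ptp(out.pixels) == 0.0

    def test_two_level_image_maps_to_cdf_values(self):
        # half zeros, half ones: empirical CDF is 0.5 at the low level, 1.0
        # at the high level
        px = np.zeros((64, 64))
        px[:, 32:] = 1.0
        out = equalize_histogram(_angio(px))
        assert np.allclose(np.unique(out.pixels), [0.5, 1.0])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_rank_order_preserved(self, seed):
        px = _rng_image(seed)
        out = equalize_histogram(_angio(px)).pixels
        i = np.argsort(px, axis=None)
        assert np.all(np.diff(out.flat[i]) >= -1e-12)


def _brute_force_vesselness(pixels, scales, beta=0.5, gamma_rel=2.0):
    """Finite-difference oracle: smooth, differentiate twice, eigensolve."""
    out = np.zeros_like(pixels)
    for sigma in scales:
        sm = ndimage.gaussian_filter(pixels, sigma)
        gy, gx = np.gradient(sm)
        hyy, hyx = np.gradient(gy)
        hxy, hxx = np.gradient(gx)
        resp = np.zeros_like(pixels)
        s_all = np.zeros_like(pixels)
        l1m = np.zeros_like(pixels)
        l2m = np.zeros_like(pixels)
        for idx in np.ndindex(pixels.shape):
            H = sigma**2 * np.array(
                [[hyy[idx], 0.5 * (hyx[idx] + hxy[idx])],
                 [0.5 * (hyx[idx] + hxy[idx]), hxx[idx]]]
            )
            ev = np.linalg.eigvalsh(H)
            l1, l2 = sorted(ev, key=abs)
            l1m[idx], l2m[idx] = l1, l2
            s_all[idx] = np.hypot(l1, l2)
        gamma = gamma_rel * s_all.max() if s_all.max() > 0 else 1.0
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2m != 0, (l1m / l2m) ** 2, 0.0)
        resp = np.exp(-rb2 / (2 * beta**2)) * (1 - np.exp(-s_all**2 / (2 * gamma**2)))
        resp[l2m >= 0] = 0.0
        out = np.maximum(out, resp)
    peak = out.max()
    return out / peak if peak > 0 else out


class TestVesselness:
    def test_constant_image_gives_zero_response(self):
        resp = hessian_vesselness(_angio(np.full((64, 64), 0.7)))
        assert np.all(resp == 0.0)

    def test_empty_scale_list_rejected(self):
        with pytest.raises(ValueError):
            hessian_vesselness(_angio(np.zeros((64, 64))), scales_px=[])

    def test_straight_ridge_against_finite_difference_oracle(self):
        # Gaussian-profile ridge extruded along columns
        y = np.arange(64)[:, None]
        px = np.exp(-((y - 32.0) ** 2) / (2 * 2.0**2)) * np.ones((1, 64))
        resp = hessian_vesselness(px, scales_px=(1.5, 2.0))
        oracle = _brute_force_vesselness(px, scales=(1.5, 2.0))
        interior = resp[5:-5, 5:-5]
        # the centerline row carries the maximal response in every column
        assert np.all(np.argmax(interior, axis=0) == 32 - 5)
        assert np.all(np.argmax(oracle[5:-5, 5:-5], axis=0) == 32 - 5)
        # the two constructions agree pointwise away from the border
        assert np.max(np.abs(interior - oracle[5:-5, 5:-5])) < 0.08

    def test_response_invariant_under_quarter_rotation(self):
        px = _rng_image(1)
        a = hessian_vesselness(px)
        b = hessian_vesselness(np.rot90(px))
        assert np.allclose(np.rot90(a), b, atol=1e-6)

    def test_response_in_unit_interval(self):
        resp = hessian_vesselness(_rng_image(2))
        assert resp.min() >= 0.0 and resp.max() <= 1.0


class TestNoiseFloor:
    def test_all_zero_response_gives_zero(self):
        assert estimate_noise_floor(np.zeros((10, 10)), FAST) == 0.0

    def test_bimodal_toy_grid(self):
        # 75 background zeros and 25 saturated pixels: the background
        # candidate set is the zeros, whose 95th percentile is 0
        resp = np.zeros(100)
        resp[:25] = 1.0
        assert estimate_noise_floor(resp.reshape(10, 10), FAST) == 0.0

    def test_degenerate_constant_response(self):
        assert estimate_noise_floor(np.full((8, 8), 0.4), FAST) == pytest.approx(0.4)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_threshold_bounded_by_response(self, seed):
        resp = _rng_image(seed, 16)
        thr = estimate_noise_floor(resp, FAST)
        assert 0.0 <= thr <= resp.max()


class TestBinarizeAndClean:
    def test_threshold_extremes(self):
        resp = _rng_image(3) * 0.99
        assert binarize(resp, 1.0).mask.sum() == 0
        assert binarize(resp, 0.0).mask.sum() == (resp > 0).sum()

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6), st.floats(0, 1), st.floats(0, 1))
    def test_raising_threshold_never_adds_pixels(self, seed, t1, t2):
        lo, hi = sorted((t1, t2))
        resp = _rng_image(seed, 16)
        assert not np.any(binarize(resp, hi).mask & ~binarize(resp, lo).mask)

    def test_small_components_removed(self):
        m = np.zeros((32, 32), dtype=bool)
        m[2, 2] = True  # single isolated pixel
        m[10, 5:25] = True  # 20-pixel line
        out = clean_mask(VesselMask(m), min_component_px=10)
        assert not out.mask[2, 2]
        assert out.mask[10, 5:25].all()

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_clean_idempotent(self, seed):
        m = np.random.default_rng(seed).uniform(size=(32, 32)) > 0.6
        once = clean_mask(VesselMask(m))
        twice = clean_mask(once)
        assert np.array_equal(once.mask, twice.mask)


class TestProjectionTailRemoval:
    def test_empty_scp_mask_is_identity(self):
        dcp = _angio(_rng_image(4), plexus="DCP")
        scp = _angio(_rng_image(5))
        empty = VesselMask(np.zeros((64, 64), dtype=bool))
        out = remove_projection_tails(dcp, scp, empty)
        assert np.array_equal(out.pixels, dcp.pixels)

    def test_fitted_gain_recovers_pure_projection(self):
        scp_px = _rng_image(6) * 0.9 + 0.05
        alpha = 0.37
        dcp = _angio(alpha * scp_px, plexus="DCP")
        scp = _angio(scp_px)
        mask = VesselMask(scp_px > 0.5)
        out = remove_projection_tails(dcp, scp, mask)
        assert np.allclose(out.pixels[mask.mask], 0.0, atol=1e-12)
        assert np.array_equal(out.pixels[~mask.mask], dcp.pixels[~mask.mask])

    def test_never_brightens_any_pixel(self):
        dcp = _angio(_rng_image(7), plexus="DCP")
        scp = _angio(_rng_image(8))
        mask = VesselMask(_rng_image(9) > 0.4)
        out = remove_projection_tails(dcp, scp, mask)
        assert np.all(out.pixels <= dcp.pixels + 1e-12)

    def test_geometry_mismatch_rejected(self):
        dcp = _angio(np.zeros((64, 64)), plexus="DCP")
        scp = _angio(np.zeros((96, 96)))
        with pytest.raises(ValueError):
            remove_projection_tails(dcp, scp, VesselMask(np.zeros((96, 96), bool)))


class TestResampling:
    def test_identity_at_target_size(self):
        img = _angio(_rng_image(10, 128))
        out = resample_canonical(img, 128)
        assert np.array_equal(out.pixels, img.pixels)

    def test_upsampling_preserves_fov(self):
        img = _angio(_rng_image(11, 100), fov_mm=6.0)
        out = resample_canonical(img, 256)
        assert out.pixels.shape == (256, 256)
        assert out.fov_mm == 6.0

    def test_constant_image_stays_constant(self):
        out = resample_canonical(_angio(np.full((100, 100), 0.25)), 256)
        assert np.allclose(out.pixels, 0.25)


class TestDensityMeasures:
    def test_perfusion_closed_forms(self):
        full = VesselMask(np.ones((64, 64), dtype=bool))
        empty = VesselMask(np.zeros((64, 64), dtype=bool))
        half = np.zeros((64, 64), dtype=bool)
        half[:32] = True
        assert perfusion_density(full) == 1.0
        assert perfusion_density(empty) == 0.0
        assert perfusion_density(VesselMask(half)) == 0.5

    def test_perfusion_region_restriction(self):
        m = np.zeros((64, 64), dtype=bool)
        m[:16] = True
        region = np.zeros((64, 64), dtype=bool)
        region[:32] = True
        assert perfusion_density(VesselMask(m), region) == 0.5
        with pytest.raises(ValueError):
            perfusion_density(VesselMask(m), np.zeros((64, 64), dtype=bool))

    def test_skeleton_of_bar_is_single_centerline(self):
        bar = np.zeros((64, 64), dtype=bool)
        bar[30:35, 2:62] = True  # 5 px wide, 60 px long
        skel = skeletonize_mask(VesselMask(bar)).skeleton
        assert not np.any(skel & ~bar)  # skeleton within the mask
        # brute-force medial axis: the row of maximal distance-to-border
        dist = ndimage.distance_transform_edt(bar)
        assert set(np.nonzero(skel[:, 10:54].sum(axis=1))[0]) <= set(
            np.nonzero(dist[:, 32] == dist[:, 32].max())[0]
        )
        # away from the bar ends, each column holds exactly one skeleton
        # pixel, on one of the medial rows
        mid = skel[:, 10:54]
        assert np.all(mid.sum(axis=0) == 1)
        assert set(np.nonzero(mid.any(axis=1))[0]) <= {31, 32, 33}
        assert 54 <= skel.sum() <= 62  # total length = bar length +/- ends

    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize_mask(VesselMask(np.zeros((64, 64), dtype=bool)))
        assert skel.skeleton.sum() == 0
        assert vessel_density(skel) == 0.0

    def test_straight_line_vessel_density(self):
        # one horizontal centerline across a 6 mm field: 6 mm of vessel in
        # 36 mm^2, i.e. 1/6 mm/mm^2 up to the (W-1)/W link convention
        skel = np.zeros((500, 500), dtype=bool)
        skel[250] = True
        mvd = vessel_density(SkeletonMask(skel, fov_mm=6.0))
        assert mvd == pytest.approx(1 / 6, rel=0.005)

    def test_disjoint_branch_only_adds_length(self):
        s1 = np.zeros((128, 128), dtype=bool)
        s1[30] = True
        s2 = s1.copy()
        s2[90, 10:50] = True
        assert vessel_density(SkeletonMask(s2)) > vessel_density(SkeletonMask(s1))

    def test_diagonal_links_count_sqrt2(self):
        diag = np.eye(64, dtype=bool)
        mvd_diag = vessel_density(SkeletonMask(diag, fov_mm=6.0))
        expected = 63 * np.sqrt(2) * (6.0 / 64) / 36.0
        assert mvd_diag == pytest.approx(expected)

    def test_pixel_count_mode_rescales(self):
        skel = np.zeros((128, 128), dtype=bool)
        skel[40, 10:100] = True
        sm = SkeletonMask(skel)
        assert vessel_density(sm, "pixel_count") == pytest.approx(
            90 * sm.pixel_mm / 36.0
        )


class TestFullChain:
    def test_qc_failure_rejects_pair(self):
        bad = _angio(np.zeros((64, 64)), signal_strength=5)
        good = _angio(np.zeros((64, 64)), plexus="DCP")
        with pytest.raises(QCRejectionError):
            compute_densities(bad, good, FAST)

    def test_blank_images_give_zero_density(self):
        scp = _angio(np.zeros((128, 128)))
        dcp = _angio(np.zeros((128, 128)), plexus="DCP")
        res_scp, res_dcp = compute_densities(scp, dcp, FAST)
        assert res_scp.mpd == 0.0 and res_scp.mvd == 0.0
        assert res_dcp.mpd == 0.0 and res_dcp.mvd == 0.0

    def test_network_density_recovered_on_small_grid(self, small_network):
        scp = _angio(small_network.image)
        dcp_t = generate_vessel_network(
            17, grid=(128, 128), n_seeds=20,
            branch_params={"max_branches": 50}, noise_level=0.0, plexus="DCP",
        )
        dcp = _angio(dcp_t.image, plexus="DCP")
        res_scp, res_dcp = compute_densities(scp, dcp, FAST)
        assert abs(res_scp.mpd - 100 * small_network.truth_mpd) <= 8.0
        assert res_dcp.mpd > 0
        assert res_scp.region_area_mm2 == pytest.approx(36.0)
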