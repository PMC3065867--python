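"""Reconstruction tests: subset construction, the OSEM/OSL updates against
hand-enumerated system matrices, penalty factors against naive triple-loop
references, and post-filtering."""

import math

import numpy as np
import pytest

from spectrecon.projector import CollimatorModel, ProjectionSet, Volume
from spectrecon.recon import (
    PriorConfig,
    ReconConfig,
    bowsher_penalty_factor,
    bowsher_select,
    gaussian_postfilter,
    make_subsets,
    mrp_penalty_factor,
    neighbourhood_median,
    neighbourhood_offsets,
    osem_update,
    osl_update,
    run_reconstruction,
    smoothing_penalty_factor,
    weighted_neighbour_mean,
)

from conftest import compact_random_volume, make_geometry, make_model
from oracles import naive_median, naive_weighted_mean, toy_2x2_system

SP1 = (1.0, 1.0, 1.0)


class TestMakeSubsets:
    def test_interleaved_partition_128_16(self):
        scheme = make_subsets(128, 16)
        assert scheme.n_subsets == 16
        for s in scheme.subsets:
            assert len(s) == 8
            assert all(b - a == 16 for a, b in zip(s, s[1:]))
        flat = sorted(i for s in scheme.subsets for i in s)
        assert flat == list(range(128))

    def test_single_subset_is_mlem(self):
        scheme = make_subsets(8, 1)
        assert scheme.subsets == [list(range(8))]

    def test_non_divisor_rejected_with_divisor_list(self):
        with pytest.raises(ValueError, match=r"valid subset counts.*\b4\b"):
            make_subsets(8, 3)

    def test_bit_reversal_processing_order(self):
        scheme = make_subsets(32, 4)
        assert [s[0] for s in scheme.subsets] == [0, 2, 1, 3]


class TestOsemUpdate:
    def test_fixed_point_on_noiseless_data(self, rng):
        truth = compact_random_volume((3, 12, 12), rng)
        truth.data += 0.1 * truth.data.max()  # strictly positive
        model = make_model(truth.shape, n_angles=6)
        p = ProjectionSet(model.forward(truth.data), model.geom, model.geom.angles_deg)
        new = osem_update(truth, p, list(range(6)), model)
        np.testing.assert_allclose(new.data, truth.data, rtol=1e-6)

    def test_zero_projections_zero_image(self, rng):
        f = Volume(np.ones((2, 8, 8)), SP1)
        model = make_model(f.shape, n_angles=4)
        p = ProjectionSet(np.zeros((4, 2, 8)), model.geom, model.geom.angles_deg)
        new = osem_update(f, p, list(range(4)), model)
        assert np.all(new.data == 0.0)

    def test_matches_hand_enumerated_matrix(self, rng):
        geom, model, A = toy_2x2_system()
        f_old = rng.random(4) + 0.5
        p_meas = rng.random(4) * 3.0
        # sanity: the operator agrees with the enumerated matrix
        np.testing.assert_allclose(
            model.forward(f_old.reshape(1, 2, 2)).ravel(), A @ f_old, atol=1e-12
        )
        # brute-force OSEM update from the matrix form
        for subset, bins in [([0], [0, 1]), ([1], [2, 3]), ([0, 1], [0, 1, 2, 3])]:
            q = A @ f_old
            expected = np.array(
                [
                    f_old[j]
                    / sum(A[i, j] for i in bins)
                    * sum(A[i, j] * p_meas[i] / q[i] for i in bins)
                    if sum(A[i, j] for i in bins) > 0
                    else 0.0
                    for j in range(4)
                ]
            )
            got = osem_update(
                Volume(f_old.reshape(1, 2, 2), SP1),
                ProjectionSet(p_meas.reshape(2, 1, 2), geom, geom.angles_deg),
                subset,
                model,
            )
            np.testing.assert_allclose(got.data.ravel(), expected, rtol=1e-10)


class TestPenaltyFactors:
    def test_uniform_image_reduces_to_osem_factor(self, rng):
        f = Volume(np.full((4, 4, 4), 2.5), SP1)
        sens = rng.random((4, 4, 4)) + 0.5
        prior = PriorConfig(prior_type="smooth", beta=0.3)
        smooth = smoothing_penalty_factor(f, prior, sens, 1e-8)
        np.testing.assert_allclose(smooth, 1.0 / sens, rtol=1e-12)
        prior_m = PriorConfig(prior_type="mrp", beta=0.3)
        np.testing.assert_allclose(
            mrp_penalty_factor(f, prior_m, sens, 1e-8), 1.0 / sens, rtol=1e-15
        )

    def test_smoothing_matches_naive_reference(self, rng):
        f = rng.random((8, 8, 8)) + 0.1
        sens = rng.random((8, 8, 8)) + 0.5
        prior = PriorConfig(prior_type="smooth", beta=0.4)
        got = smoothing_penalty_factor(Volume(f, SP1), prior, sens, 1e-8)
        A = naive_weighted_mean(f)
        expected = 1.0 / (sens + 0.4 * (f - A) / np.maximum(A, 1e-8))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_mrp_matches_naive_reference(self, rng):
        f = rng.random((8, 8, 8))
        sens = rng.random((8, 8, 8)) + 0.5
        prior = PriorConfig(prior_type="mrp", beta=0.3)
        got = mrp_penalty_factor(Volume(f, SP1), prior, sens, 1e-8)
        M = naive_median(f)
        expected = 1.0 / (sens + 0.3 * (f - M) / np.maximum(M, 1e-8))
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_mrp_window_median_of_1_to_27(self):
        f = np.arange(1.0, 28.0).reshape(3, 3, 3)
        M = neighbourhood_median(f)
        assert M[1, 1, 1] == 14.0

    def test_mrp_penalty_vanishes_on_monotone_ramp(self):
        f = np.tile(np.arange(1.0, 9.0)[None, None, :], (5, 5, 1))
        M = neighbourhood_median(f)
        np.testing.assert_allclose(M[1:-1, 1:-1, 1:-1], f[1:-1, 1:-1, 1:-1])


class TestBowsher:
    def test_uniform_anatomy_selects_closest_by_tiebreak(self):
        ana = Volume(np.zeros((5, 5, 5)), SP1)
        prior = PriorConfig(prior_type="bowsher", bowsher_B=9, anatomical=ana)
        sel = bowsher_select(ana, prior)
        # all anatomical differences equal -> stable sort keeps the
        # (distance, lexicographic) pre-ordering: first 9 of the scanned 18
        assert np.all(sel.mask[:9, 2, 2, 2])
        assert not np.any(sel.mask[9:, 2, 2, 2])

    def test_step_edge_selects_same_side(self):
        ana_data = np.zeros((3, 3, 6))
        ana_data[:, :, 3:] = 1000.0
        ana = Volume(ana_data, SP1)
        prior = PriorConfig(prior_type="bowsher", bowsher_B=6, anatomical=ana)
        sel = bowsher_select(ana, prior)
        # voxel just left of the edge must select only same-side neighbours
        for k, off in enumerate(sel.offsets):
            if sel.mask[k, 1, 1, 2]:
                assert 2 + off[2] <= 2, f"selected cross-edge offset {off}"

    def test_scan_count_selection_keeps_everything(self):
        ana = Volume(np.zeros((4, 4, 4)), SP1)
        prior = PriorConfig(prior_type="bowsher", bowsher_scan=18, bowsher_B=18,
                            anatomical=ana)
        sel = bowsher_select(ana, prior)
        assert np.all(sel.mask[:, 1:-1, 1:-1, 1:-1])

    def test_uniform_anatomy_full_b_reduces_to_smoothing(self, rng):
        f = Volume(rng.random((6, 6, 6)) + 0.1, SP1)
        sens = rng.random((6, 6, 6)) + 0.5
        ana = Volume(np.zeros((6, 6, 6)), SP1)
        prior = PriorConfig(prior_type="bowsher", beta=0.3, bowsher_scan=18,
                            bowsher_B=18, anatomical=ana)
        sel = bowsher_select(ana, prior)
        got = bowsher_penalty_factor(f, prior, sel, sens, 1e-8)
        smooth_prior = PriorConfig(prior_type="smooth", beta=0.3)
        offsets = neighbourhood_offsets(3)[:18]
        expected = smoothing_penalty_factor(f, smooth_prior, sens, 1e-8, offsets=offsets)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_matches_naive_reference_across_edge(self, rng):
        ana_data = np.zeros((4, 4, 4))
        ana_data[:, :, 2:] = 500.0
        f = rng.random((4, 4, 4)) + 0.1
        sens = np.ones((4, 4, 4))
        ana = Volume(ana_data, SP1)
        prior = PriorConfig(prior_type="bowsher", beta=0.3, bowsher_scan=6,
                            bowsher_B=3, anatomical=ana)
        sel = bowsher_select(ana, prior)
        got = bowsher_penalty_factor(Volume(f, SP1), prior, sel, sens, 1e-8)
        # naive: same-rule selection with explicit sort per voxel
        offsets = sel.offsets
        A = np.zeros_like(f)
        for z in range(4):
            for y in range(4):
                for x in range(4):
                    cands = []
                    for k, (dz, dy, dx) in enumerate(offsets):
                        zz, yy, xx = z + dz, y + dy, x + dx
                        if 0 <= zz < 4 and 0 <= yy < 4 and 0 <= xx < 4:
                            cands.append(
                                (abs(ana_data[zz, yy, xx] - ana_data[z, y, x]), k)
                            )
                    cands.sort()
                    keep = [k for _, k in cands[:3]]
                    num = den = 0.0
                    for k in keep:
                        dz, dy, dx = offsets[k]
                        w = 1.0 / math.sqrt(dz**2 + dy**2 + dx**2)
                        num += w * f[z + dz, y + dy, x + dx]
                        den += w
                    A[z, y, x] = num / den
        expected = 1.0 / (1.0 + 0.3 * (f - A) / np.maximum(A, 1e-8))
        np.testing.assert_allclose(got, expected, atol=1e-12)


class TestOslUpdate:
    def test_beta_zero_is_bitwise_osem(self, rng):
        f = compact_random_volume((3, 10, 10), rng)
        f.data += 0.05
        model = make_model(f.shape, n_angles=6)
        p = ProjectionSet(
            model.forward(f.data) + rng.random((6, 3, 10)),
            model.geom,
            model.geom.angles_deg,
        )
        subset = [0, 3]
        a = osem_update(f, p, subset, model)
        b = osl_update(f, p, subset, model, PriorConfig(prior_type="smooth", beta=0.0))
        assert np.array_equal(a.data, b.data)
        c = osl_update(f, p, subset, model, PriorConfig(prior_type="none"))
        assert np.array_equal(a.data, c.data)

    def test_uniform_fixed_point_with_priors(self, rng):
        # uniform activity reproducing its own projections: both factors
        # are neutral for every prior
        f = Volume(np.full((2, 8, 8), 1.5), SP1)
        model = make_model(f.shape, n_angles=4)
        p = ProjectionSet(model.forward(f.data), model.geom, model.geom.angles_deg)
        for ptype in ("smooth", "mrp"):
            new = osl_update(f, p, [0, 1, 2, 3], model,
                             PriorConfig(prior_type=ptype, beta=0.3))
            np.testing.assert_allclose(new.data, f.data, rtol=1e-9)

    def test_matches_hand_evaluation_with_smoothing_prior(self, rng):
        geom, model, A = toy_2x2_system()
        f_old = rng.random(4) + 0.5
        p_meas = rng.random(4) * 2.0 + 0.5
        beta = 0.3
        subset, bins = [0], [0, 1]
        q = A @ f_old
        f_img = f_old.reshape(1, 2, 2)
        # hand evaluation: c_L and the relative smoothing penalty factor
        sens = np.array([sum(A[i, j] for i in bins) for j in range(4)])
        c_l = np.array([sum(A[i, j] * p_meas[i] / q[i] for i in bins) for j in range(4)])
        Aj = naive_weighted_mean(f_img).ravel()
        c_p = 1.0 / (sens + beta * (f_old - Aj) / np.maximum(Aj, 1e-8))
        expected = f_old * c_p * c_l
        got = osl_update(
            Volume(f_img, SP1),
            ProjectionSet(p_meas.reshape(2, 1, 2), geom, geom.angles_deg),
            subset,
            model,
            PriorConfig(prior_type="smooth", beta=beta),
        )
        np.testing.assert_allclose(got.data.ravel(), expected, rtol=1e-10)

    def test_updates_stay_nonnegative(self, rng):
        f = Volume(rng.random((2, 8, 8)) + 1e-3, SP1)
        model = make_model(f.shape, n_angles=4)
        p = ProjectionSet(
            rng.poisson(3.0, (4, 2, 8)).astype(float), model.geom, model.geom.angles_deg
        )
        for ptype, beta in [("none", 0.0), ("smooth", 0.9), ("mrp", 0.9)]:
            new = osl_update(f, p, [0, 2], model, PriorConfig(prior_type=ptype, beta=beta))
            assert np.all(new.data >= 0.0)


class TestRunReconstruction:
    def test_beta_zero_osl_run_equals_osem_run(self, rng):
        f = compact_random_volume((2, 12, 12), rng)
        model = make_model(f.shape, n_angles=8)
        p_data = rng.poisson(np.maximum(model.forward(f.data), 0) + 1.0).astype(float)
        p = ProjectionSet(p_data, model.geom, model.geom.angles_deg)
        kw = dict(n_iterations=2, n_subsets=4, grid_shape=f.shape, spacing=f.spacing,
                  collimator=CollimatorModel(enabled=False))
        a = run_reconstruction(p, ReconConfig(prior=PriorConfig("none"), **kw))
        b = run_reconstruction(p, ReconConfig(prior=PriorConfig("smooth", beta=0.0), **kw))
        assert np.array_equal(a.data, b.data)

    def test_mlem_likelihood_non_decreasing_small(self, rng):
        truth = compact_random_volume((2, 16, 16), rng)
        model = make_model(truth.shape, n_angles=12)
        clean = model.forward(truth.data)
        noisy = rng.poisson(clean * (2000.0 / clean.sum())).astype(float)
        p = ProjectionSet(noisy, model.geom, model.geom.angles_deg)
        cfg = ReconConfig(n_iterations=15, n_subsets=1, prior=PriorConfig("none"),
                          collimator=CollimatorModel(enabled=False),
                          grid_shape=truth.shape, spacing=truth.spacing)
        out = run_reconstruction(p, cfg)
        ll = [r["log_likelihood"] for r in out.meta["log"]]
        assert len(ll) == 15
        diffs = np.diff(ll)
        assert np.all(diffs >= -1e-7 * np.abs(ll[0]))


class TestPostfilter:
    def test_zero_fwhm_identity(self, rng):
        v = Volume(rng.random((3, 5, 5)), SP1)
        assert np.array_equal(gaussian_postfilter(v, 0.0).data, v.data)

    def test_fwhm_sigma_conversion_via_second_moment(self):
        n = 41
        data = np.zeros((n, n, n))
        data[n // 2, n // 2, n // 2] = 1.0
        fwhm = 2.3548200450309493  # sigma = 1 voxel
        out = gaussian_postfilter(Volume(data, SP1), fwhm).data
        i = np.arange(n) - n // 2
        var = np.sum(out * (i**2)[:, None, None])
        assert var == pytest.approx(1.0, rel=0.01)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            gaussian_postfilter(Volume(np.ones((2, 2, 2)), SP1), -1.0)
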