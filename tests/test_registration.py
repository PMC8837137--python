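import numpy as np
import pytest

from bonereg.geometry import (
    Point3Set,
    RigidTransform,
    apply_transform,
    compose,
    invert,
    rotation_about_axis,
    transform_discrepancy,
)
from bonereg.registration import (
    CpdConfig,
    RegistrationError,
    RigidCPD,
    cpd_posteriors,
    farthest_point_sampling,
    fiducial_registration_error,
    fit_rigid_corresponding,
    register_model_to_model,
    register_model_to_points,
    rigid_cpd,
)
from bonereg.synthetic import OperatorModel, perturb_segmentation, simulate_operator_points
from conftest import random_rigid

ZERO_NOISE = OperatorModel(0.0, 0.0)


def brute_force_posteriors(moving, fixed, sigma2, w):
    """Direct evaluation of the mixture responsibilities."""
    m, n = len(moving), len(fixed)
    P = np.empty((m, n))
    for i in range(m):
        for j in range(n):
            d2 = np.sum((moving[i] - fixed[j]) ** 2)
            P[i, j] = np.exp(-d2 / (2 * sigma2))
    c = (2 * np.pi * sigma2) ** 1.5 * w / (1 - w) * m / n
    return P / (P.sum(axis=0) + c)


class TestCpdCore:
    def test_identical_sets_give_identity(self, rng):
        pts = Point3Set(rng.normal(0, 10, (50, 3)))
        res = rigid_cpd(pts, pts, CpdConfig(outlier_weight=0.0))
        # matrix-level check: the angle extraction itself has an ~1e-6 deg
        # arccos noise floor even for numerically exact rotations
        assert np.abs(res.transform.rotation - np.eye(3)).max() < 1e-9
        assert np.linalg.norm(res.transform.translation) < 1e-6

    def test_equidistant_point_splits_posteriors(self):
        moving = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        fixed = np.array([[1.0, 0, 0]])
        P = cpd_posteriors(moving, fixed, 1.0, 0.0)
        np.testing.assert_allclose(P.ravel(), [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("w", [0.0, 0.1, 0.4])
    def test_posteriors_match_brute_force(self, rng, w):
        moving = rng.normal(0, 3, (3, 3))
        fixed = rng.normal(0, 3, (4, 3))
        P = cpd_posteriors(moving, fixed, 1.7, w)
        np.testing.assert_allclose(
            P, brute_force_posteriors(moving, fixed, 1.7, w), atol=1e-12)

    def test_recovers_known_transform_from_surface_samples(self, rng, coarse_femur):
        from bonereg.metrics import sample_surface

        samples, _ = sample_surface(coarse_femur, 500, rng)
        truth = RigidTransform(rotation_about_axis(rng.standard_normal(3), 10.0),
                               8.0 * rng.standard_normal(3) / np.sqrt(3))
        moving = Point3Set(samples)
        fixed = Point3Set(truth.apply(samples))
        res = rigid_cpd(moving, fixed, CpdConfig(seed=1))
        rot, tr = transform_discrepancy(res.transform, truth)
        assert rot < 0.1 and tr < 0.05

    def test_sigma2_nonincreasing_on_matched_instances(self, rng, coarse_femur):
        moving = Point3Set(coarse_femur.vertices[
            farthest_point_sampling(coarse_femur.vertices, 400, 0)])
        for trial in range(10):
            t = random_rigid(rng, 15, 20)
            fixed = Point3Set(t.apply(moving.points)
                              + rng.normal(0, 0.3, moving.points.shape))
            res = rigid_cpd(moving, fixed, CpdConfig(seed=1, max_iterations=80))
            log = res.log
            assert np.all(np.diff(log) <= 1e-9 * np.maximum(log[:-1], 1e-12))

    def test_likelihood_nonincreasing_even_on_subset_instances(self, rng, coarse_femur):
        # the EM guarantee proper: mixture NLL never increases, including on
        # partial/subset instances where sigma^2 itself may wobble
        verts = coarse_femur.vertices
        moving = Point3Set(verts[farthest_point_sampling(verts, 300, 0)])
        for trial in range(5):
            t = random_rigid(rng, 15, 20)
            sel = rng.permutation(len(verts))[:64]
            fixed = Point3Set(t.apply(verts[sel]) + rng.normal(0, 0.3, (64, 3)))
            res = rigid_cpd(moving, fixed,
                            CpdConfig(seed=1, max_iterations=60,
                                      track_likelihood=True))
            nll = res.nll_log
            assert np.all(np.diff(nll) <= 1e-9 * np.maximum(np.abs(nll[:-1]), 1.0))

    def test_equivariance_under_rigid_conjugation(self, rng):
        base = rng.normal(0, 15, (60, 3))
        moving = Point3Set(base)
        fixed = Point3Set(random_rigid(rng, 10, 5).apply(base)
                          + rng.normal(0, 0.2, base.shape))
        res0 = rigid_cpd(moving, fixed, CpdConfig(seed=1))
        for _ in range(20):
            q = random_rigid(rng)
            res1 = rigid_cpd(apply_transform(q, moving), apply_transform(q, fixed),
                             CpdConfig(seed=1))
            conj = compose(compose(q, res0.transform), invert(q))
            rot, tr = transform_discrepancy(res1.transform, conj)
            assert rot < 1e-4 and tr < 1e-4

    def test_rotations_always_proper(self, rng):
        # near-planar (reflective-prone) configurations
        for _ in range(20):
            base = rng.normal(0, 10, (30, 3)) * np.array([1.0, 1.0, 1e-4])
            fixed = Point3Set(random_rigid(rng, 30, 5).apply(base))
            res = rigid_cpd(Point3Set(base), fixed, CpdConfig(seed=1))
            assert np.linalg.det(res.transform.rotation) > 0.999999

    def test_degenerate_inputs_rejected(self, rng):
        line = np.outer(np.arange(8.0), [1.0, 0, 0])
        with pytest.raises(RegistrationError, match="collinear"):
            rigid_cpd(Point3Set(line), Point3Set(rng.normal(0, 1, (8, 3))))
        with pytest.raises(RegistrationError, match="at least 4"):
            rigid_cpd(Point3Set(rng.normal(0, 1, (3, 3))),
                      Point3Set(rng.normal(0, 1, (8, 3))))

    def test_model_front_end_matches_function(self, rng):
        base = rng.normal(0, 15, (40, 3))
        fixed = Point3Set(random_rigid(rng, 10, 5).apply(base))
        a = RigidCPD(fixed, Point3Set(base), CpdConfig(seed=2)).fit()
        b = rigid_cpd(Point3Set(base), fixed, CpdConfig(seed=2))
        np.testing.assert_array_equal(a.transform.rotation, b.transform.rotation)
        assert "converged" in a.summary()


class TestModelRegistration:
    def test_self_registration_is_identity(self, coarse_femur):
        pts = simulate_operator_points(coarse_femur, 128, ZERO_NOISE, seed=4)
        res = register_model_to_points(coarse_femur, pts, CpdConfig(seed=1))
        rot, tr = transform_discrepancy(res.transform, RigidTransform.identity())
        assert rot < 0.05 and tr < 0.05

    def test_recovers_displacement_from_zero_noise_points(self, rng, coarse_femur):
        truth = random_rigid(rng, 15, 15)
        displaced = coarse_femur.transformed(truth)
        pts = simulate_operator_points(displaced, 128, ZERO_NOISE, seed=4)
        res = register_model_to_points(coarse_femur, pts, CpdConfig(seed=1))
        rot, tr = transform_discrepancy(res.transform, truth)
        assert rot < 0.1 and tr < 0.05

    def test_partial_coverage_still_registers(self, rng, coarse_femur):
        truth = random_rigid(rng, 15, 15)
        displaced = coarse_femur.transformed(truth)
        pts = simulate_operator_points(displaced, 128, ZERO_NOISE,
                                       region="partial", seed=4)
        res = register_model_to_points(coarse_femur, pts, CpdConfig(seed=1))
        rot, tr = transform_discrepancy(res.transform, truth)
        assert rot < 0.5 and tr < 0.5

    def test_error_median_decreases_with_point_count(self, coarse_femur):
        truth = RigidTransform(rotation_about_axis([1, 2, 3], 12.0), [6, -4, 9])
        displaced = coarse_femur.transformed(truth)
        noisy = OperatorModel(0.3, 0.0)
        cfg = CpdConfig(seed=1, moving_sample_count=500,
                        max_iterations=50, tolerance=1e-6)
        medians = []
        for count in (32, 128, 1024):
            errs = []
            for rep in range(5):
                pts = simulate_operator_points(displaced, count, noisy,
                                               seed=100 * count + rep)
                res = register_model_to_points(coarse_femur, pts, cfg)
                rot, tr = transform_discrepancy(res.transform, truth)
                errs.append(rot)
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]

    def test_too_few_points_rejected(self, coarse_femur):
        with pytest.raises(RegistrationError, match="4 attraction points"):
            register_model_to_points(
                coarse_femur, Point3Set(np.zeros((3, 3)) + np.eye(3, 3)))

    def test_model_to_model_self_is_identity(self, coarse_femur):
        res = register_model_to_model(coarse_femur, coarse_femur,
                                      CpdConfig(seed=1, moving_sample_count=500))
        rot, tr = transform_discrepancy(res.transform, RigidTransform.identity())
        assert rot < 0.05 and tr < 0.05

    def test_model_to_model_recovers_displacement(self, rng, coarse_femur):
        truth = random_rigid(rng, 15, 15)
        res = register_model_to_model(coarse_femur, coarse_femur.transformed(truth),
                                      CpdConfig(seed=1, moving_sample_count=500))
        rot, tr = transform_discrepancy(res.transform, truth)
        assert rot < 0.1 and tr < 0.05

    def test_model_to_model_tolerates_surface_perturbation(self, rng, coarse_femur):
        truth = random_rigid(rng, 15, 15)
        displaced = coarse_femur.transformed(truth)
        reference = perturb_segmentation(displaced, 0.3, 10.0, seed=7)
        res = register_model_to_model(coarse_femur, reference,
                                      CpdConfig(seed=1, moving_sample_count=500))
        rot, tr = transform_discrepancy(res.transform, truth)
        # rotation about the near-cylindrical shaft axis is a soft mode:
        # tangential sliding costs little surface distance, so a 0.3 mm
        # correlated perturbation can move it by around a degree
        assert rot < 1.5 and tr < 0.5


class TestFiducialFit:
    def test_identity_for_equal_sets(self, rng):
        pts = Point3Set(rng.normal(0, 20, (5, 3)))
        t = fit_rigid_corresponding(pts, pts)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(t.translation).max() < 1e-12

    def test_exact_recovery_of_known_transform(self, rng):
        src = Point3Set(rng.normal(0, 20, (5, 3)))
        truth = random_rigid(rng)
        tgt = apply_transform(truth, src)
        t = fit_rigid_corresponding(src, tgt)
        assert np.abs(t.rotation - truth.rotation).max() < 1e-9
        assert np.abs(t.translation - truth.translation).max() < 1e-9

    def test_noisy_fit_matches_numerical_minimizer(self, rng):
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        src = rng.normal(0, 20, (5, 3))
        truth = random_rigid(rng, 30, 10)
        tgt = truth.apply(src) + rng.normal(0, 0.2, (5, 3))

        def fre(params):
            r = Rotation.from_rotvec(params[:3]).as_matrix()
            res = src @ r.T + params[3:] - tgt
            return np.sum(res * res)

        best = np.inf
        for _ in range(8):
            x0 = np.r_[rng.normal(0, 0.5, 3), rng.normal(0, 5, 3)]
            out = minimize(fre, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-15,
                                    "maxiter": 20000})
            best = min(best, out.fun)
        t = fit_rigid_corresponding(Point3Set(src), Point3Set(tgt))
        ours = fiducial_registration_error(Point3Set(src), Point3Set(tgt), t)
        assert abs(ours - np.sqrt(best / 5)) < 1e-6

    def test_noiseless_fit_beats_random_perturbations(self, rng):
        src = rng.normal(0, 15, (6, 3))
        truth = random_rigid(rng)
        tgt = truth.apply(src)
        t = fit_rigid_corresponding(Point3Set(src), Point3Set(tgt))
        base = fiducial_registration_error(Point3Set(src), Point3Set(tgt), t)
        for _ in range(1000):
            pert = compose(random_rigid(rng, 5.0, 1.0), t)
            alt = fiducial_registration_error(Point3Set(src), Point3Set(tgt), pert)
            assert alt > base

    def test_collinear_and_short_inputs_rejected(self, rng):
        line = np.outer(np.arange(5.0), [1.0, 1.0, 0.0])
        with pytest.raises(RegistrationError, match="collinear"):
            fit_rigid_corresponding(Point3Set(line), Point3Set(line))
        two = Point3Set(rng.normal(0, 1, (2, 3)))
        with pytest.raises(RegistrationError, match="3 corresponding"):
            fit_rigid_corresponding(two, two)


class TestFre:
    def test_zero_for_perfect_correspondence(self, rng):
        src = Point3Set(rng.normal(0, 10, (5, 3)))
        t = random_rigid(rng)
        assert fiducial_registration_error(src, apply_transform(t, src), t) < 1e-12

    def test_single_offset_pair_closed_form(self, rng):
        src = Point3Set(rng.normal(0, 10, (5, 3)))
        tgt = src.points.copy()
        tgt[2, 0] += 1.0
        fre = fiducial_registration_error(src, Point3Set(tgt),
                                          RigidTransform.identity())
        assert abs(fre - np.sqrt(1.0 / 5.0)) < 1e-12

    def test_matches_direct_formula(self, rng):
        src = Point3Set(rng.normal(0, 10, (7, 3)))
        tgt = Point3Set(rng.normal(0, 10, (7, 3)))
        t = random_rigid(rng)
        direct = np.sqrt(np.mean(
            np.sum((t.apply(src.points) - tgt.points) ** 2, axis=1)))
        assert abs(fiducial_registration_error(src, tgt, t) - direct) < 1e-12

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(RegistrationError):
            fiducial_registration_error(Point3Set(rng.normal(0, 1, (5, 3))),
                                        Point3Set(rng.normal(0, 1, (4, 3))),
                                        RigidTransform.identity())


class TestFarthestPointSampling:
    def test_deterministic_given_seed(self, rng):
        pts = rng.normal(0, 10, (200, 3))
        a = farthest_point_sampling(pts, 50, seed=3)
        b = farthest_point_sampling(pts, 50, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_returns_all_when_count_exceeds_points(self, rng):
        pts = rng.normal(0, 10, (10, 3))
        np.testing.assert_array_equal(farthest_point_sampling(pts, 50, 0),
                                      np.arange(10))

    def test_ties_break_to_lowest_index(self):
        # two duplicated farthest candidates: argmax must take the first
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [10, 0, 0], [5, 0, 0]])
        idx = farthest_point_sampling(pts, 2, seed=0)
        if idx[0] == 0:
            assert idx[1] == 1  # not 2
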