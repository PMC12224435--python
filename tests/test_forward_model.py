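"""Forward-model unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmri_posterior import forward_model as fm


def random_fiber(rng) -> fm.FiberParams:
    fast = np.sort(rng.uniform(1.0, 3.0, 2))
    slow = np.sort(rng.uniform(0.1, 0.6, 2))
    return fm.FiberParams(theta=rng.uniform(0, math.pi),
                          phi=rng.uniform(0, math.pi),
                          lam1=fast[1], lam2=fast[0],
                          lam3=slow[1], lam4=slow[0])


class TestTensorConstruction:
    def test_axis_aligned_tensor_is_diagonal(self):
        f = fm.FiberParams(theta=0.0, phi=0.0, lam1=2.0, lam2=1.0,
                           lam3=0.5, lam4=0.25)
        d_fast, d_slow = fm.tensor_from_fiber(f)
        np.testing.assert_allclose(d_fast, np.diag([1.0, 1.0, 2.0]),
                                   atol=1e-12)
        np.testing.assert_allclose(d_slow, np.diag([0.25, 0.25, 0.5]),
                                   atol=1e-12)

    def test_trace_equals_eigenvalue_sum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            f = random_fiber(rng)
            d_fast, d_slow = fm.tensor_from_fiber(f)
            assert np.trace(d_fast) == pytest.approx(f.lam1 + 2 * f.lam2)
            assert np.trace(d_slow) == pytest.approx(f.lam3 + 2 * f.lam4)

    def test_quadratic_form_along_and_across_axis(self):
        # oracle: eigendecomposition of the constructed matrix
        f = fm.FiberParams(theta=math.pi / 4, phi=math.pi / 3,
                           lam1=2.0, lam2=1.0, lam3=0.5, lam4=0.25)
        d_fast, _ = fm.tensor_from_fiber(f)
        m = f.direction
        assert m @ d_fast @ m == pytest.approx(2.0, abs=1e-12)
        p, v = fm.orthonormal_completion(m)
        assert p @ d_fast @ p == pytest.approx(1.0, abs=1e-12)
        assert v @ d_fast @ v == pytest.approx(1.0, abs=1e-12)
        evals = np.sort(np.linalg.eigvalsh(d_fast))
        np.testing.assert_allclose(evals, [1.0, 1.0, 2.0], atol=1e-12)

    def test_invalid_eigenvalues_rejected(self):
        with pytest.raises(ValueError):
            fm.FiberParams(theta=0, phi=0, lam1=1.0, lam2=2.0,
                           lam3=0.5, lam4=0.25)
        with pytest.raises(ValueError):
            fm.FiberParams(theta=0, phi=0, lam1=2.0, lam2=0.0,
                           lam3=0.5, lam4=0.25)


class TestSignalSimulation:
    def test_b0_normalization(self, small_scheme):
        scheme0 = fm.AcquisitionScheme(
            directions=small_scheme.directions,
            bvalues=np.zeros_like(small_scheme.bvalues),
            shell_ids=np.full(small_scheme.n_measurements, -1))
        rng = np.random.default_rng(1)
        for n in (1, 2, 3):
            vp = fm.VoxelParams(fibers=tuple(random_fiber(rng)
                                             for _ in range(n)))
            s = fm.simulate_signal(vp, scheme0)
            np.testing.assert_allclose(s.values, 1.0, atol=1e-14)

    def test_single_fiber_biexponential_value(self):
        # S = 0.7 e^-2 + 0.3 e^-0.5 at b=1000, u along the fiber
        scheme = fm.AcquisitionScheme(
            directions=np.array([[0.0, 0.0, 1.0]]),
            bvalues=np.array([1000.0]), shell_ids=np.array([0]))
        f = fm.FiberParams(theta=0.0, phi=0.0, lam1=2.0, lam2=1.0,
                           lam3=0.5, lam4=0.25, w=0.7)
        s = fm.simulate_signal(fm.VoxelParams(fibers=(f,)), scheme)
        expected = 0.7 * math.exp(-2.0) + 0.3 * math.exp(-0.5)
        assert s.values[0] == pytest.approx(expected, rel=1e-12)

    def test_isotropic_tensor_gives_direction_independent_signal(self, scheme):
        f = fm.FiberParams(theta=0.7, phi=0.3, lam1=1.5, lam2=1.5,
                           lam3=0.3, lam4=0.3)
        s = fm.simulate_signal(fm.VoxelParams(fibers=(f,)), scheme)
        for sid in range(3):
            shell_vals = s.on_shell(sid)
            np.testing.assert_allclose(shell_vals, shell_vals[0], atol=1e-12)

    def test_monotone_decay_in_b(self):
        rng = np.random.default_rng(3)
        u = np.array([[0.3, 0.5, math.sqrt(1 - 0.34)]])
        bs = np.array([0.0, 500.0, 1000.0, 2000.0, 3000.0, 5000.0])
        scheme = fm.AcquisitionScheme(directions=np.repeat(u, bs.size, 0),
                                      bvalues=bs,
                                      shell_ids=np.arange(bs.size) - 1)
        for _ in range(10):
            vp = fm.VoxelParams(fibers=(random_fiber(rng),))
            vals = fm.simulate_signal(vp, scheme).values
            assert np.all(np.diff(vals) <= 1e-15)

    def test_rotation_equivariance(self, scheme):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(4)
        rot = Rotation.random(random_state=5).as_matrix()
        vp = fm.VoxelParams(fibers=(random_fiber(rng), random_fiber(rng)))
        s_ref = fm.simulate_signal(vp, scheme).values
        rotated_fibers = []
        for f in vp.fibers:
            m_rot = rot @ f.direction
            theta, phi = fm.unit_to_spherical(m_rot)
            rotated_fibers.append(fm.FiberParams(
                theta=theta, phi=phi, lam1=f.lam1, lam2=f.lam2,
                lam3=f.lam3, lam4=f.lam4, w=f.w))
        scheme_rot = fm.AcquisitionScheme(
            directions=scheme.directions @ rot.T,
            bvalues=scheme.bvalues, shell_ids=scheme.shell_ids)
        s_rot = fm.simulate_signal(
            fm.VoxelParams(fibers=tuple(rotated_fibers)), scheme_rot).values
        np.testing.assert_allclose(s_rot, s_ref, atol=1e-10)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.sampled_from([2, 3]))
    def test_fiber_permutation_leaves_signal_bit_identical(self, seed, n):
        import itertools
        rng = np.random.default_rng(seed)
        scheme = fm.hcp_like_scheme(15)
        vp = fm.VoxelParams(fibers=tuple(random_fiber(rng) for _ in range(n)))
        ref = fm.simulate_signal(vp, scheme).values
        for order in itertools.permutations(range(n)):
            sig = fm.simulate_signal(vp.permuted(order), scheme).values
            assert np.array_equal(sig, ref)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_antipodal_parameterization_leaves_signal_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        scheme = fm.hcp_like_scheme(15)
        f = random_fiber(rng)
        theta_a, phi_a = fm.unit_to_spherical(-f.direction)
        f_anti = fm.FiberParams(theta=theta_a, phi=phi_a, lam1=f.lam1,
                                lam2=f.lam2, lam3=f.lam3, lam4=f.lam4)
        s1 = fm.simulate_signal(fm.VoxelParams(fibers=(f,)), scheme).values
        s2 = fm.simulate_signal(fm.VoxelParams(fibers=(f_anti,)),
                                scheme).values
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestNoise:
    def test_zero_sigma_is_identity(self, small_scheme):
        vp = fm.VoxelParams(fibers=(random_fiber(np.random.default_rng(6)),))
        s = fm.simulate_signal(vp, small_scheme)
        assert fm.add_noise(s, 0.0, seed=1) is s

    def test_noise_std_matches_sigma(self):
        scheme = fm.AcquisitionScheme(
            directions=np.tile([[0.0, 0.0, 1.0]], (100_000, 1)),
            bvalues=np.full(100_000, 1000.0),
            shell_ids=np.zeros(100_000, dtype=int))
        s = fm.Signal(values=np.ones(100_000), scheme=scheme)
        noisy = fm.add_noise(s, 0.04, seed=7)
        assert np.std(noisy.values - 1.0) == pytest.approx(0.04, rel=0.01)

    def test_seeded_noise_is_reproducible(self, small_scheme):
        vp = fm.VoxelParams(fibers=(random_fiber(np.random.default_rng(8)),))
        s = fm.simulate_signal(vp, small_scheme)
        a = fm.add_noise(s, 0.04, seed=42).values
        b = fm.add_noise(s, 0.04, seed=42).values
        assert np.array_equal(a, b)

    def test_negative_sigma_rejected(self, small_scheme):
        vp = fm.VoxelParams(fibers=(random_fiber(np.random.default_rng(9)),))
        s = fm.simulate_signal(vp, small_scheme)
        with pytest.raises(ValueError):
            fm.add_noise(s, -0.1, seed=0)


class TestPriorSampling:
    def test_single_fiber_ranges(self, prior):
        draws = fm.sample_prior(prior, 1, 2000, seed=10)
        a = np.vstack([vp.as_vector() for vp in draws])
        assert np.all((a[:, 2] >= 1.0) & (a[:, 2] <= 3.0))
        assert np.all((a[:, 3] >= 1.0) & (a[:, 3] <= 3.0))
        assert np.all(a[:, 2] >= a[:, 3])
        assert np.all((a[:, 5] >= 0.1) & (a[:, 5] <= 0.6))
        assert np.all(a[:, 4] >= a[:, 5])
        assert all(vp.fibers[0].w == prior.w_fast for vp in draws)

    def test_two_fiber_angles_within_window(self, prior):
        draws = fm.sample_prior(prior, 2, 2000, seed=11)
        for vp in draws:
            ang = fm.crossing_angle_deg(vp.fibers[0].direction,
                                        vp.fibers[1].direction)
            assert 10.0 - 1e-6 <= ang <= 90.0 + 1e-6

    def test_three_fiber_minimum_pairwise_angle(self, prior):
        import itertools
        draws = fm.sample_prior(prior, 3, 1000, seed=12)
        for vp in draws:
            for i, j in itertools.combinations(range(3), 2):
                ang = fm.crossing_angle_deg(vp.fibers[i].direction,
                                            vp.fibers[j].direction)
                assert ang >= 45.0 - 1e-6

    def test_multi_fiber_fa_floor(self, prior):
        draws = fm.sample_prior(prior, 2, 1000, seed=13)
        for vp in draws:
            for f in vp.fibers:
                fa = math.sqrt((f.lam1 - f.lam2) ** 2
                               / (f.lam1**2 + 2 * f.lam2**2))
                assert fa > prior.min_fa_multi

    def test_infeasible_constraints_raise(self, prior):
        import dataclasses
        bad = dataclasses.replace(prior, min_angle_deg={1: 0, 2: 89.9, 3: 89.9})
        with pytest.raises(RuntimeError):
            fm.sample_prior(bad, 3, 10, seed=14)


class TestPermutationEquivalence:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (3, 6)])
    def test_equivalent_permutation_count(self, n, expected):
        assert fm.count_equivalent_permutations(n) == expected

    def test_out_of_range_count_rejected(self):
        with pytest.raises(ValueError):
            fm.count_equivalent_permutations(4)


class TestScheme:
    def test_directions_are_unit(self, scheme):
        norms = np.linalg.norm(scheme.directions, axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_shells_group_by_bvalue(self, scheme):
        np.testing.assert_allclose(sorted(scheme.shells),
                                   [1000.0, 2000.0, 3000.0])
        for sid, b in enumerate((1000.0, 2000.0, 3000.0)):
            assert np.all(scheme.bvalues[scheme.shell_mask(sid)] == b)

    def test_shell_assignment_with_jitter(self):
        bvals = np.array([0.0, 995.0, 2040.0, 2960.0])
        bvecs = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]]).T
        sch = fm.AcquisitionScheme.from_bvals_bvecs(
            bvals, bvecs, nominal_shells=[1000, 2000, 3000])
        assert list(sch.shell_ids) == [-1, 0, 1, 2]

    def test_mismatched_bvecs_rejected(self):
        with pytest.raises(ValueError):
            fm.AcquisitionScheme.from_bvals_bvecs(
                np.array([0.0, 1000.0]), np.zeros((3, 5)))
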