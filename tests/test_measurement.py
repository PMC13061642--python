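"""Interferometric single-pixel measurement with Poisson shot noise."""

import numpy as np
import pytest

from lsom import (
    ComplexField,
    Dot,
    MeasurementRecord,
    NoiseModel,
    RepetitionPlan,
    measure_coefficient,
    measure_vector,
    mode_mask,
    object_band_field,
    submeasurement_intensity,
)

from conftest import in_span_band_field


class TestModeMask:
    def test_halves_disjoint_and_tile_band(self, basis_1d):
        a = mode_mask(basis_1d, 2, 0, "A", 0.0)
        bm = basis_1d.band_modes()
        # target half carries conj(S_k), other half conj(S_r): supports split
        on_target = np.abs(a.samples - np.conj(bm[:, 2])) < 1e-14
        on_ref = np.abs(a.samples - np.conj(bm[:, 0])) < 1e-14
        assert not np.any(on_target & on_ref & (np.abs(a.samples) > 0))
        assert np.all(on_target | on_ref)

    def test_phase_steps_differ_by_sign_on_reference_half(self, basis_1d):
        m0 = mode_mask(basis_1d, 2, 0, "A", 0.0)
        mpi = mode_mask(basis_1d, 2, 0, "A", np.pi)
        diff = m0.samples - mpi.samples
        same = m0.samples - mpi.samples == 0
        # where they differ, m_pi = -m_0 (reference half)
        changed = ~same
        assert np.allclose(mpi.samples[changed], -m0.samples[changed])
        # where they agree, that's the target half
        assert np.any(same)

    def test_configs_swap_halves(self, basis_1d):
        a = mode_mask(basis_1d, 2, 0, "A", 0.0)
        b = mode_mask(basis_1d, 2, 0, "B", 0.0)
        bm = basis_1d.band_modes()
        a_target = np.abs(a.samples - np.conj(bm[:, 2])) < 1e-14
        b_target = np.abs(b.samples - np.conj(bm[:, 2])) < 1e-14
        assert not np.any(a_target & b_target)

    def test_self_reference_collimation(self, basis_1d):
        # field = γ_r c_r S_r with the (k=r, step 0) mask: on-axis
        # amplitude equals the full band inner product γ_r c_r
        c_r = 0.37 - 0.21j
        field = ComplexField(
            basis_1d.gammas[0] * c_r * basis_1d.band_modes()[:, 0],
            basis_1d.band_grid,
            "fourier",
        )
        m = mode_mask(basis_1d, 0, 0, "A", 0.0)
        amp = np.sum(basis_1d.band_grid.weights * m.samples * field.samples)
        # conj(S_r)·S_r integrates to 1 over the full band
        assert abs(amp - basis_1d.gammas[0] * c_r) < 1e-10

    def test_bad_mode_index(self, basis_1d):
        with pytest.raises(ValueError):
            mode_mask(basis_1d, 99, 0, "A", 0.0)


class TestSubmeasurementIntensity:
    def test_zero_field_zero_counts(self, basis_1d):
        f = ComplexField(np.zeros(basis_1d.band_grid.n_points), basis_1d.band_grid, "fourier")
        m = mode_mask(basis_1d, 1, 0, "A", 0.0)
        counts = submeasurement_intensity(f, m, NoiseModel(poisson=True, seed=0), scale=10.0, repetitions=5)
        assert np.all(counts == 0)

    def test_reference_only_field_phase_invariant(self, basis_1d):
        # no target component: stepping the reference phase cannot change
        # the expected intensity.  The target mask must share the
        # reference mode's parity — the half-band overlap of a same-parity
        # pair vanishes exactly, while opposite-parity pairs have genuine
        # half-field crosstalk.
        field = ComplexField(
            basis_1d.gammas[0] * basis_1d.band_modes()[:, 0],
            basis_1d.band_grid,
            "fourier",
        )
        noise = NoiseModel(poisson=False)
        vals = []
        for ph in (0.0, np.pi):
            m = mode_mask(basis_1d, 2, 0, "A", ph)
            vals.append(submeasurement_intensity(field, m, noise, scale=1.0)[0])
        assert abs(vals[0] - vals[1]) < 1e-10 * max(vals[0], 1e-30)

    def test_poisson_variance_matches_mean(self, basis_1d):
        field = in_span_band_field(basis_1d, [1, 0.3, 0, 0, 0, 0])
        m = mode_mask(basis_1d, 1, 0, "A", 0.0)
        noise = NoiseModel(poisson=True, seed=42)
        counts = submeasurement_intensity(field, m, noise, scale=2e4, repetitions=10_000)
        assert abs(counts.var() / counts.mean() - 1.0) < 0.05

    def test_zero_scale_rejected(self, basis_1d):
        f = ComplexField(np.zeros(basis_1d.band_grid.n_points), basis_1d.band_grid, "fourier")
        m = mode_mask(basis_1d, 1, 0, "A", 0.0)
        with pytest.raises(ValueError, match="scale"):
            submeasurement_intensity(f, m, NoiseModel(), scale=0.0)


class TestMeasureCoefficient:
    def test_noiseless_exact_diagonal(self, basis_1d):
        c_o = np.array([0.8, -0.2 + 0.5j, 0.1j, 0.3, -0.05, 0.02j])
        field = in_span_band_field(basis_1d, c_o)
        noise = NoiseModel(poisson=False)
        for s_r in (1.0, 2.0):
            for k in range(6):
                c, _ = measure_coefficient(field, basis_1d, k, 0, 1, noise, s_r=s_r)
                assert abs(c - basis_1d.gammas[k] * c_o[k] / s_r) < 1e-12

    def test_self_reference_real_positive_for_centered_dot(self, basis_1d):
        from lsom import Line

        band = object_band_field(Line(width=0.125, dim=1), basis_1d)
        c, _ = measure_coefficient(band, basis_1d, 0, 0, 1, NoiseModel(poisson=False))
        assert abs(c.imag) < 1e-12 * abs(c)
        assert c.real > 0

    def test_shot_noise_scaling_with_r_and_p(self, basis_1d):
        # std(c_m) ∝ 1/√(R·P_sin) over two settings of each parameter
        field = in_span_band_field(basis_1d, [1, 0.4, 0.2, 0.1, 0.03, 0.01])
        rng = np.random.default_rng(11)

        def mc_std(reps, p_sin, n=400):
            noise = NoiseModel(photons_per_submeasurement=p_sin, poisson=True, seed=1)
            vals = [
                measure_coefficient(field, basis_1d, 2, 0, reps, noise, rng=rng)[0]
                for _ in range(n)
            ]
            return np.std(vals)

        s11 = mc_std(1, 1e4)
        s41 = mc_std(4, 1e4)
        s14 = mc_std(1, 4e4)
        assert abs(s11 / s41 - 2.0) < 0.3
        assert abs(s11 / s14 - 2.0) < 0.3

    def test_invalid_repetitions(self, basis_1d):
        field = in_span_band_field(basis_1d, [1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match=">= 1"):
            measure_coefficient(field, basis_1d, 1, 0, 0, NoiseModel())


class TestMeasureVector:
    def test_noiseless_ideal_diagonal(self, basis_1d):
        c_o = np.array([1.0, 0.5 - 0.2j, 0.3j, 0.1, 0.05, 0.02])
        field = in_span_band_field(basis_1d, c_o)
        c_m, rec = measure_vector(
            field, basis_1d, 6, 0, RepetitionPlan.uniform(6), NoiseModel(poisson=False), s_r=2.0
        )
        assert np.max(np.abs(c_m - basis_1d.gammas * c_o / 2.0)) < 1e-12
        assert rec.repetitions.tolist() == [1] * 6

    def test_doubled_plan_shrinks_errors_sqrt2(self, basis_1d):
        field = in_span_band_field(basis_1d, [1, 0.4, 0.2, 0.1, 0.03, 0.01])
        rng = np.random.default_rng(21)
        noise = NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=2)

        def stds(plan, n=300):
            vals = np.array(
                [measure_vector(field, basis_1d, 6, 0, plan, noise, rng=rng)[0] for _ in range(n)]
            )
            return vals.std(axis=0)

        s1 = stds(RepetitionPlan.uniform(6, 1))
        s2 = stds(RepetitionPlan.uniform(6, 2))
        ratios = s1 / s2
        assert np.all(np.abs(ratios - np.sqrt(2)) < np.sqrt(2) * 0.15)

    def test_unbiased_within_three_standard_errors(self, basis_1d):
        c_o = np.array([1.0, 0.5 - 0.2j, 0.3j, 0.1, 0.05, 0.02])
        field = in_span_band_field(basis_1d, c_o)
        noiseless, _ = measure_vector(
            field, basis_1d, 6, 0, RepetitionPlan.uniform(6), NoiseModel(poisson=False)
        )
        rng = np.random.default_rng(31)
        noise = NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=3)
        n = 600
        vals = np.array(
            [measure_vector(field, basis_1d, 6, 0, RepetitionPlan.uniform(6), noise, rng=rng)[0] for _ in range(n)]
        )
        se = vals.std(axis=0) / np.sqrt(n)
        assert np.all(np.abs(vals.mean(axis=0) - noiseless) < 3 * se)

    def test_seed_determinism_bit_for_bit(self, basis_1d):
        field = in_span_band_field(basis_1d, [1, 0.4, 0.2, 0.1, 0.03, 0.01])
        noise = NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=99)
        a, ra = measure_vector(field, basis_1d, 6, 0, RepetitionPlan.uniform(6), noise, keep_counts=True)
        b, rb = measure_vector(field, basis_1d, 6, 0, RepetitionPlan.uniform(6), noise, keep_counts=True)
        assert np.array_equal(a, b)
        for k in range(6):
            assert np.array_equal(ra.counts[k], rb.counts[k])

    def test_photon_accounting(self, basis_1d):
        field = in_span_band_field(basis_1d, [1, 0.4, 0.2, 0.1, 0.03, 0.01])
        noise = NoiseModel(photons_per_submeasurement=1e4, poisson=True, seed=5)
        plan = RepetitionPlan(np.array([1, 2, 1, 3, 1, 1]))
        _, rec = measure_vector(field, basis_1d, 6, 0, plan, noise, keep_counts=True)
        total = sum(rec.counts[k].sum() for k in range(6))
        assert rec.photon_total == total
        assert rec.photon_total > 0

    def test_n_prime_13_vector_in_2d(self, basis_2d):
        # the 2D demonstration measures a length-13 coefficient vector
        dot = Dot(diameter=0.125, dim=2)
        band = object_band_field(dot, basis_2d)
        c_m, _ = measure_vector(
            band, basis_2d, 13, 0, RepetitionPlan.uniform(13), NoiseModel(poisson=False)
        )
        assert c_m.shape == (13,)

    def test_n_prime_exceeding_modes(self, basis_1d):
        field = in_span_band_field(basis_1d, [1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="exceeds"):
            measure_vector(field, basis_1d, 7, 0, RepetitionPlan.uniform(7), NoiseModel())
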