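import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from neuroturb.geometry import ParcellationGeometry, pairwise_distances
from neuroturb.signal import PhaseField
from neuroturb.turbulence import (
    DEFAULT_LAMBDAS,
    TurbulenceAnalyzer,
    amplitude_turbulence,
    build_kernels,
    fit_power_law,
    information_cascade,
    information_cascade_flow,
    lambda_grid,
    local_kuramoto,
    node_level_metastability,
    state_slope_profile,
    transfer_correlation,
    turbulence_profile,
)

TR = 2.0


def phase_field(phases):
    phases = np.asarray(phases, dtype=float)
    return PhaseField(phases=phases, valid_window=(0, phases.shape[1]), tr=TR)


def order_field(modulus, lam=0.12):
    from neuroturb.turbulence import LocalOrderField

    modulus = np.asarray(modulus, dtype=float)
    return LocalOrderField(modulus=modulus, phase=np.zeros_like(modulus), lam=lam)


class TestLambdaGrid:
    def test_default_grid_has_11_scales_with_readouts(self):
        assert len(DEFAULT_LAMBDAS) == 11
        for lam in (0.01, 0.12, 0.30):
            assert np.any(np.isclose(DEFAULT_LAMBDAS, lam))


class TestBuildKernels:
    def test_characteristic_scales_closed_form(self):
        dist = np.array([[0.0, 100.0], [100.0, 0.0]])
        k = build_kernels(dist, np.array([0.01]))
        assert k[0.01][0, 1] == pytest.approx(np.exp(-1.0))
        dist = np.array([[0.0, 3.0], [3.0, 0.0]])
        k = build_kernels(dist, np.array([0.3]))
        assert k[0.3][0, 1] == pytest.approx(np.exp(-0.9))

    def test_unit_diagonal_and_row_norms(self, dist30):
        k = build_kernels(dist30)
        for lam in k.lambdas:
            w = k[lam]
            assert np.all(np.diag(w) == 1.0)
            assert np.allclose(k.norms[float(lam)], w.sum(axis=1))

    def test_matches_scalar_loop_oracle(self, dist30):
        k = build_kernels(dist30, np.array([0.12]))
        w = k[0.12]
        for i in range(30):
            for j in range(30):
                assert w[i, j] == pytest.approx(np.exp(-0.12 * dist30[i, j]), abs=1e-15)

    def test_rejects_nonpositive_lambda(self, dist30):
        with pytest.raises(ValueError):
            build_kernels(dist30, np.array([0.0, 0.1]))


class TestLocalKuramoto:
    def test_full_synchrony_unit_modulus(self, dist30):
        k = build_kernels(dist30)
        pf = phase_field(np.full((30, 50), 1.2))
        for lam in k.lambdas:
            field = local_kuramoto(pf, k, lam)
            assert np.allclose(field.modulus, 1.0, atol=1e-12)

    def test_two_node_antiphase_closed_form(self):
        r = 25.0
        dist = np.array([[0.0, r], [r, 0.0]])
        for lam in (0.05, 0.12, 0.3):
            k = build_kernels(dist, np.array([lam]))
            pf = phase_field(np.array([[0.0] * 10, [np.pi - 1e-15] * 10]))
            field = local_kuramoto(pf, k, lam)
            expected = (1 - np.exp(-lam * r)) / (1 + np.exp(-lam * r))
            assert np.allclose(field.modulus, expected, atol=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        coords = rng.uniform(-60, 60, (40, 3))
        geom = ParcellationGeometry(tuple(map(str, range(40))), coords)
        dist = pairwise_distances(geom)
        phases = rng.uniform(-np.pi, np.pi, (40, 30))
        k = build_kernels(dist, np.array([0.3]))
        field = local_kuramoto(phase_field(phases), k, 0.3)
        for n in range(40):
            weights = np.exp(-0.3 * dist[n])
            norm = weights.sum()
            for t in range(0, 30, 7):
                z = np.sum(weights * np.exp(1j * phases[:, t])) / norm
                assert field.modulus[n, t] == pytest.approx(abs(z), abs=1e-12)
                assert field.phase[n, t] == pytest.approx(np.angle(z), abs=1e-12)

    def test_kernel_limit_converges_to_self(self):
        # at very large lambda only the self-weight survives -> modulus 1
        coords = np.array([[0, 0, 0], [40, 0, 0], [0, 40, 0], [0, 0, 40.0]])
        geom = ParcellationGeometry(("a", "b", "c", "d"), coords)
        dist = pairwise_distances(geom)
        k = build_kernels(dist, np.array([50.0]))
        pf = phase_field(np.array([[0.1], [2.0], [-2.5], [3.0]]))
        field = local_kuramoto(pf, k, 50.0)
        assert np.all(field.modulus > 1 - 1e-3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        phases=arrays(
            np.float64,
            (12, 8),
            elements=st.floats(-np.pi, np.pi - 1e-9),
        )
    )
    def test_modulus_bounded_property(self, phases, dist30):
        k = build_kernels(dist30[:12, :12], np.array([0.01, 0.12]))
        for lam in (0.01, 0.12):
            field = local_kuramoto(phase_field(phases), k, lam)
            assert np.all(field.modulus >= 0.0)
            assert np.all(field.modulus <= 1.0)

    def test_nan_phase_rejected(self, dist30):
        k = build_kernels(dist30, np.array([0.12]))
        ph = np.zeros((30, 20))
        ph[3, 5] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            local_kuramoto(phase_field(ph), k, 0.12)


class TestAmplitudeTurbulence:
    def test_constant_field_zero(self):
        assert amplitude_turbulence(order_field(np.full((5, 20), 0.7))) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_bernoulli_half_field(self):
        mod = np.zeros((2, 10))
        mod[1] = 1.0
        assert amplitude_turbulence(order_field(mod)) == pytest.approx(0.5)

    def test_matches_flattened_std_oracle(self, rng):
        mod = rng.uniform(0, 1, (8, 40))
        assert amplitude_turbulence(order_field(mod)) == pytest.approx(
            float(np.std(mod.reshape(-1))), abs=1e-14
        )

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            amplitude_turbulence(order_field(np.array([[0.5]])))


class TestTurbulenceProfile:
    def test_profile_length_matches_grid(self, dist30, rng):
        k = build_kernels(dist30)
        pf = phase_field(rng.uniform(-np.pi, np.pi, (30, 40)))
        assert turbulence_profile(pf, k).shape == (11,)

    def test_sync_low_noise_high(self, geom30, dist30):
        from neuroturb.signal import bandpass, extract_phases
        from neuroturb.synthetic import generate_bold

        k = build_kernels(dist30)
        sync = generate_bold(geom30, "global_sync", {"noise_sd": 1e-4}, 200, TR, seed=1)
        noise = generate_bold(geom30, "independent_noise", None, 200, TR, seed=2)
        d_sync = turbulence_profile(extract_phases(bandpass(sync)), k)
        d_noise = turbulence_profile(extract_phases(bandpass(noise)), k)
        assert np.all(d_sync < 0.05)
        assert np.all(d_noise > d_sync)


class TestInformationCascade:
    def test_shared_ar1_series_recovers_autocorrelation(self, rng):
        # same AR(1) modulus at both scales: lag-1 correlation ~ rho
        rho, T = 0.7, 4000
        eps = rng.standard_normal((6, T)) * np.sqrt(1 - rho**2)
        x = np.zeros((6, T))
        for t in range(1, T):
            x[:, t] = rho * x[:, t - 1] + eps[:, t]
        mod = 0.5 + 0.1 * x  # keep in [0,1]-ish; correlation is scale-free
        f = information_cascade_flow(order_field(mod), order_field(mod))
        assert f == pytest.approx(rho, abs=3 / np.sqrt(T))

    def test_independent_noise_near_zero(self, rng):
        T = 2000
        f = information_cascade_flow(
            order_field(rng.uniform(0, 1, (5, T))), order_field(rng.uniform(0, 1, (5, T)))
        )
        assert abs(f) <= 3 / np.sqrt(T)

    def test_bounded(self, rng):
        f = information_cascade_flow(
            order_field(rng.uniform(0, 1, (4, 50))), order_field(rng.uniform(0, 1, (4, 50)))
        )
        assert -1.0 <= f <= 1.0

    def test_zero_variance_nodes_excluded(self, rng):
        hi = rng.uniform(0, 1, (3, 100))
        lo = hi.copy()
        hi[0] = 0.5  # constant node ignored
        f = information_cascade_flow(order_field(hi), order_field(lo))
        assert np.isfinite(f)

    def test_all_constant_rejected(self):
        with pytest.raises(ValueError):
            information_cascade_flow(
                order_field(np.full((3, 50), 0.5)), order_field(np.full((3, 50), 0.5))
            )

    def test_cascade_mean_identity_and_symmetry(self):
        assert information_cascade(np.array([0.3, 0.3, 0.3])) == pytest.approx(0.3)
        assert information_cascade(np.array([0.2, 0.4])) == pytest.approx(0.3)
        assert information_cascade(np.array([0.4, 0.2])) == pytest.approx(0.3)

    def test_cascade_empty_rejected(self):
        with pytest.raises(ValueError):
            information_cascade(np.array([]))


class TestTransferCorrelation:
    def test_exact_power_law_curve(self):
        centres = np.linspace(9, 33, 20)
        c = 0.8
        slope, intercept = fit_power_law(centres, c * centres**-0.5)
        assert slope == pytest.approx(-0.5, abs=1e-6)
        assert intercept == pytest.approx(np.log(c), abs=1e-6)

    def test_flat_curve_zero_slope(self):
        centres = np.linspace(9, 33, 10)
        slope, _ = fit_power_law(centres, np.full(10, 0.4))
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_positive_bins_rejected(self):
        with pytest.raises(ValueError, match="3"):
            fit_power_law(np.array([1.0, 2.0, 3.0]), np.array([0.5, -0.1, -0.2]))

    def test_decays_with_distance_on_simulated_subject(self, geom100, dist100):
        from neuroturb.signal import bandpass, extract_phases
        from neuroturb.synthetic import generate_bold

        ts = generate_bold(geom100, "hopf_forward", {"G": 1.5}, 200, TR, seed=5)
        pf = extract_phases(bandpass(ts))
        k = build_kernels(dist100, np.array([0.12]))
        field = local_kuramoto(pf, k, 0.12)
        A, _ = transfer_correlation(field, dist100, (8.0, 34.0), 20)
        assert A < 0

    def test_r_range_in_error_message(self, dist30, rng):
        field = order_field(rng.uniform(0, 1, (30, 30)))
        with pytest.raises(ValueError, match="0.1"):
            transfer_correlation(field, dist30, (0.0, 0.1), 5)


class TestNodeMetastability:
    def test_constant_in_time_zero(self):
        nlm = node_level_metastability(order_field(np.full((4, 30), 0.3)))
        assert np.allclose(nlm, 0.0, atol=1e-12)

    def test_alternating_node_half(self):
        mod = np.full((2, 10), 0.5)
        mod[1] = np.tile([0.0, 1.0], 5)
        nlm = node_level_metastability(order_field(mod))
        assert nlm[0] == 0.0
        assert nlm[1] == pytest.approx(0.5)

    def test_matches_row_std_oracle(self, rng):
        mod = rng.uniform(0, 1, (7, 25))
        assert np.allclose(
            node_level_metastability(order_field(mod)), mod.std(axis=1, ddof=0), atol=1e-14
        )


class TestStateSlopeProfile:
    def test_two_states_difference(self):
        mean_D = np.array([[0.1, 0.2], [0.3, 0.1]])
        slopes = state_slope_profile(mean_D, ["rest", "sleep"])
        assert np.allclose(slopes, [0.2, -0.1])

    def test_exact_line(self):
        mean_D = np.array([[1.0], [2.0], [3.0]])
        assert state_slope_profile(mean_D, ["a", "b", "c"])[0] == pytest.approx(1.0)

    def test_ols_oracle_unordered_means(self):
        # OLS of {3,1,2} on ranks {1,2,3}: slope = cov/var = -0.5
        mean_D = np.array([[3.0], [1.0], [2.0]])
        assert state_slope_profile(mean_D, ["a", "b", "c"])[0] == pytest.approx(-0.5)

    def test_missing_scale_rejected(self):
        with pytest.raises(ValueError):
            state_slope_profile(np.array([[0.1, np.nan], [0.2, 0.3]]), ["a", "b"])


class TestTurbulenceAnalyzer:
    def test_full_synchrony_degeneracy(self, dist30):
        pf = phase_field(np.full((30, 40), 0.5))
        analyzer = TurbulenceAnalyzer().fit(dist30)
        nlm = analyzer.node_metastability(pf)
        assert np.allclose(nlm, 0.0, atol=1e-12)
        for lam in DEFAULT_LAMBDAS:
            field = local_kuramoto(pf, analyzer.kernels_, lam)
            assert amplitude_turbulence(field) == pytest.approx(0.0, abs=1e-12)

    def test_transform_table_shape(self, dist30, rng):
        analyzer = TurbulenceAnalyzer(lambdas=lambda_grid(0.01, 0.12, 0.03)).fit(dist30)
        pfs = [phase_field(rng.uniform(-np.pi, np.pi, (30, 60))) for _ in range(2)]
        table = analyzer.transform(pfs)
        assert set(table["subject"]) == {0, 1}
        assert len(table) == 2 * len(analyzer.kernels_.lambdas)
        # cascade is constant within subject
        for _, grp in table.groupby("subject"):
            assert grp["cascade"].nunique() == 1

    def test_sklearn_params_roundtrip(self):
        analyzer = TurbulenceAnalyzer(dt_steps=2)
        params = analyzer.get_params()
        assert params["dt_steps"] == 2
        analyzer.set_params(n_bins=10)
        assert analyzer.n_bins == 10
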