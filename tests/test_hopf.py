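import numpy as np
import pytest

from neuroturb.geometry import build_connectome
from neuroturb.hopf import (
    FcOfDistance,
    ForcingSpec,
    HopfCouplingEstimator,
    HopfSystem,
    fc_of_distance,
    fit_error,
    simulate,
    sweep_coupling,
)
from neuroturb.signal import BoldTimeSeries, bandpass
from neuroturb.synthetic import default_node_frequencies

W05 = 2 * np.pi * 0.05


def uncoupled_system(n=2, a=0.25, noise_sd=0.0, dt=0.05):
    return HopfSystem(
        connectome=np.zeros((n, n)), a=a, omega=W05, G=0.0, noise_sd=noise_sd, dt=dt, tr=2.0
    )


class TestSimulate:
    def test_limit_cycle_radius_sqrt_a(self):
        """Uncoupled noiseless node with a>0 settles on a cycle of radius sqrt(a)."""
        sys = uncoupled_system(a=0.25, dt=0.005)
        _, xs, ys = simulate(
            sys, 64, seed=0, transient_s=60.0,
            initial_state=(np.full(2, 0.5), np.zeros(2)), full_state=True,
        )
        radius = np.hypot(xs, ys)
        assert np.all(np.abs(radius[:, -10:] - 0.5) < 1e-6)

    def test_subcritical_decay_to_fixed_point(self):
        sys = uncoupled_system(a=-0.1, dt=0.05)
        _, xs, ys = simulate(
            sys, 64, seed=0, transient_s=0.0,
            initial_state=(np.full(2, 0.3), np.zeros(2)), full_state=True,
        )
        mod = np.hypot(xs, ys)[0]
        assert mod[-1] < 1e-3
        assert np.all(np.diff(mod) <= 1e-12)

    def test_seeded_determinism_and_independent_node_noise(self, dist30):
        C = build_connectome(dist30)
        sys = HopfSystem(connectome=C, a=-0.02, omega=W05, G=1.0)
        a = simulate(sys, 80, seed=5)
        b = simulate(sys, 80, seed=5)
        assert np.array_equal(a.values, b.values)
        # two identical nodes with independent noise streams diverge
        assert not np.allclose(a.values[0], a.values[1])

    def test_noise_scaling_monotone_variance(self):
        var = []
        for nu in (0.005, 0.01, 0.02):
            vs = []
            for seed in range(5):
                sys = HopfSystem(
                    connectome=np.zeros((1, 1)), a=-0.02, omega=W05, G=0.0, noise_sd=nu
                )
                vs.append(simulate(sys, 150, seed=seed).values.var())
            var.append(np.mean(vs))
        assert var[0] < var[1] < var[2]

    def test_coupling_increases_coherence(self, dist30):
        C = build_connectome(dist30)
        omega = default_node_frequencies(30, seed=3)

        def mean_fc(G):
            vals = []
            for seed in range(3):
                sys = HopfSystem(connectome=C, a=-0.02, omega=omega, G=G)
                ts = simulate(sys, 150, seed=seed)
                c = np.corrcoef(ts.values)
                vals.append(c[np.triu_indices(30, 1)].mean())
            return np.mean(vals)

        assert mean_fc(2.0) > mean_fc(0.0)

    def test_divergence_reported(self):
        # strong positive a with huge coupling on a dense connectome blows up
        sys = HopfSystem(connectome=np.ones((3, 3)) * 1e3, a=5.0, omega=W05, G=1e3,
                         noise_sd=0.0, dt=0.1)
        from neuroturb.hopf import SimulationDiverged

        with pytest.raises(SimulationDiverged):
            with np.errstate(all="ignore"):
                simulate(
                    sys, 64, seed=0,
                    initial_state=(np.array([1.0, 2.0, 3.0]), np.ones(3)),
                )

    def test_forcing_changes_trajectory(self):
        sys = uncoupled_system(a=-0.02, noise_sd=0.01)
        base = simulate(sys, 80, seed=1)
        forced = simulate(
            sys, 80, forcing=ForcingSpec(amplitude=0.1, omega0=W05, enabled=True), seed=1
        )
        assert not np.allclose(base.values, forced.values)


class TestFcOfDistance:
    def test_identical_signals_unit_fc(self, dist30, rng):
        x = rng.standard_normal(200)
        ts = BoldTimeSeries(values=np.tile(x, (30, 1)), tr=2.0)
        curve = fc_of_distance(ts, dist30, 10)
        assert np.allclose(curve.fc, 1.0)
        assert np.allclose(curve.s, 0.0, atol=1e-12)

    def test_independent_noise_null(self, dist30, rng):
        T = 500
        ts = BoldTimeSeries(values=rng.standard_normal((30, T)), tr=2.0)
        curve = fc_of_distance(ts, dist30, 5)
        assert np.all(np.abs(curve.fc) <= 3 / np.sqrt(T))

    def test_matches_brute_force_oracle(self, dist30, rng):
        ts = BoldTimeSeries(values=rng.standard_normal((30, 100)), tr=2.0)
        edges = np.linspace(0, dist30[np.triu_indices(30, 1)].max(), 8)
        curve = fc_of_distance(ts, dist30, edges)
        # brute force: per-pair Pearson, binned
        vals = {b: [] for b in range(7)}
        for i in range(30):
            for j in range(i + 1, 30):
                r = np.corrcoef(ts.values[i], ts.values[j])[0, 1]
                b = min(np.searchsorted(edges, dist30[i, j], side="right") - 1, 6)
                vals[b].append(r)
        expected = [np.mean(vals[b]) for b in range(7) if len(vals[b]) >= 2]
        assert np.allclose(curve.fc, expected, atol=1e-12)

    def test_sparse_bins_dropped_with_counts(self, dist30, rng):
        ts = BoldTimeSeries(values=rng.standard_normal((30, 100)), tr=2.0)
        curve = fc_of_distance(ts, dist30, 40)
        assert np.all(curve.counts >= 2)
        assert len(curve.bin_centres) == len(curve.fc)


class TestFitError:
    def _curve(self, centres, fc):
        fc = np.asarray(fc, dtype=float)
        return FcOfDistance(
            bin_centres=np.asarray(centres, float), fc=fc, s=2 * (1 - fc),
            counts=np.full(len(fc), 10),
        )

    def test_identity_zero(self):
        c = self._curve(np.linspace(5, 50, 10), np.linspace(0.9, 0.1, 10))
        assert fit_error(c, c, (5, 50)) == 0.0

    def test_constant_offset_is_delta(self):
        centres = np.linspace(5, 50, 10)
        a = self._curve(centres, np.linspace(0.9, 0.1, 10))
        b = self._curve(centres, np.linspace(0.9, 0.1, 10) + 0.07)
        assert fit_error(a, b, (5, 50)) == pytest.approx(0.07)

    def test_matches_norm_oracle(self, rng):
        centres = np.linspace(5, 50, 12)
        fa, fb = rng.uniform(0, 1, 12), rng.uniform(0, 1, 12)
        sel = (centres >= 10) & (centres <= 40)
        expected = np.sqrt(np.mean((fa[sel] - fb[sel]) ** 2))
        got = fit_error(self._curve(centres, fa), self._curve(centres, fb), (10, 40))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self._curve(np.linspace(5, 50, 10), np.full(10, 0.5))
        b = self._curve(np.linspace(6, 51, 10), np.full(10, 0.5))
        with pytest.raises(ValueError):
            fit_error(a, b, (5, 50))


class TestSweepCoupling:
    def test_self_fit_at_zero_coupling(self, dist30):
        C = build_connectome(dist30)
        omega = default_node_frequencies(30, seed=3)
        template = HopfSystem(connectome=C, a=-0.02, omega=omega, G=0.0)
        ts = bandpass(simulate(template, 150, seed=9))
        emp = fc_of_distance(ts, dist30, 12)
        g_grid = np.array([0.0, 1.0, 2.0])
        fit = sweep_coupling(template, emp, g_grid, dist30, n_reps=2,
                            duration_volumes=150, seed=9)
        assert fit.g_opt == 0.0
        assert len(fit.fit_errors) == len(g_grid)

    def test_estimator_interface(self, dist30):
        C = build_connectome(dist30)
        omega = default_node_frequencies(30, seed=3)
        gen = HopfSystem(connectome=C, a=-0.02, omega=omega, G=1.0)
        subjects = [simulate(gen, 150, seed=s) for s in (1, 2)]
        est = HopfCouplingEstimator(
            dist=dist30, g_grid=np.array([0.0, 1.0, 2.0]), n_reps=2,
            duration_volumes=120, seed=4,
        )
        est.fit(subjects)
        assert est.g_opt_ in est.coupling_fit_.g_grid
        assert est.system_.G == est.g_opt_
        assert np.all(est.fit_errors_[np.isfinite(est.fit_errors_)] >= 0)
        params = est.get_params()
        assert params["n_reps"] == 2
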