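"""Stochastic integrator: determinism, fixed point, oracle agreement, variance."""

import numpy as np
import pytest

from critwave import LatticeSpec, NoiseSpec
from critwave.dynamics import (
    IntegrationError,
    Trajectory,
    impulse_response,
    integrate,
    stationary_variance,
)
from critwave.spectral import linear_propagate


class TestNoiseSpec:
    def test_negative_eta_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(eta=-0.1)

    def test_timestep_stability_guard(self):
        spec = LatticeSpec(8, g=20.0)
        with pytest.raises(ValueError, match="dt"):
            integrate(spec, NoiseSpec(eta=0.1, dt=0.01), T=1.0)


class TestIntegrate:
    def test_zero_input_zero_state_stays_zero(self, small_spec, quiet_noise):
        traj = integrate(small_spec, quiet_noise, T=1.0)
        assert np.all(traj.states == 0.0)

    def test_deterministic_given_seed(self, small_spec):
        noise = NoiseSpec(eta=0.3, seed=42, dt=0.01)
        a = integrate(small_spec, noise, T=2.0)
        b = integrate(small_spec, noise, T=2.0)
        assert np.array_equal(a.states, b.states)

    def test_different_seeds_differ(self, small_spec):
        a = integrate(small_spec, NoiseSpec(0.3, seed=1, dt=0.01), T=1.0)
        b = integrate(small_spec, NoiseSpec(0.3, seed=2, dt=0.01), T=1.0)
        assert not np.array_equal(a.states, b.states)

    def test_linear_regime_matches_spectral_oracle(self, small_spec):
        """With a tiny impulse the cubic term is negligible and the full
        nonlinear integrator must track exp(At) x0."""
        x0 = np.zeros(small_spec.n_sites)
        x0[small_spec.site_index(4, 4)] = 1e-3
        traj = integrate(
            small_spec, NoiseSpec(0.0, 0, 1e-3), x0=x0, T=2.0,
            save_stride=2000, method="heun", cubic=True,
        )
        ref = linear_propagate(small_spec, x0, 2.0)
        assert np.abs(traj.states[-1] - ref).max() < 1e-3 * np.abs(ref).max()

    def test_halving_dt_halves_endpoint_error(self, small_spec):
        """Euler strong-order consistency for the deterministic part."""
        x0 = np.zeros(small_spec.n_sites)
        x0[0] = 1.0
        ref = linear_propagate(small_spec, x0, 1.0)
        errs = []
        for dt in (0.01, 0.005):
            traj = integrate(
                small_spec, NoiseSpec(0.0, 0, dt), x0=x0, T=1.0,
                save_stride=10**6, method="euler", cubic=False,
            )
            errs.append(np.abs(traj.states[-1] - ref).max())
        assert errs[1] / errs[0] == pytest.approx(0.5, rel=0.25)

    def test_variance_increases_with_eta(self):
        spec = LatticeSpec(16, 1.0)
        out = []
        for eta in (0.05, 0.1, 0.2, 0.4):
            traj = integrate(spec, NoiseSpec(eta, seed=9, dt=0.01), T=80.0,
                             save_stride=10)
            v, _ = stationary_variance(traj, burn_in=40.0)
            out.append(v)
        assert all(b > a for a, b in zip(out, out[1:]))

    def test_instability_raises_with_context(self):
        spec = LatticeSpec(8, 1.0)
        x0 = np.full(spec.n_sites, 50.0)  # cubic blows up under explicit Euler
        with pytest.raises(IntegrationError, match="dt"):
            integrate(spec, NoiseSpec(0.0, 0, 0.01), x0=x0, T=5.0)

    def test_stochastic_requires_euler(self, small_spec):
        with pytest.raises(ValueError):
            integrate(small_spec, NoiseSpec(0.5, 0, 0.01), T=1.0, method="rk4")


class TestStationaryVariance:
    def test_zero_trajectory(self, small_spec, quiet_noise):
        traj = integrate(small_spec, quiet_noise, T=1.0)
        v, per_site = stationary_variance(traj, burn_in=0.5)
        assert v == 0.0
        assert np.all(per_site == 0.0)

    def test_constant_trajectory(self):
        times = np.linspace(0, 10, 11)
        states = np.full((11, 16), 3.0)
        v, _ = stationary_variance(Trajectory(times, states), burn_in=2.0)
        assert v == pytest.approx(9.0)

    def test_burn_in_must_leave_samples(self, small_spec, quiet_noise):
        traj = integrate(small_spec, quiet_noise, T=1.0)
        with pytest.raises(ValueError):
            stationary_variance(traj, burn_in=2.0)


class TestImpulseResponse:
    def test_envelope_decays_with_distance(self):
        from critwave.lattice import distance_shells

        spec = LatticeSpec(16, 1.0)
        shells = distance_shells(spec)
        traj = impulse_response(spec, T=2.0)
        snap = np.abs(traj.states[-1])
        shell_means = [snap[shells.shells[int(r)]].mean() for r in shells.radii]
        # locality: amplitude near center far exceeds the outermost shells
        assert shell_means[0] + shell_means[1] > 10 * shell_means[-1]

    def test_small_impulse_scales_linearly(self):
        spec = LatticeSpec(16, 1.0)
        big = impulse_response(spec, T=2.0, amplitude=1e-3, save_stride=100)
        small = impulse_response(spec, T=2.0, amplitude=1e-4, save_stride=100)
        ref = big.states[-1]
        scaled = 10.0 * small.states[-1]
        denom = np.abs(ref).max()
        assert np.abs(scaled - ref).max() / denom < 1e-2

    def test_wraparound_warning_recorded(self):
        spec = LatticeSpec(8, 1.0)
        traj = impulse_response(spec, T=10.0)  # guard is n/(4g) = 2
        assert "warning" in traj.meta

    def test_trajectory_roundtrip(self, tmp_path):
        spec = LatticeSpec(8, 1.0)
        traj = impulse_response(spec, T=1.0, save_stride=10)
        path = tmp_path / "traj.npz"
        traj.save(path)
        back = Trajectory.load(path)
        assert np.array_equal(back.states, traj.states)
        assert back.meta["n"] == spec.n
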