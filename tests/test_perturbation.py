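"""Tangent-linear propagation, attenuation profiles, and decay-model fits."""

import math

import numpy as np
import pytest

from critwave import LatticeSpec, NoiseSpec
from critwave.lattice import distance_shells
from critwave.perturbation import (
    AttenuationProfile,
    FitWindowError,
    attenuation_profile,
    default_horizon,
    derive_seed,
    fit_attenuation,
    range_vs_input,
    tangent_propagate,
    twin_difference,
)
from critwave.spectral import linear_propagate


class TestTangentPropagate:
    def test_zero_background_is_pure_linear_response(self):
        """With eta=0 the background stays 0, the damping vanishes, and the
        tangent flow reduces to exp(At) applied to the impulse."""
        spec = LatticeSpec(8, 1.0)
        run = tangent_propagate(
            spec, NoiseSpec(0.0, 0, 1e-3), T=1.5, burn_in=0.0,
            save_stride=1500, method="rk4",
        )
        assert np.all(run.background.states == 0.0)
        d0 = np.zeros(spec.n_sites)
        d0[run.center] = 1.0
        ref = linear_propagate(spec, d0, 1.5)
        assert np.abs(run.delta.states[-1] - ref).max() < 1e-8

    def test_frozen_background_closed_form(self):
        """x^2 frozen at v: delta(t) = exp(-3vt) * exp(At) delta0 exactly."""
        spec = LatticeSpec(16, 1.0)
        v = 0.3
        run = tangent_propagate(
            spec, NoiseSpec(0.0, 0, 1e-3), T=3.0, burn_in=0.0,
            frozen_variance=v, method="rk4", save_stride=1000,
        )
        d0 = np.zeros(spec.n_sites)
        d0[run.center] = 1.0
        for i, t in enumerate(run.delta.times):
            ref = math.exp(-3 * v * t) * linear_propagate(spec, d0, t)
            err = np.linalg.norm(run.delta.states[i] - ref) / np.linalg.norm(ref)
            assert err < 1e-3

    def test_tangent_flow_is_exactly_linear_in_amplitude(self):
        spec = LatticeSpec(8, 1.0)
        noise = NoiseSpec(0.2, seed=5, dt=0.01)
        one = tangent_propagate(spec, noise, T=2.0, amplitude=1.0)
        scaled = tangent_propagate(spec, noise, T=2.0, amplitude=0.25)
        assert np.allclose(one.delta.states * 0.25, scaled.delta.states,
                           rtol=0, atol=1e-14)
        assert np.array_equal(one.background.states, scaled.background.states)

    def test_perturbation_bounded_by_initial_norm_when_damped(self):
        """Frozen nonnegative damping: sup_t ||delta|| <= ||delta(0)||."""
        spec = LatticeSpec(8, 1.0)
        run = tangent_propagate(
            spec, NoiseSpec(0.0, 0, 0.005), T=4.0, burn_in=0.0,
            frozen_variance=0.1, method="heun", save_stride=20,
        )
        norms = np.linalg.norm(run.delta.states, axis=1)
        assert norms.max() <= norms[0] * (1 + 1e-9)

    def test_stochastic_run_stays_bounded(self):
        spec = LatticeSpec(16, 1.0)
        run = tangent_propagate(spec, NoiseSpec(0.3, 3, 0.01), T=8.0)
        norms = np.linalg.norm(run.delta.states, axis=1)
        assert np.all(np.isfinite(norms))
        assert norms.max() <= norms[0] * 1.5

    def test_twin_trajectory_agrees_as_eps_shrinks(self):
        """Finite-difference twin runs converge to the tangent solution."""
        spec = LatticeSpec(8, 1.0)
        noise = NoiseSpec(0.2, seed=8, dt=0.01)
        tangent = tangent_propagate(spec, noise, T=3.0, save_stride=30)
        errs = []
        for eps in (1e-1, 1e-3):
            twin = twin_difference(spec, noise, T=3.0, eps=eps, save_stride=30)
            errs.append(
                np.abs(twin.states[-1] - tangent.delta.states[-1]).max()
            )
        # one-sided difference: linearization error is O(eps)
        assert errs[1] < errs[0] / 10
        assert errs[1] < 5e-4


class TestAttenuationProfile:
    def test_shell_zero_contains_initial_unit_amplitude(self):
        spec = LatticeSpec(8, 1.0)
        shells = distance_shells(spec)
        run = tangent_propagate(spec, NoiseSpec(0.1, 2, 0.01), T=1.0)
        prof = attenuation_profile([run], shells)
        assert prof.M[0] >= 1.0  # max over time includes t=0

    def test_zero_input_profile_strictly_positive(self):
        spec = LatticeSpec(16, 1.0)
        shells = distance_shells(spec)
        run = tangent_propagate(spec, NoiseSpec(0.0, 0, 0.01), T=6.0, burn_in=0.0)
        prof = attenuation_profile([run], shells)
        assert np.all(prof.M > 0)

    def test_profile_is_mean_of_run_profiles(self):
        spec = LatticeSpec(8, 1.0)
        shells = distance_shells(spec)
        runs = [
            tangent_propagate(spec, NoiseSpec(0.2, s, 0.01), T=1.0)
            for s in (1, 2)
        ]
        merged = attenuation_profile(runs, shells)
        singles = [attenuation_profile([r], shells) for r in runs]
        assert np.allclose(merged.M, 0.5 * (singles[0].M + singles[1].M))

    def test_inconsistent_runs_rejected(self):
        spec = LatticeSpec(8, 1.0)
        shells = distance_shells(spec)
        a = tangent_propagate(spec, NoiseSpec(0.1, 1, 0.01), T=0.5)
        b = tangent_propagate(spec, NoiseSpec(0.2, 1, 0.01), T=0.5)
        with pytest.raises(ValueError):
            attenuation_profile([a, b], shells)


def synthetic_profile(fn, r_max=30, n=64):
    radii = np.arange(0.0, r_max + 1)
    M = np.array([fn(max(r, 1e-9)) for r in radii])
    M[0] = max(M[1], 1.0)
    return AttenuationProfile(
        radii=radii, M=M, n_realizations=1, eta=0.1,
        meta={"bc": "periodic", "n": n, "g": 1.0},
    )


class TestFitAttenuation:
    def test_exact_exponential_recovered(self):
        prof = synthetic_profile(lambda r: math.exp(-r / 5.0))
        fits = fit_attenuation(prof)
        assert fits.exponential.lam == pytest.approx(5.0, abs=1e-6)
        assert fits.exponential.kappa * fits.exponential.lam == pytest.approx(1.0)
        assert fits.preferred == "exponential"

    def test_power_law_identified_on_noiseless_input(self):
        prof = synthetic_profile(lambda r: r ** -0.5)
        fits = fit_attenuation(prof)
        assert fits.power_law.r2 > fits.exponential.r2
        assert fits.preferred == "power-law"
        assert fits.power_law.exponent == pytest.approx(-0.5, abs=1e-9)

    def test_too_few_usable_shells(self):
        prof = synthetic_profile(lambda r: math.exp(-r / 5.0), r_max=3)
        with pytest.raises(FitWindowError):
            fit_attenuation(prof)

    def test_floor_clipped_window_rejected(self):
        prof = synthetic_profile(lambda r: math.exp(-r * 6.0))  # underflows fast
        with pytest.raises(FitWindowError):
            fit_attenuation(prof)

    def test_rising_window_rejected(self):
        prof = synthetic_profile(lambda r: 1.0 + 0.1 * r)
        with pytest.raises(FitWindowError):
            fit_attenuation(prof)

    def test_full_shells_only_under_periodic_bc(self):
        # same synthetic decay, but radii extend past n/2: the fit window
        # must not use them
        prof = synthetic_profile(lambda r: math.exp(-r / 5.0), r_max=45, n=64)
        fits = fit_attenuation(prof)
        assert fits.exponential.window.max() <= 32


class TestRangeVsInput:
    def test_seed_isolation_under_grid_permutation(self):
        """Each eta's result depends only on (master seed, eta), so the
        grid may be extended or reordered without changing rows."""
        spec = LatticeSpec(16, 1.0)
        kw = dict(n_realizations=2, master_seed=7, T=4.0, burn_in=2.0)
        full = range_vs_input(spec, [0.1, 0.3], **kw)
        only = range_vs_input(spec, [0.3], **kw)
        row_full = full[full.eta == 0.3].iloc[0]
        row_only = only.iloc[0]
        for col in ("lam", "kappa", "r2"):
            a, b = row_full[col], row_only[col]
            assert (a == b) or (np.isnan(a) and np.isnan(b))

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            range_vs_input(LatticeSpec(16, 1.0), [0.2, 0.1])

    def test_per_eta_failure_recorded_not_fatal(self):
        # horizon of two steps: the perturbation cannot reach the outer
        # shells, the window is floor-clipped, and the fit must fail softly
        spec = LatticeSpec(8, 1.0)
        table = range_vs_input(spec, [0.05], n_realizations=1, master_seed=1,
                               T=0.02, burn_in=0.5)
        assert len(table) == 1
        assert isinstance(table.iloc[0]["error"], str)

    def test_derive_seed_keyed_on_eta_value(self):
        a = derive_seed(1, 0.1, 0)
        b = derive_seed(1, 0.1, 0)
        c = derive_seed(1, 0.2, 0)
        assert a.entropy == b.entropy
        assert a.entropy != c.entropy


def test_default_horizon_reaches_every_shell():
    spec = LatticeSpec(64, 1.0)
    shells = distance_shells(spec)
    T = default_horizon(spec, shells)
    # worst-case ballistic arrival at radius r is r / (2g)
    assert T >= shells.radii.max() * 0.8 / (2 * spec.g)
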