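"""Tangent-linear perturbation propagation and attenuation-length fitting.

The central experiment: a noise-driven background x(t) evolves under the
full nonlinear model while an infinitesimal perturbation delta, confined
at time zero to a single site, is carried along by the tangent-linear
(Floquet) dynamics

    d(delta)/dt = A delta - 3 x(t)^2 delta,

the linearization of the cubic model about the running background.  The
background variance enters as an effective temporal damping ~ 3<x^2>, so
with input present the outgoing perturbation "wave" is attenuated
exponentially in distance, with attenuation length lambda = 1/kappa that
shrinks as the input amplitude eta grows.  At eta = 0 the background
vanishes, the damping disappears, and the decay is algebraic (power-law):
the susceptibility range is infinite.

The profile statistic follows the experiment's definition: for each site
the maximum |delta| it ever attains, then averaged over each distance
shell and over noise realizations; the attenuation length comes from a
log-linear fit over the outermost shells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_BURN_IN,
    NoiseSpec,
    Trajectory,
    _check_overflow,
    step_euler_maruyama,
    step_heun,
    step_rk4,
)
from .lattice import DistanceShells, LatticeSpec, build_coupling, distance_shells
from .spectral import speed_scale

__all__ = [
    "PerturbationRun",
    "AttenuationProfile",
    "AttenuationFit",
    "AttenuationFitPair",
    "FitWindowError",
    "tangent_propagate",
    "twin_difference",
    "attenuation_profile",
    "fit_attenuation",
    "range_vs_input",
    "default_horizon",
    "derive_seed",
]

#: numeric floor below which a shell amplitude is treated as unresolved
AMPLITUDE_FLOOR = 1e-12


class FitWindowError(RuntimeError):
    """The requested fit window is unusable (too few shells, clipped, or rising)."""


@dataclass
class PerturbationRun:
    """A background trajectory with its co-integrated tangent perturbation."""

    background: Trajectory
    delta: Trajectory
    center: int
    eta: float
    #: per-site max over *every* integration step of |delta| (not strided)
    site_max: np.ndarray = field(repr=False)
    meta: dict[str, Any] = field(default_factory=dict)


def derive_seed(master_seed: int, eta: float, realization: int) -> np.random.SeedSequence:
    """Counter-based child seed for one (eta, realization) cell.

    Keyed on the eta *value*, not its grid position, so extending or
    permuting the grid never reshuffles existing runs.
    """
    eta_key = int(round(eta * 10**9))
    return np.random.SeedSequence([int(master_seed), eta_key, int(realization)])


def default_horizon(spec: LatticeSpec, shells: DistanceShells | None = None) -> float:
    """Measurement horizon T = 0.8 * r_max / v, v = 2g the dispersion speed scale.

    Long enough for the front to sweep the whole fit window (worst-case
    ballistic arrival is r_max / 2g), short enough to limit re-entrant
    propagation around the torus.
    """
    if shells is None:
        shells = distance_shells(spec)
    return 0.8 * float(shells.radii.max()) / speed_scale(spec)


def tangent_propagate(
    spec: LatticeSpec,
    noise: NoiseSpec,
    center: int | tuple[int, int] | None = None,
    T: float = 10.0,
    burn_in: float | None = None,
    save_stride: int = 10,
    amplitude: float = 1.0,
    frozen_variance: float | None = None,
    method: str = "euler",
    rng: np.random.Generator | None = None,
) -> PerturbationRun:
    """Co-integrate background and tangent-linear perturbation.

    The same noise realization drives only the background x; the tangent
    state delta starts as an impulse of ``amplitude`` at ``center`` and
    evolves under d(delta)/dt = A delta - 3 x^2 delta.  The background is
    first burned in for ``burn_in`` time units (default 50/g) so the
    perturbation rides on stationary activity.

    ``frozen_variance`` is a test hook: it replaces the fluctuating x^2 by
    a constant v, for which the exact solution is
    exp(-3 v t) * exp(A t) delta0.  Deterministic steppers ("heun",
    "rk4") are available only when the background is frozen or eta = 0.
    """
    if center is None:
        center = spec.center
    c_idx = spec.site_index(*center) if isinstance(center, tuple) else int(center)
    if burn_in is None:
        burn_in = DEFAULT_BURN_IN / spec.g
    noise.check_stability(spec)
    deterministic = frozen_variance is not None or noise.eta == 0
    if method != "euler" and not deterministic:
        raise ValueError("deterministic steppers require frozen or zero-input background")

    A = build_coupling(spec)
    n = spec.n_sites
    dt = noise.dt
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    x = np.zeros(n)
    if frozen_variance is None and noise.eta > 0:
        for step in range(int(round(burn_in / dt))):
            x = step_euler_maruyama(A, x, dt, True, noise.eta, rng)
            if step % 256 == 0:
                _check_overflow(x, dt, spec.g)

    delta = np.zeros(n)
    delta[c_idx] = amplitude
    site_max = np.abs(delta)

    n_steps = int(round(T / dt))
    times = [0.0]
    x_saved, d_saved = [x.copy()], [delta.copy()]

    def damping_sq(xv: np.ndarray) -> np.ndarray | float:
        return frozen_variance if frozen_variance is not None else xv**2

    for step in range(1, n_steps + 1):
        xsq = damping_sq(x)
        if method == "euler":
            delta = delta + dt * (A @ delta - 3.0 * xsq * delta)
        elif method == "heun":
            k1 = A @ delta - 3.0 * xsq * delta
            d1 = delta + dt * k1
            k2 = A @ d1 - 3.0 * xsq * d1
            delta = delta + 0.5 * dt * (k1 + k2)
        else:  # rk4; background frozen or zero, so xsq is step-constant
            def f(d):
                return A @ d - 3.0 * xsq * d
            k1 = f(delta)
            k2 = f(delta + 0.5 * dt * k1)
            k3 = f(delta + 0.5 * dt * k2)
            k4 = f(delta + dt * k3)
            delta = delta + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if frozen_variance is None:
            if noise.eta > 0:
                x = step_euler_maruyama(A, x, dt, True, noise.eta, rng)
            elif method == "heun":
                x = step_heun(A, x, dt, True)
            elif method == "rk4":
                x = step_rk4(A, x, dt, True)
            else:
                x = step_euler_maruyama(A, x, dt, True, 0.0, rng)
        np.maximum(site_max, np.abs(delta), out=site_max)
        if step % 256 == 0:
            _check_overflow(delta, dt, spec.g)
            _check_overflow(x, dt, spec.g)
        if step % save_stride == 0 or step == n_steps:
            times.append(step * dt)
            x_saved.append(x.copy())
            d_saved.append(delta.copy())
    _check_overflow(delta, dt, spec.g)

    meta = {
        "n": spec.n, "g": spec.g, "bc": spec.bc, "eta": noise.eta,
        "seed": noise.seed, "dt": dt, "burn_in": burn_in,
        "center": c_idx, "amplitude": amplitude,
        "frozen_variance": frozen_variance, "method": method,
    }
    bg = Trajectory(np.asarray(times), np.asarray(x_saved), dict(meta, kind="background"))
    dl = Trajectory(np.asarray(times), np.asarray(d_saved), dict(meta, kind="tangent"))
    return PerturbationRun(
        background=bg, delta=dl, center=c_idx, eta=noise.eta,
        site_max=site_max, meta=meta,
    )


def twin_difference(
    spec: LatticeSpec,
    noise: NoiseSpec,
    center: int | tuple[int, int] | None = None,
    T: float = 10.0,
    burn_in: float | None = None,
    eps: float = 1e-4,
    save_stride: int = 10,
) -> Trajectory:
    """Finite-difference cross-check of the tangent system.

    Two trajectories share the same noise realization; one receives an
    extra impulse of size eps at ``center`` after burn-in.  Returns
    (x_perturbed - x_reference)/eps, which converges to the tangent
    solution as eps -> 0 (but suffers cancellation for very small eps).
    """
    if center is None:
        center = spec.center
    c_idx = spec.site_index(*center) if isinstance(center, tuple) else int(center)
    if burn_in is None:
        burn_in = DEFAULT_BURN_IN / spec.g
    noise.check_stability(spec)
    A = build_coupling(spec)
    dt = noise.dt
    rng = np.random.default_rng(noise.seed)

    x = np.zeros(spec.n_sites)
    for _ in range(int(round(burn_in / dt))):
        x = step_euler_maruyama(A, x, dt, True, noise.eta, rng)
    xp = x.copy()
    xp[c_idx] += eps

    n_steps = int(round(T / dt))
    times, diffs = [0.0], [(xp - x) / eps]
    sqrt_dt = math.sqrt(dt)
    for step in range(1, n_steps + 1):
        xi = rng.standard_normal(spec.n_sites) if noise.eta > 0 else 0.0
        x = x + dt * (A @ x - x**3) + noise.eta * sqrt_dt * xi
        xp = xp + dt * (A @ xp - xp**3) + noise.eta * sqrt_dt * xi
        if step % save_stride == 0 or step == n_steps:
            times.append(step * dt)
            diffs.append((xp - x) / eps)
    meta = {"n": spec.n, "g": spec.g, "eta": noise.eta, "eps": eps, "center": c_idx}
    return Trajectory(np.asarray(times), np.asarray(diffs), meta)


@dataclass(frozen=True)
class AttenuationProfile:
    """Per-shell maximal perturbation amplitude M(r), realization-averaged."""

    radii: np.ndarray  # strictly increasing, lattice units
    M: np.ndarray  # >= 0
    n_realizations: int
    eta: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(self.M < 0):
            raise ValueError("M must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.radii, "M": self.M})


def attenuation_profile(
    runs: Sequence[PerturbationRun],
    shells: DistanceShells,
    stat: str = "mean",
) -> AttenuationProfile:
    """Distance profile M(r): shell statistic of per-site max_t |delta|.

    Shell mean by default (variance reduction); ``stat="max"`` exposes the
    per-shell maximum instead.  Multiple runs must share lattice, eta and
    center; their profiles are arithmetically averaged.
    """
    if len(runs) == 0:
        raise ValueError("need at least one run")
    ref = runs[0]
    for run in runs[1:]:
        same = (
            run.eta == ref.eta
            and run.center == ref.center
            and run.meta.get("n") == ref.meta.get("n")
            and run.meta.get("g") == ref.meta.get("g")
        )
        if not same:
            raise ValueError("runs disagree in lattice spec, eta, or center")
    if ref.center != shells.center:
        raise ValueError("shells center does not match run center")
    reducer = {"mean": np.mean, "max": np.max}[stat]
    profiles = []
    for run in runs:
        profiles.append(
            [reducer(run.site_max[shells.shells[int(r)]]) for r in shells.radii]
        )
    M = np.asarray(profiles).mean(axis=0)
    return AttenuationProfile(
        radii=shells.radii.astype(float),
        M=M,
        n_realizations=len(runs),
        eta=ref.eta,
        meta={"stat": stat, "bc": ref.meta.get("bc", "periodic"),
              "n": ref.meta.get("n"), "g": ref.meta.get("g")},
    )


@dataclass(frozen=True)
class AttenuationFit:
    """One decay-model fit to the outer window of a profile."""

    model: str  # "exponential" | "power-law"
    slope: float
    intercept: float
    r2: float
    aic: float
    window: np.ndarray  # radii used
    kappa: float | None = None  # exponential only: spatial decay constant
    lam: float | None = None  # 1/kappa (inf when kappa <= 0)
    exponent: float | None = None  # power-law only


@dataclass(frozen=True)
class AttenuationFitPair:
    exponential: AttenuationFit
    power_law: AttenuationFit

    @property
    def preferred(self) -> str:
        return (
            "exponential"
            if self.exponential.aic < self.power_law.aic
            else "power-law"
        )


def _ls_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    rss = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / ss_tot if ss_tot > 0 else 1.0
    n = len(x)
    aic = n * math.log(max(rss, 1e-300) / n) + 2 * 2
    return float(slope), float(intercept), r2, aic


def fit_attenuation(
    profile: AttenuationProfile,
    window_frac: float = 1.0 / 3.0,
    floor: float = AMPLITUDE_FLOOR,
    drop_outer: int | None = None,
    max_radius: float | None = None,
) -> AttenuationFitPair:
    """Fit exponential and power-law decay to the outermost shells.

    The window is the outermost ``window_frac`` of usable radii (r > 0 and
    M above ``floor``), excluding the outermost ``drop_outer`` shells
    (defaults to 2 under open boundaries, 0 under periodic).  log M is
    regressed on r (exponential: slope = -kappa, lambda = 1/kappa) and on
    log r (power law); both fits are returned with r^2 and AIC.

    Under periodic boundaries only *full* shells, r <= n/2, enter the fit
    (``max_radius`` overrides): beyond half the edge length the
    minimum-image shell is direction-censored and the four periodic image
    waves focus at the torus corner, inflating M there.

    Raises :class:`FitWindowError` rather than extrapolating when fewer
    than 4 shells remain, when floor-clipped shells punch holes in the
    window, or when the window amplitude is rising with distance.
    """
    if drop_outer is None:
        drop_outer = 2 if profile.meta.get("bc") == "open" else 0
    if max_radius is None:
        n = profile.meta.get("n")
        if n is not None and profile.meta.get("bc", "periodic") == "periodic":
            max_radius = n / 2
        else:
            max_radius = math.inf
    radii, M = profile.radii, profile.M
    keep = (radii > 0) & (radii <= max_radius)
    if drop_outer > 0:
        if int(keep.sum()) <= drop_outer:
            raise FitWindowError("too few shells after dropping boundary shells")
        keep &= radii < radii[keep][-drop_outer]
    radii, M = radii[keep], M[keep]
    usable = M > floor
    if usable.sum() < 4:
        raise FitWindowError(
            f"only {int(usable.sum())} shells above floor {floor:g}; need >= 4"
        )
    r_u, m_u = radii[usable], M[usable]
    n_window = max(4, math.ceil(window_frac * len(r_u)))
    r_w, m_w = r_u[-n_window:], m_u[-n_window:]
    # clipped shells inside the window span would bias the log fit silently
    clipped_inside = (~usable) & (radii >= r_w[0])
    if np.any(clipped_inside):
        raise FitWindowError(
            "floor-clipped shells inside the fit window "
            f"(radii {radii[clipped_inside].tolist()}); profile unresolved there"
        )
    log_m = np.log(m_w)
    s_e, b_e, r2_e, aic_e = _ls_fit(r_w, log_m)
    if s_e >= 0:
        raise FitWindowError(
            f"window amplitude non-decaying (log-slope {s_e:.3g} >= 0)"
        )
    kappa = -s_e
    exp_fit = AttenuationFit(
        model="exponential", slope=s_e, intercept=b_e, r2=r2_e, aic=aic_e,
        window=r_w, kappa=kappa, lam=(1.0 / kappa) if kappa > 0 else math.inf,
    )
    s_p, b_p, r2_p, aic_p = _ls_fit(np.log(r_w), log_m)
    pow_fit = AttenuationFit(
        model="power-law", slope=s_p, intercept=b_p, r2=r2_p, aic=aic_p,
        window=r_w, exponent=s_p,
    )
    return AttenuationFitPair(exponential=exp_fit, power_law=pow_fit)


def range_vs_input(
    spec: LatticeSpec,
    eta_grid: Sequence[float],
    n_realizations: int = 8,
    master_seed: int = 0,
    center: int | tuple[int, int] | None = None,
    dt: float | None = None,
    T: float | None = None,
    burn_in: float | None = None,
    window_frac: float = 1.0 / 3.0,
    stat: str = "mean",
    keep_profiles: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[float, AttenuationProfile]]:
    """Attenuation length versus input amplitude: the full pipeline per eta.

    For each eta the tangent experiment is repeated over ``n_realizations``
    seeds (derived from ``master_seed`` and the eta value, so rows are
    independent of grid order), profiles are averaged, and the outer-window
    fits performed.  Zero-input rows are deterministic and run once.
    Per-eta fit failures are recorded in the ``error`` column, not raised.
    """
    if list(eta_grid) != sorted(eta_grid):
        raise ValueError("eta_grid must be sorted ascending")
    if dt is None:
        dt = 0.01 / spec.g
    if center is None:
        center = spec.center
    shells = distance_shells(spec, center)
    if T is None:
        T = default_horizon(spec, shells)

    rows = []
    profiles: dict[float, AttenuationProfile] = {}
    for eta in eta_grid:
        n_real = 1 if eta == 0 else n_realizations
        runs = []
        for real in range(n_real):
            rng = np.random.default_rng(derive_seed(master_seed, eta, real))
            noise = NoiseSpec(eta=eta, seed=master_seed, dt=dt)
            runs.append(
                tangent_propagate(
                    spec, noise, center=center, T=T, burn_in=burn_in,
                    save_stride=max(1, int(round(0.1 / dt))), rng=rng,
                )
            )
        prof = attenuation_profile(runs, shells, stat=stat)
        profiles[float(eta)] = prof
        row = {
            "eta": float(eta), "n_realizations": n_real,
            "lam": math.nan, "kappa": math.nan, "r2": math.nan,
            "r2_power": math.nan, "aic_exp": math.nan, "aic_power": math.nan,
            "preferred": "", "error": "",
        }
        try:
            fits = fit_attenuation(prof, window_frac=window_frac)
        except FitWindowError as err:
            row["error"] = str(err)
        else:
            row.update(
                lam=fits.exponential.lam, kappa=fits.exponential.kappa,
                r2=fits.exponential.r2, r2_power=fits.power_law.r2,
                aic_exp=fits.exponential.aic, aic_power=fits.power_law.aic,
                preferred=fits.preferred,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if keep_profiles:
        return table, profiles
    return table
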