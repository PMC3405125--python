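# Methods

## Model

The lattice places one scalar unit on each site of an `N x N` torus
(N even, default periodic boundaries). The coupling matrix is
`A[i, j] = g * sigma(j)` for nearest neighbours, `sigma` the checkerboard
parity of the presynaptic site: an inhibitory unit inhibits all four of
its neighbours with the same magnitude `g` that an excitatory unit uses
to excite. Because nearest neighbours always carry opposite parity the
matrix is antisymmetric *exactly* (the two matched entries are the same
floating-point number with opposite signs), so the linear dynamics is
norm-preserving and every eigenvalue is purely imaginary: the network
sits at a high-dimensional Hopf bifurcation, with no stability margin to
hide input-independent length- or timescales in.

The full dynamics per site is `dx/dt = Ax - x^3 + I(t)`, with a strictly
local cubic saturation and, when driven, spatiotemporal Gaussian white
noise `I` of amplitude `eta` (independent across sites and time steps,
variance `eta^2 dt` per Euler step). State variables are real scalars;
the cubic is the simplest local saturating nonlinearity consistent with
the balanced-coupling picture, and it fixes the tangent damping
coefficient below to `3 x^2`. A complex-state variant would change that
prefactor but none of the monotonicity phenomenology tested here.

### Spectral structure

Writing `A = C S` with `C` the g-weighted adjacency and `S = diag(sigma)`,
the checkerboard gives `S C S = -C`, hence `A^2 = -C^2`. `C` is
translation invariant and diagonal in the 2D DFT basis with symbol
`omega(k) = 2g(cos kx + cos ky)`; the eigenvalue multiset of `A` is
`{i * omega(k)}` over the discrete Brillouin grid (verified against dense
eigendecomposition in the tests). Splitting the exponential series into
even and odd parts yields the exact propagator

```
exp(At) x = cos(Ct) x + t sinc(Ct) (Ax),
```

two FFTs per evaluation, norm-preserving to round-off. This closed form
*is* the continuum "space-time membrane" picture made exact on the
lattice, and serves as the oracle for every time-stepping integrator.
Group speed is direction dependent: `2g` along axes, `2*sqrt(2)*g` along
diagonals; the package uses `v = 2g` as the horizon speed scale because
it is the worst-case (slowest) ballistic arrival bound on the square
fundamental domain.

## Integrators

* **Euler–Maruyama** (default, the only stepper valid with noise):
  additive noise, so Ito and Stratonovich coincide. Default
  `dt = 0.01/g`; a guard rejects `dt * 4g >= 0.5` (band edge `4g` must be
  resolved) and an overflow guard aborts with the offending `dt, g` named.
  On the purely imaginary spectrum Euler inflates the norm by
  `O(dt)` per unit time; this is measured, not hidden (see the
  conservation checks).
* **Heun** and **RK4** (deterministic only): used for zero-input
  convergence studies and oracle comparisons, where Euler's `O(dt)` norm
  inflation would mask the physics. The cubic-dissipation monotonicity
  check (`d||x||^2/dt = -2 sum x^4 <= 0`) uses Heun, whose spurious
  growth is `O(dt^3)` per unit time and therefore far below the cubic
  contraction.

## Tangent-linear experiment

The perturbation is propagated as a true tangent system
`d(delta)/dt = A delta - 3 x^2 delta` co-integrated with the background
(same noise realization driving `x` only), not as a difference of twin
trajectories — this avoids finite-difference cancellation; a twin-run
mode exists as a cross-check and converges to the tangent solution as the
impulse size shrinks. The background is burned in for `50/g` before the
impulse so the perturbation rides on stationary activity.

* **Profile statistic**: per site, the maximum of `|delta|` over *every*
  integration step (tracked inside the loop, so storage stride cannot
  alias peaks); then the mean over each distance shell (variance
  reduction; shell max is available as an option); then the arithmetic
  mean over realizations. Profiles are averaged before fitting — fitting
  per-realization lambdas and averaging is noisier in the log-tail.
* **Distance shells**: rounded Euclidean minimum-image distance. Fits use
  only *full* shells `r <= N/2`: beyond half the edge the minimum-image
  shell samples only near-diagonal directions and the four periodic image
  waves focus at the torus corner, visibly inflating `M(r)` there.
* **Fit window**: the outermost third of usable radii (`M` above a
  `1e-12` floor), at least 4 shells; under open boundaries the outermost
  2 shells are additionally dropped (edge reflections). `log M` is
  regressed on `r` (exponential; `kappa = -slope`, `lambda = 1/kappa`)
  and on `log r` (power law); both are reported with `r^2` and AIC (equal
  parameter count, so the AIC comparison reduces to residual sums on the
  same response). A rising or floor-clipped window is a diagnostic error,
  never a silent extrapolation.
* **Horizon**: `T = 0.8 * r_max / (2g)` with `r_max` the largest
  minimum-image radius (~0.707 N). Since every direction propagates at
  `>= 2g`, the front reaches all analysed shells (`r <= N/2`) within the
  horizon, while re-entrant propagation contaminates only the excluded
  corner shells.
* **Seeds**: each (eta, realization) cell derives its generator from
  `SeedSequence([master, round(eta * 1e9), realization])`, so extending or
  permuting the eta grid never reshuffles existing runs. The `eta = 0`
  row is deterministic (background identically zero) and runs once.
* **Default experiment scale**: `N = 64`, `g = 1`, `dt = 0.01`,
  `eta in {0, 0.05, 0.1, 0.2, 0.4}`, 8 realizations per driven eta — a
  desk-scale configuration in which the monotone `lambda(eta)` ordering
  is stable from seed to seed.

### What the mean-field damping check does and does not show

Averaging the tangent equation suggests the background enters as an
effective damping `3 <x^2>`. Measured as the decay rate of the
realization-averaged `log ||delta||_2`, the rate sits at roughly 80% of
`3 <x^2>`: the identity `d log||delta|| / dt = -3 * (delta^2-weighted
x^2)` shows the perturbation preferentially occupies transiently quiet
sites, so the delta-weighted variance is genuinely below the plain
average. This is a real fluctuation correction, not an integrator
artifact — though at the default `dt = 0.01` the Euler discretization
biases the ratio further (to ~0.70); the damping-consistency check
therefore integrates at `dt = 0.0025`, where the ratio is converged
(~0.83 at `dt = 0.001`). The comparison is made over a short horizon
(`T = 3/g`, 16 realizations, N = 32): the mean-field statement is a
lowest-order one and the quiet-site weighting deepens on longer windows.

### Front speed

Shell arrival is the first local maximum of the per-shell *max* `|x|`
exceeding 1% of the global maximum; speed is the reciprocal slope of
arrival time versus radius over the outer half of full shells. The shell
max (rather than mean) is deliberate: arrival is direction dependent
(`2g` to `2*sqrt(2)*g`), and the mean smears the crest across directions,
leaving ill-conditioned arrival times, while the leading crest gives a
cleanly linear fit. The estimate therefore tracks the *fastest*
(diagonal) front, ~2.7 lattice units per unit time at `g = 1`.

## Forced Hopf oscillator

`dz/dt = i w0 z - |z|^2 z + F exp(i w0 t)`, forcing exactly at resonance
(detuning out of scope). Steady state `R = F^(1/3)`; linearizing the
co-rotating amplitude equation about `R` gives the radial rate
`3 F^(2/3)` and phase rate `F^(2/3)` — reported separately, never mixed
into one fit. The simulator uses fixed-step RK4 on the complex lab-frame
ODE (`dt = min(0.05/w0, 0.02/rate)`); the empirical rate is fitted to
`log |a - R|` over deviations between `3e-3 R` and `3e-2 R`, small enough
that the quadratic correction to the linearization (which biases the
apparent rate downward by ~`|a - R|/R`) is below 2%, and far above RK4
round-off. At `F = 0` there is no linear relaxation (algebraic decay);
the code flags this rather than fitting.

## Synthetic inputs

No external data exists for this model; every input is generated
internally (lattice spec, white-noise drive, impulse initial conditions).
The white-noise drive stands in for sensory input of a given intensity;
it reproduces the input-gated attenuation phenomenology but none of the
spatial or temporal structure of real stimuli, so passing tests
demonstrate properties of the model class, not fits to physiological
recordings. Lattice units are abstract: no mapping to cortical
millimeters or physiological propagation speeds is attempted.

## Known limitations

* Attenuation lengths at small `eta` approach the analysed window size
  (`lambda ~ 20` at `eta = 0.05` on `N = 64`), so their absolute values
  carry finite-size bias even though the ordering in `eta` is robust.
* The Euler background at `dt = 0.01/g` carries a few-percent variance
  inflation relative to finer steps; quantities that depend on absolute
  variances (not orderings) should be run at smaller `dt`.
* Open boundaries are supported for robustness checks, but all spectral
  machinery (dispersion, exact propagator) requires periodicity.
* Internal (per-unit) noise, long-range connectivity, spiking dynamics,
  and self-tuning of the balanced state are out of scope.
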