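# Methods

## Problem setting

Photoacoustic tomography (PAT) reconstructs a map of absorbed optical energy
`X` from acoustic pressure recorded by ultrasound detectors around the
object. In the sparse-view regime — few detector positions `p` on the scan
circle — the discretised problem `Y = K X` is underdetermined, and the
package solves it by compressed sensing: `X = Ψ θ` with `Ψ` an orthonormal
wavelet basis and `θ` sparse, giving `Y = A θ` with `A = K Ψ`.

## Forward model

Detectors sit uniformly on a circle of radius `R` (default 40 mm) enclosing
a square pixel grid (default 30 × 30 mm). At each position the pressure
spectrum is sampled at `q` temporal frequencies drawn uniformly at random
from a band (default [0.2, 3] MHz), independently per position. The entry of
`K` coupling detector `r_m` at wavenumber `k_n = 2πf_n/c` to pixel `r_ij` is

    i · c · k_n · exp(−i k_n |r_m − r_ij|) / |r_m − r_ij|,

a monopole (spherical-wave) Green's-function model with homogeneous sound
speed `c` (default 1500 m/s). All global physical constants are folded into
one normalization factor, `c·k_mid/R` with `k_mid` the band-centre
wavenumber, chosen so a typical matrix entry is O(1). A global scale cancels
between simulation and inversion; normalising keeps the solvers' adaptive
regularization weight on a meaningful scale.

Because `X` is real and `K` complex, inversion uses the real-lifted system
`[Re K; Im K]` of shape 2M × N (M = p·q), doubling the usable measurement
count consistently for simulation and inversion.

Measurement noise is circular white Gaussian, renormalised after drawing so
the requested SNR `10·log10(‖Y‖²/‖e‖²)` holds exactly; this removes draw-to-
draw SNR jitter from the noise sweeps.

### Information content of the scan

A point often hidden by matrix dimensions: the pressure spectrum at one
detector is the Fourier transform of a signal time-limited to the image's
range spread `Δd/c` (≈ 28 µs for a 30 mm grid), so a band `B` supplies only
about `B·Δd/c` independent complex samples per position — ≈ 79 for the
default band, regardless of how many frequencies `q` are drawn. Sampling
`q > 79` frequencies per position adds redundant rows: at 128 px with
q = 128 and 50 positions, the 12 800-row lifted system has numerical rank
≈ 6 700. Since the 128-px head phantom has ≈ 7 700 exactly nonzero wavelet
coefficients, *exact* recovery from 50 views is impossible under this
physics no matter the solver; the achievable regime is high-quality partial
recovery. This bound shapes the defaults of the experiment module and the
scale of the shipped studies (below).

## Sparsity basis

Default `Ψ` is Daubechies-4 with periodization boundary at the maximum
decomposition depth compatible with the image side, which keeps the 2-D DWT
exactly unitary: analysis is simultaneously the inverse and the adjoint of
synthesis (Parseval holds to machine precision), and the Gram matrix of
`A = KΨ` equals that of `K` alone — the solvers exploit this to factor one
2M × 2M matrix per scan geometry. An identity basis is available for solver
tests on synthetic sparse vectors. Family, depth and boundary are
configurable; non-orthogonal families are rejected.

## Solvers

Both solvers maximise the Gaussian surrogate
`F_σ(θ) = Σ exp(−θ_i²/σ²)` (so `N − F_σ → ‖θ‖₀` as `σ → 0`) over a
geometrically decreasing σ-schedule (graduated non-convexity):
`σ_0 = 4·max|θ_0|` with `θ_0` the minimum-norm solution, `σ_{j+1} = ρ σ_j`.
Each σ gets `L` inner iterations of a gradient-ascent step
`θ ← θ + μσ²∇F_σ(θ)` followed by a pull toward the data:

* **SL0** projects exactly onto `{θ : Aθ = y}`:
  `θ ← θ − Aᵀ(AAᵀ)⁻¹(Aθ − y)`.
* **ReSL0** relaxes the data constraint to the inequality
  `‖Aθ − y‖ ≤ δ` (`δ` = `error_tolerance`, typically the measurement-noise
  norm) and pulls back with the damped correction
  `θ ← θ − Aᵀ(AAᵀ + λ⁻¹I)⁻¹(Aθ − y)` — the Lagrange form of the nearest
  point inside the residual ball. The multiplier `λ` is resolved exactly by
  a monotone root-find in the cached eigenbasis so the post-projection
  residual equals `δ` (discrepancy principle), evaluated once per outer
  iteration at the first inner gradient step and then held fixed for the
  inner loop; it is clipped to `[λ_floor, λ_cap]` and recorded. An iterate
  already inside the ball is left untouched, so noise below the tolerance is
  never fitted. With `δ = 0` the projection reduces to the exact one and
  ReSL0 follows SL0; the initial point is the `δ`-ball Tikhonov solution
  (the minimum-norm start when `δ = 0`).

Why the exact multiplier rather than a heuristic ratio: the classical
sparsity-step-to-misfit-gradient ratio for λ (available as the standalone
`adaptive_lambda` function) is degenerate at both ends on this problem
class. Started from a feasible point its denominator vanishes, λ pegs at
the cap and the solver collapses onto SL0 — inheriting SL0's noise
amplification through the smallest Gram eigenvalues (measured −40 dB PSNR
at 20 dB SNR). Started from an infeasible point the ratio shrinks as the
iterate shrinks, the data pull dies, and the iterate collapses to zero.
Resolving λ from the residual constraint it is meant to enforce removes
both failure modes and keeps the noiseless limit exact.

### Parameters

| name | default | meaning |
|---|---|---|
| `rho` | 0.8 | σ decay per outer iteration, must be in (0.5, 1); finer = slower, deeper |
| `mu` | 1.0 | inner step size; the update `θ(1 − 2μe^{−θ²/σ²})` at μ=1 equals the classical smoothed-L0 reference step |
| `inner_iters` | 3 | gradient+projection steps per σ |
| `sigma_min_ratio` | 1e-4 | schedule floor relative to σ₀ (caps resolvable coefficient scale) |
| `stop_tol` | 0.005 | relative image-change stopping threshold |
| `max_outer` | 200 | hard cap; exceeding it flags `converged_ = False` |
| `error_tolerance` | 0 | residual tolerance δ of the data constraint (ReSL0); set to the noise norm for noisy data |
| `lambda_floor/cap` | 1e-12 / 1e12 | clipping of the resolved multiplier λ (ReSL0) |

### Stopping rule

The solvers stop when the relative image change drops below `stop_tol`
(default 0.005) — but the change is measured across **one tenfold σ
reduction** (a window of `⌈ln10/−lnρ⌉` outer iterations), not between
adjacent iterates. Adjacent-iterate changes scale with `(1−ρ)` and vanish on
the transient plateaus between coefficient-collapse events, so an
adjacent-iterate test stops far from convergence and its firing point
depends on the schedule granularity; the windowed form is invariant to ρ and
still halts stalled runs on noisy data. The test is also gated on
`σ < max|θ|`: above that, the gradient step is a near-uniform scaling that
the projection exactly undoes, leaving the iterate stationary for the wrong
reason. A σ floor (`sigma_min_ratio`) terminates the schedule regardless.

### Numerics

All projections share one symmetric eigendecomposition of `G = AAᵀ` per
scan geometry (cached on the sensing operator), so ReSL0's per-iteration λ
costs O(M²) instead of a fresh O(M³) factorization. Tomographic Gram
matrices are legitimately near-singular (relative eigenvalues to 1e-15) and,
when `q` exceeds the per-position information limit, genuinely rank
deficient; the solver then switches to pseudo-inverse truncation at a
relative eigenvalue of 1e-14 — directions below that level carry only
eigensolver noise and are truncated in shifted solves as well (leaving them
in amplifies rounding noise by up to 10¹² and destroys the iterate). The
exact equality projection raises a rank error when `G` is structurally
singular (more measurements than unknowns) or numerically zero-ranked;
near-machine-level deficiency (e.g. one duplicated row among well-scaled
ones) sits inside eigensolver noise and cannot be detected reliably.

`y = 0` returns the zero solution immediately (σ₀ = 0 makes the schedule
undefined). Non-finite measurements are rejected.

## Quality metrics

`psnr = 10·log10(N·MAX²/‖X−X̂‖²)` with `MAX` the ground-truth maximum
(equals the conventional MAX²/MSE form), +inf for identical images. `nmae`
is the percent-scale relative 2-norm error `100·‖X̂−X‖₂/‖X‖₂`; despite the
"mean absolute error" name it is a Euclidean ratio, implemented exactly as
defined for comparability with the reference studies. The two are monotone
transforms of each other at fixed N, MAX and `‖X‖` (asserted in tests).

## Phantoms

* **Shepp-Logan**: classical (non-modified) 10-ellipse parameter set,
  point-sampled at pixel centres (a pixel takes the summed intensity of
  covering ellipses; no anti-aliasing), then min-max rescaled to [0, 1].
* **Vessel phantom**: seeded random smooth walks painted at width 1–3 px,
  intensity in [0.6, 1]; bit-reproducible per seed; nonzero support stays
  well under 25 % of pixels (the sparsity premise).
* **Resolution target**: four groups of four parallel bars at decreasing
  pitch plus two disks of different radius/contrast; deterministic.

The vessel and resolution phantoms are procedural stand-ins with the
qualitative structure of their laboratory counterparts, not replicas of any
specific bitmap, so studies on them are reproducible only in trend.

## Experiment harness and shipped study sizes

`run_view_sweep` / `run_noise_sweep` build, for each cell, the geometry and
a seeded frequency draw, simulate data, reconstruct with every registered
solver under the common stopping rule, and score with PSNR/NMAE; rows carry
all seeds, so a sweep is bit-reproducible (CPU time aside). Noise sweeps
reuse one frequency draw per position count across SNR levels and
repetitions, so noise curves share a fixed geometry. Per-cell and
per-repetition sub-seeds are derived through `numpy` seed sequences from two
named base seeds (frequency, noise). Dense `K` is used while it fits a
configurable memory budget (default 8 GiB); beyond that the operator
recomputes blocks on demand with identical semantics, and a cell whose Gram
factorization alone exceeds the budget is refused with a size estimate.

The headline shipped study (and `scripts/acceptance.py`) runs the noiseless
view-count experiment at **80 × 80 px with q = 50**, scaling both the pixel
count and the per-position frequency count by the same factor from the
128 px / q = 128 reference configuration so that the measurement ratio
`2pq/N = p/64` of every row is preserved. This size was chosen because
(a) q = 50 stays below the ≈ 79 independent samples available per position,
so no drawn measurement is wasted (the reference configuration is ≈ 60 %
redundant), and (b) a full study — two cells × two solvers × five frequency
seeds — completes in minutes on one CPU. At this scale the noiseless
solvers reach ≈ 63 dB PSNR at 50 views and ≈ 59 dB at 45 views (medians
over five draws). Exact recovery (>100 dB) is not reachable at any scale
under this forward model: the per-position information bound caps the
effective measurement count below the phantom's exact wavelet support (see
above). Passing tests therefore demonstrate the high-quality partial
recovery regime and the solver orderings, not bit-exact inversion; real
detector data additionally differ by transducer response, heterogeneous
sound speed and modelling error that the synthetic studies do not emulate.

## Known limitations

* 2-D geometry, homogeneous sound speed, ideal point detectors; no
  transducer impulse response.
* L1 (basis-pursuit) and total-variation reconstructions are not
  implemented; `register_solver` is the adapter hook for external solvers.
* The vessel/resolution phantoms are qualitative stand-ins (above).
* At image sides below ~80 px the head phantom's wavelet representation is
  too dense for sparse-view recovery to enter its high-quality regime;
  benchmark at 80 px or above.
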