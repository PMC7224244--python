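# Methods

## The continuation engine

The engine follows solution curves of `F(v, λ) = 0` (state `v ∈ Rⁿ`, scalar
parameter `λ`) parametrised by pseudo-arclength. At a converged point the
unit tangent `(v̇, λ̇)` is the null vector of the n×(n+1) extended Jacobian
`[F_v | F_λ]`; the next point solves `F = 0` together with

```
θ² (v − v₀)ᵀ v̇₀ + (λ − λ₀) λ̇₀ − Δs = 0,
```

whose augmented Jacobian stays nonsingular through saddle-node folds. The
predictor is linear extrapolation of length `Δs`; the corrector is Newton's
method, terminated once the augmented residual 2-norm drops below
`newton_tol` (default 1e−10) and capped at `max_newton = 10` iterations. A
secant tangent (difference of the last two points over `Δs`) is available
as a cheap alternative to the exact null-space solve. The weight `θ`
defaults to 1 (plain arclength): the worked problems here have state and
parameter of comparable scale. Stepsize is fixed by default; optional
adaptation halves `Δs` on corrector failure and doubles it after repeated
fast convergence.

Folds are flagged by sign changes of the tangent's parameter component
between accepted points and refined by bisection in arclength from the
bracketing anchor (tolerance `fold_refine_tol`, default 1e−8; the 2D
problem uses 1e−3 to bound the number of Krylov solves). Stability is
judged on the eigenvalues of `F_v`: stable iff the maximal real part is
below −1e−8 after excluding caller-supplied structural modes (translational
zeros, matched by |cosine similarity| > 0.98 of eigenvectors); real parts
within ±1e−8 are reported as marginal.

Two linear-algebra safeguards matter in practice and are part of the
engine's contract rather than incidental detail:

- **Dense solves are verified.** LAPACK's partially-pivoted LU can suffer
  catastrophic element growth on the advection-dominated Jacobians of
  co-moving-frame problems (first-derivative off-diagonals ~1/Δξ dominate
  the diagonal); at N = 2000 the computed solution of a well-conditioned
  system (condition ≈ 240) was wrong by three orders of magnitude. Every
  dense solve is therefore checked against the backward-error bound
  `|Ax − b| ≤ 1e−9 (|A|_F |x| + |b|)` and redone by a rank-revealing QR
  least-squares solve when it fails.
- **Matrix-free solves tolerate the probe noise floor.** The
  finite-difference product `Jφ ≈ [G(V + εφ) − G(V)]/ε` carries a relative
  error of order `ε`, so GMRES's internal recurrence can report stagnation
  even when the true residual meets tolerance; solves are accepted whenever
  the directly evaluated relative residual is within 100× `krylov_tol`.
  Restarted GMRES needs a Krylov space of roughly 250 vectors on the 2D
  augmented Jacobian, so the restart length defaults to 300 (about 20 MB at
  N = 64) — shorter restarts stagnate indefinitely.

## Model library

The firing rate is `f(u) = 1/(1 + e^{−βu})` with exact derivative
`β f (1 − f)`; the exponent is clamped to ±700 and the output to the open
interval (0, 1) so the range and monotonicity invariants survive extreme
`βu` in float64. Kernels are pure pointwise functions (truncation is owned
by consumers): the 1D Mexican hat `10 e^{−4x²} − 6 e^{−x²}` (and its
one-parameter family with inhibition amplitude `B`), the unit-mass
exponential `½ e^{−|x|}`, and the 2D Mexican hat
`e^{−r²} − 0.17 e^{−0.2 r²}`. The scalar toy problem
`g(u; μ) = u⁴ − u + μ² − 1` exercises the engine on a closed curve with two
symmetric folds at `μ* = ±√(1 + u* − u*⁴)`, `u* = 4^{−1/3}`.

## Stationary 1D bumps

On the circle `[−π, π]`, even solutions are expanded in `N` cosine modes;
projecting the fixed-point equation gives
`−u_j + w_j ∫ cos(jy) f(Σ u_i cos(iy) − h) dy = 0` with the kernel's cosine
coefficients `w_j`. Integrals use the trapezoid rule on `M` equispaced
nodes (default `M = 128`, configurable; computing kernel coefficients
demands `M ≥ 4N` against aliasing). Evenness removes the translational zero
mode structurally, so no mode exclusion is needed for stability. If the
kernel's cosine series terminates at mode `NF`, truncation at `N = NF + 1`
is exact — verified as a property test.

At `β = 20` the sigmoid's transition width (~0.05 in `y` at the bump edge)
is marginal for `M = 128`: the discrete solution is internally consistent
but sits ~1e−3 from the continuum one; `M = 512` brings the off-grid
residual of the integral equation below 1e−6. Branch computations are
internal comparisons for which `M` cancels, so the cheap default stands.

Initial bumps come from projecting a Gaussian onto the modes, integrating
the truncated mode ODEs (classical RK4, dt = 0.01) until the derivative
norm falls below 1e−8, then Newton-polishing. The blob settles to a clean
single bump for starting thresholds `h ≳ 0.3`; below that the background
destabilises into multi-bump states, so 0.3 is the default starting point.

## Travelling 1D fronts

In the frame `ξ = x − ct` the front solves
`0 = c du/dξ − u + (w ∗ f(u − h))` on `[0, 50]` with 1000 points, plus the
pinning condition `∫ (u − û) û_ξ dξ = 0` against the template
`û(ξ) = ½(1 + tanh(25 − ξ))`; the state is `(u, c)` and the continuation
parameter `h`.

**Boundary closure.** The domain truncation is closed by constant
extension: the field is taken to continue at its end values outside
`[0, L]`, adding the analytic kernel tail masses (`½ e^{−ξ}` and
`½ e^{−(L−ξ)}`) to the convolution, and the end rows of the second-order
central difference use ghost values `u_{−1} = u_0`, `u_N = u_{N−1}`. Plain
truncation is not viable here: losing half the kernel mass at each end
creates O(1) boundary layers that spawn a spurious fold of the front branch
at `h ≈ 0.5001`, and one-sided end differences nearly annihilate the
growing mode `e^{ξ/c}` (excluded by boundedness on the line), leaving the
Jacobian close to singular. Each discrete convolution row (including tails)
is additionally normalised to unit mass — the continuum kernel integrates
to 1 exactly, while the trapezoid rule has an O(Δξ²) error at the `|x|`
kink — which makes the uniform states exact discrete solutions and restores
the `u → 1 − u`, `h → 1 − h` symmetry at machine precision, so the computed
speed vanishes identically at `h = ½` and the speed curve is antisymmetric
to rounding.

The front linearisation keeps a numerically-zero eigenvalue whose
eigenvector is the discretised `du/dξ`; stability is judged on the
remaining spectrum. Initial fronts are formed by semi-implicit time
stepping (decay implicit, convolution explicit, dt = 0.05) from a step
initial condition, with the speed estimated from the interface displacement
over the final quarter of the horizon; the profile is re-centred on the
template (anticipating the drift during a short resettling pass) and
polished by a damped (backtracking) Newton iteration.

Convergence of the computed speed is cleanly second order in the grid
spacing (2.1e−4 per halving at Δξ = 0.05, ratio 4 at the next halving); the
Richardson limit agrees with the independent shooting oracle to ~1e−6.

## Heteroclinic shooting

Because `½ e^{−|x|}` is the Green function of `1 − d²/dx²`, the front
equation collapses exactly to `c u‴ − u″ − c u′ + u = f(u − h)`, a
three-dimensional first-order system singular at `c = 0`. The outer fixed
points carry (for `c > 0`) a 2D unstable and 1D stable manifold — the
linearisation eigenvalues solve `λ³ − λ²/c − λ + (1 − f′)/c = 0`, which for
flat firing rate factorises as `(λ−1)(λ+1)(λ−1/c)` — so a front is a
codimension-one connection in `c`. The speed is found by launching a
trajectory a displacement of 1e−6 along the one-dimensional transverse
eigenvector of the appropriate fixed point (backwards in `ξ` from the low
state for `c > 0`; forwards from the high state for `c < 0`), integrating
(RK45, rtol = atol = 1e−10) until it exits a tube of radius 0.05 around the
heteroclinic corridor, and bisecting the signed `u`-mismatch from the far
fixed point to 1e−8 in `c`. The region `|c| ≤ 0.02` (thresholds near ½) is
excluded — the reduction divides by `c` — and is covered by the grid
continuation instead. The mismatch functional is a design choice; it is
validated by the cross-method agreement with the grid continuation
(< 1e−3 at h ∈ {0.3, 0.4, 0.6, 0.7}).

## 2D travelling bumps

The activity/adaptation pair on the periodic square `[0, 15)²`
(`A = 2, β = 5, h = 0.8, B = 0.4, τ = 3`) is posed in the frame
`ξ = x + ct` of a leftward-moving bump. The co-moving adaptation equation
carries the transport term `c τ ∂a/∂ξ`, as forced by applying the change of
variables to the adaptation dynamics (a `strict_paper` flag substitutes
`∂u/∂ξ` there for comparison with the printed form, which we read as a
typographical slip). Translation invariance in `y` is removed by projecting
onto fields symmetric about `y = L/2` after every Newton update (the
projection is exact on the symmetric subspace, and the Krylov iterations
remain in it because the linearisation commutes with the reflection);
invariance in `ξ` by the phase condition
`u(L/2, L/2) = (1/L) ∫ u(ξ, L/2) dξ`. Convolution is spectral (FFT,
minimum-image kernel sampling — exact circular quadrature); `∂/∂ξ` is
second-order central with periodic wrap.

The `2N² + 1` system is solved matrix-free: GMRES(300) on
`Jφ ≈ [G(V + εφ) − G(V)]/ε` with `ε = 1e−7 (1 + |V|)/|φ|`; the few
rightmost eigenvalues of the 2N² state-block dynamics come from implicitly
restarted Arnoldi iteration on the same products. Both translations
survive as near-neutral modes of that block — zero only up to the O(Δx²)
differencing error (~1e−2 at N = 64) — and are excluded from stability
verdicts by eigenvector correlation with `(∂_ξ u, ∂_ξ a)` and
`(∂_y u, ∂_y a)`.

Initial bumps: semi-implicit time stepping from a Gaussian blob with the
adaptation field seeded ~one kernel width ahead in `+x` (an x-symmetric
start is a stationary state of the symmetric dynamics and never begins to
travel), drift measured by a circular centroid of the mid-row activity
(robust to the flat-topped profiles that make a discrete argmax flip
between twin maxima), then Newton–Krylov polish.

Problem sizes: tests and demos run at `N = 64` per dimension (the
full-resolution `N = 256` is supported); the bump speed changes by 3.3e−3
between N = 64 and N = 128. At `N = 16` on this domain (Δx ≈ 1, the kernel
scale) no travelling bump is resolved — the state degenerates to a nearly
ξ-uniform profile with ill-determined speed — so `N = 32` is the smallest
meaningful grid and is used for the dense-versus-Krylov equivalence check.
The branch in the gain `A` has a stable segment bounded by saddle-nodes at
`A ≈ 1.61` and `A ≈ 2.11` at N = 64.

**Fold test function.** At a saddle-node of a *travelling* wave the
dynamics-block fold mode forms a Jordan pair with the ξ-translation zero,
so a "rightmost eigenvalue excluding translational modes" criterion is
ill-posed exactly at the fold (the exclusion filter eats the critical
mode). The fold/eigenvalue consistency check therefore uses the standard
test function instead: the eigenvalue nearest zero of the *wave-system*
Jacobian (the `2N² + 1` block including the speed column and phase row,
which is singular precisely at the fold), computed matrix-free by
GMRES-based inverse power iteration restricted to the symmetric subspace
(the permanent y-translation null vector is antisymmetric and projected
away). This eigenvalue changes sign across both folds, with the bracketing
points within 1e−6 of the fold in `A`.

## Two-parameter fold curves

At a fold of the bump branch the Galerkin Jacobian `J = F_v` is singular;
appending `Jφ = 0` and `φᵀφ = 1` gives `2N + 1` equations for
`W = (v, φ, h)`, continued in the kernel's inhibition amplitude `B`
(kernel `10 e^{−4x²} − B e^{−x²}`, coefficients recomputed per `B`). `Jφ`
is formed matrix-free by a *centred* directional difference (`ε = 1e−6`;
the centred form keeps the O(ε²) truncation under the 1e−9 corrector
tolerance, where a one-sided quotient would floor at ~1e−7); the assembled
product serves as the cross-check oracle. `φ` is seeded from the
eigenvector of the assembled Jacobian at the one-parameter fold, normalised
with its largest-magnitude entry positive; extended Newton then converges
in ≤ 5 iterations, and the recovered threshold matches the one-parameter
fold to < 1e−4. Along the curve the fold threshold rises monotonically as
`B` decreases.

## Periodic orbits via the Poincaré map

The FitzHugh–Nagumo example integrates
`dv/dt = (v(v + 0.1)(1 − v) − w + i_app)/0.1`, `dw/dt = v − w/2` (the
cubic's coefficients, the drive `i_app = 1` and the voltage timescale are
configurable; this default reading is validated at build time by direct
simulation producing a stable limit cycle through the section). The return
map `ψ` on `Σ = {(v, w): v > 0.5, w = 1}` (upward crossings) is defined by
adaptive integration (rtol = atol = 1e−10) with terminal event location;
crossings failing the half-space gate restart the integration nudged off
the section, and the time cap is 100 units. Tangential hits and
never-returning trajectories raise typed errors; inside a continuation a
lost orbit truncates the branch with a diagnostic. The orbit is a fixed
point `V* = ψ(V*)` (`V* ≈ 0.9815` at the defaults), stable iff
`|ψ′(V*)| < 1` (`ψ′ ≈ 0.025`); the scalar residual `V − ψ(V)` is continued
in `i_app` by the same engine with a finite-difference Jacobian, which also
handles unstable orbits.

## What the generated data does and does not show

All inputs are synthesised by time-stepping the models themselves, so every
test exercises the full pipeline (initialisation → correction →
continuation → stability) under exactly the stated model equations. What
passing tests do **not** show: behaviour under heterogeneous or noisy
kernels, non-even 1D bumps (the cosine basis is structurally even),
patterns outside the reflection-symmetric subspace in 2D, and resolutions
beyond those stated above. Figure-level fold positions are asserted only
against internal refinements and cross-method oracles, not external
values — the branch topology, symmetries, and cross-method agreements are
the scientific surface.

## Known limitations

- No branch switching at bifurcation points, and no Hopf-curve
  continuation (complex leading eigenvalues are reported, not followed).
- The shooting module cannot cross `c = 0`; the grid continuation covers
  the symmetric-threshold region.
- The 2D solver has no preconditioner; GMRES cost grows near folds.
- Fold bisection assumes a simple quadratic fold between the bracketing
  points; closely spaced fold pairs inside one step would be merged.
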