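# neurocont

Pseudo-arclength continuation for high-dimensional neural field models.

Neural field equations — nonlocal integro-differential models of cortical
activity of Wilson–Cowan/Amari type,

```
∂u/∂t = −u(x,t) + ∫ w(x − y) f(u(y,t) − h) dy,
```

with a sigmoidal firing rate `f(u) = 1/(1 + e^{−βu})` and an even synaptic
kernel `w` — support localized "bumps", travelling fronts, and moving
two-dimensional bumps. Understanding where these patterns exist, whether
they are stable, and how they are created and destroyed as parameters vary
is a bifurcation problem that usually cannot be solved in closed form.

`neurocont` implements the standard numerical machinery for this, for
researchers in computational neuroscience and nonlinear dynamics:

- a generic **pseudo-arclength predictor–corrector engine**: unit-tangent
  prediction, Newton correction of the augmented system
  `F(v, λ) = 0`, `(v − v₀)ᵀv̇₀ + (λ − λ₀)λ̇₀ − Δs = 0`,
  fold (saddle-node) detection with bisection refinement, and stability from
  the eigenvalues of the state-block Jacobian `F_v`;
- **stationary 1D bumps** on the circle via a cosine-Galerkin truncation
  (evenness removes the translational zero mode), continued in the firing
  threshold `h`;
- **travelling 1D fronts** in the co-moving frame `ξ = x − ct`, with the
  unknown speed closed by a template pinning condition
  `∫ (u − û) û_ξ dξ = 0`, continued in `h`;
- an independent **heteroclinic-shooting oracle** for front speeds, using
  the exact reduction of the nonlocal equation to the third-order ODE
  `c u‴ − u″ − c u′ + u = f(u − h)` (the exponential kernel is the Green
  function of `1 − d²/dx²`);
- **2D travelling bumps with adaptation**, solved **matrix-free**: Newton
  steps use restarted GMRES driven by finite-difference Jacobian–vector
  products `Jφ ≈ [G(V + εφ) − G(V)]/ε`, and stability uses implicitly
  restarted Arnoldi iteration on the same products;
- **two-parameter fold curves** via the extended (bordered) system
  `F = 0`, `Jφ = 0`, `φᵀφ = 1`;
- **periodic orbits as Poincaré-map fixed points** (FitzHugh–Nagumo
  example), continued in a model parameter with the same engine.

All starting solutions are generated by time-stepping the models — the
package needs no external data.

## Worked example

Follow the travelling front of the 1D field with exponential coupling
(`β = 20`, domain `[0, 50]`, 1000 grid points) and locate where its speed
reverses:

```python
from neurocont import front1d
from neurocont.continuation import ContinuationSettings

problem = front1d.FrontProblem()            # h = 0.3 to start
front = front1d.initial_front(problem)      # time-step, then Newton-polish
print(f"c(h=0.3) = {front.speed:.6f}")

settings = ContinuationSettings(ds=0.3, max_steps=45, newton_tol=1e-9,
                                adapt_step=True, ds_max=0.6)
branch = front1d.continue_front_in_h(problem, front, settings)
print(f"fold at h = {branch.folds[0].parameter:.6f}")
print(f"speed reversal at h = "
      f"{front1d.speed_zero_crossing(problem, branch):.6f}")
```

prints

```
c(h=0.3) = 0.803998
fold at h = 0.802463
speed reversal at h = 0.500000
```

The front moves at speed `c ≈ 0.804` at threshold `h = 0.3` (the active
state invades), stops exactly at the symmetry point `h = 1/2` (the model is
invariant under `u → 1 − u`, `h → 1 − h` there), and the stable front is
destroyed in a saddle-node at `h ≈ 0.8025` — the same threshold at which
the spatially uniform states lose bistability (`h ≈ 0.80285`). The
independent shooting oracle gives `c(0.3) = 0.804281`, matching the grid
continuation to its discretisation error.

## Demos

Each worked problem has a driver, runnable from the shell:

```
neurocont run toy            # closed curve of the scalar toy model, 2 folds
neurocont run bumps1d        # 1D bump branch in h, fold at h ≈ 1.009
neurocont run front1d        # front speed vs h
neurocont run shoot          # shooting speeds at several h
neurocont run bump2d         # 2D travelling bump branch in the gain A
neurocont run foldcurve      # fold curve in the (h, B) plane
neurocont run fhn            # FHN periodic orbit via the Poincare map
neurocont plot <branch.tsv>  # export a plot-ready CSV
```

Branch tables are written as delimited text with a `#` metadata header
carrying everything needed to re-run the demo.

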