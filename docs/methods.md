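# Methods

## Model

`kinetaxis` simulates a velocity-jump (run-and-tumble) description of cell
migration under two simultaneous directional cues. The mesoscopic state is
the distribution `p(t, x, v, vhat)` of positions `x` in a rectangular domain,
speeds `v` in `[0, V]` and polarization directions `vhat` on the unit circle.
It evolves by the transport equation

```
dp/dt + v vhat . grad p = mu ( rho T psi - p )
```

where `rho` is the spatial density, `mu` the turning frequency, `psi(v)` the
speed density and `T(x, vhat)` the transition probability of the post-tumble
direction. `T` encodes the two guidance cues:

* **contact guidance** — a non-polarized fiber network described by the
  bimodal von Mises direction density
  `q(x, vhat) = cosh(k(x) u(x).vhat) / (2 pi I0(k(x)))` with concentration
  `k(x) >= 0` and fiber axis `u = (cos theta_q, sin theta_q)`. The density
  is antipodally symmetric, so its mean direction vanishes and its influence
  is purely orientational (anisotropic diffusion along the axis);
* **chemotaxis** — a strictly positive chemoattractant `S(x)` whose
  asymmetry between opposite sensing directions provides the only source of
  a preferred *sense* of motion.

Cells sense both cues non-locally along protrusions of maximal length `R`
(the sensing radius), weighting the sampled values with kernels
`gamma(lambda)` supported in `[0, R]`: a Dirac delta at `R` (membrane-tip
sensing), a Heaviside profile (uniform averaging along the protrusion), a
Dirac at 0 (local sensing) or an arbitrary tabulated profile. Two sensing
strategies are implemented: *independent* (each cue averaged with its own
kernel, `T` proportional to the product of the two averages) and *dependent*
(one simultaneous average of `S q` with a single kernel). With Dirac-at-R
kernels for everything the two transition probabilities coincide exactly;
this identity, and the full pattern of coincidences of the macroscopic
limits, are enforced by tests.

## Regime analysis and macroscopic limits

The characteristic variation lengths `l_S = 1 / sup |grad S| / S` and
`l_q = 1 / sup_x sup_vhat |grad q . vhat| / q` are compared with `R` through
`eta_S = R / l_S` and `eta_q = R / l_q`. The four quadrants of
(`eta_S`, `eta_q`) relative to 1 select the macroscopic limit:

* both large (case i): pure advection by the full non-local mean post-tumble
  velocity;
* both small (case ii): a drift-diffusion equation with diffusion tensor
  `D Dq` (`D` the speed energy, `Dq` the fiber variance-covariance tensor)
  and drift `Ubar [ Gq div(Dq) + GS Dq grad(S)/S ]`, of Keller-Segel type
  with logarithmic chemotactic sensitivity (`Gq`, `GS` are the kernel moment
  ratios `Gamma_1/Gamma_0`; for the dependent model they are equal);
* mixed (cases iii and iv): advection with a two-term drift combining the
  non-locally averaged fiber statistics with the chemoattractant (gradient
  or ray average), each term carrying its own normalization constant.

The suprema in `l_S`, `l_q` are evaluated by grid scans, using analytic
gradients when the field is parametric. Ties `eta = 1` are deterministically
assigned to the fast branch. The ratio `eta = l_S / l_q` is independent of
`R` and separates fiber-dominated (`eta > 1`) from chemotaxis-dominated
dynamics.

Two genuinely open points were resolved as follows:

* **Degenerate normalizations (cases iii/iv).** The per-node constants `c0`,
  `c1` appear as denominators and are asserted non-zero by the theory. When
  a denominator and its numerator vanish together (e.g. homogeneous cues)
  the corresponding expansion term is absent and contributes zero; a
  vanishing denominator under a non-vanishing numerator raises a
  `DegenerateNormalizationError` naming the grid node, never a silent
  regularization.
* **Symmetric averaged fibers (case iii).** When the ray-averaged fiber
  density is itself antipodally symmetric (homogeneous fibers, or local
  fiber sensing), the hyperbolic expansion degenerates identically and the
  correct limit is parabolic: `caseiii_drift` then returns drift
  `Ubar G_S D_qtilde grad(S)/S` together with the diffusion tensor
  `D D_qtilde` (the anisotropic-diffusion-with-chemotactic-correction
  model).

## Numerics

**Direction space** is discretized with `N_theta` uniform angles; an even
count puts antipodal pairs on-grid (exact symmetry of `q`), and a count
divisible by 4 keeps specular wall reflections on-grid. The rectangle rule
on the circle is spectrally accurate; for very concentrated densities the
aliasing error is governed by `I_N(k)/I_0(k) ~ exp(-N^2/2k)`, so `k = 700`
needs roughly 128 nodes or more for quadrature statements at `1e-8`.

**Bessel evaluations** use exponentially scaled functions (`ive`) and
log-domain forms throughout, so `k = 700` neither overflows nor loses the
normalization.

**Ray quadrature**: midpoint rule with `N_lambda = 16` nodes on the
(boundary-truncated) kernel support; Dirac kernels are direct point lookups,
annihilated when the sensing point falls outside the domain. Off-grid cue
values are obtained by bilinearly interpolating the *parameters* (`S`
analytically where parametric; `k` and the fiber axis through the
angle-doubled axial vector) and re-evaluating the density, which preserves
its unit mass exactly. No per-ray renormalization is applied after boundary
truncation; the node-wise normalization `c(x)` alone restores unit
probability mass, so directions whose rays are annihilated get zero weight
and their mass is redistributed.

**Kinetic solver**: Strang splitting of transport and turning. Transport is
a dimensionally split conservative finite-volume upwind sweep per
(direction, speed) node under a CFL bound (default number 0.45); an optional
limited second-order (minmod/MUSCL) correction is available for convergence
studies — the first-order default is the robust positivity-preserving
choice. Specular reflection is implemented through the flux pairing
`theta -> pi - theta` (x-walls) and `theta -> -theta` (y-walls): the wall
influx of a direction equals the wall outflux of its mirror, conserving mass
to round-off. The turning substep is the exact solution of the relaxation
ODE, `p <- E + exp(-mu dt)(p - E)` with `E = rho T psi` and `rho` frozen,
unconditionally positive and mass-neutral.

**Speeds**: the model-level default is a uniform speed density on `[0, V]`
with `V = 1`; the solver discretizes it with `N_v` midpoint nodes (default
4; a single-speed mode `N_v = 1` places all mass at `V/2` for fast runs).
A "vanishing initial speed" start places the mass on the lowest positive
speed node — a literal `v = 0` node would never leave its cell and distort
relaxation. Cross-scale comparisons evaluate the macroscopic coefficients at
the *discrete* speed moments of the solver so that the two scales share the
same `Ubar` and `D`.

**Limit solvers**: upwind finite-volume advection with wall-normal drift
zeroed at the boundary (the no-flux condition of the hyperbolic limit), and,
for case ii, conservative fluxes whose diffusive part discretizes the double
divergence `div((1/mu) div(D Dq rho))` with the tensor inside both
derivatives. This is *not* the Fickian form `div(D Dq grad rho)`: the two
differ wherever `Dq` varies in space, and a regression test drives the
operator with constant `rho` (Fickian would vanish; the double divergence
must match the analytic double divergence of `D Dq`).

**Default parameters**: `V = 1`, `mu = 1`, CFL 0.45, `N_theta = 32`,
`N_v = 4`, 128 x 128 spatial grid for full reproductions, with a reduced
64 x 64 / 16-direction / single-speed preset for quick runs. The canonical
experiments state no grids, time steps, `V` or `mu`; these defaults make the
advective and turning time scales comparable (both O(1)), which is the
regime the scaling analysis assumes.

## The canonical experiments

The builders in `kinetaxis.experiments` encode the four canonical study scenarios
(stripe with local fiber sensing; four sensing-strategy variants; five
regime rows on a Gaussian alignment bump; electrospun-fiber scaffold under a
linear gradient). Two parameter choices deserve note:

* the stripe scenario's chemoattractant variance defaults to 0.05 (the
  figure-caption value; the body text's 0.1 is available as an override);
* the linear chemoattractant `S = m_S y` vanishes at `y = 0` while the model
  requires `S > 0` (normalizations divide by `S`); a configurable floor,
  default `0.01 m_S`, regularizes it. The scaffold scenario uses independent
  Heaviside sensing for both cues (the scenario description fixes `R = 0.7`
  and the fields but not the kernels; Heaviside matches the neighbouring
  regime-comparison experiments).

**Angular resolution of the stripe runs.** With stripe concentration
`k = 700` the orientation density concentrates in a cone of width
`~ 1/sqrt(k)` (about 2 degrees). On coarse direction grids (16 or 32 nodes)
every off-axis node is suppressed by factors like `exp(-53)`, transverse
motion inside the stripe is numerically impossible, and the population stays
trapped on the stripe axis indefinitely. The breakout and relaxation
diagnostics of the stripe scenario are therefore computed at 128 direction
nodes (64 x 64 spatial grid, single speed), the coarsest angular grid that
resolves the cone; there the population climbs the stripe, leaves it
sideways when its center of mass reaches the height of the chemoattractant
(y close to 4), and settles exponentially into its stationary state.

**Relaxation time.** The relaxation of the stripe scenario is quantified as
the e-folding time of `|com(t) - com(inf)|` fitted on the exponential tail
(deficits between 0.3 and 0.02 length units). The early climb phase is
deliberately excluded: there the chemotactic bias between up- and
down-facing protrusions is saturated (ratios like `e^30`), so the climb
speed is kernel-independent. The kernel dependence predicted by the moment
ratio `Gamma(delta_R) / Gamma(H) = 2` is a linear-response statement and is
recovered in the near-equilibrium exponential regime: the measured e-folding
ratio between Heaviside and Dirac-at-R chemoattractant sensing is about 1.9.
The first-crossing time of a fixed tolerance band, by contrast, mixes the
saturated transient in and yields a smaller ratio (about 1.3).

## What the synthetic configurations do and do not show

All inputs are analytic fields; there is no measured data anywhere. The
configurations emulate the canonical study conditions: stripe or
Gaussian-bump fiber geometries with constant axis, Gaussian or linear
chemoattractants, Gaussian initial cell clouds. They do not emulate fiber
networks reconstructed from imaging (spatially varying axis fields with
noise), chemoattractant consumption or production, cell-cell interactions,
or any coupling of the cues to cell speed. Passing tests therefore
demonstrate the internal consistency of the kinetic/macroscopic framework
and its qualitative experimental signatures (cooperation vs competition of
cues, regime-dependent spreading), not quantitative agreement with any
particular biological dataset.

## Known limitations

* First-order upwind transport carries numerical diffusion of order
  `v dx / 2`; on coarse grids it is comparable to the physical diffusivity
  `D/(2 mu)`. Cross-scale L1 comparisons use the minmod scheme, a turning
  frequency of 2 and matched discrete speed moments so that the
  R-dependent part of the kinetic-vs-macroscopic discrepancy dominates the
  scheme baseline; the residual baseline is still a few percent.
* The case-iii/iv drift formulas are asymptotic objects with sign-changing
  normalizations; on generic fields they can be arbitrarily large near the
  degenerate set. They are evaluated and tested pointwise and through their
  reductions; integrating them as PDE drifts over a whole domain is only
  meaningful away from that set.
* Direction space is the unit circle; three-dimensional direction spheres,
  polarized fiber networks (non-zero mean fiber direction) and time-evolving
  cues are out of scope.
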