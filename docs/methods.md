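# Methods

`ringrupture` models constant-velocity optical-tweezers pulling
experiments on a ring-shaped protein complex (cohesin) that
topologically entraps DNA, and the inference of the ring's
disengagement parameters from the measured rupture forces.

## Physical model

**Tether mechanics.** A double-stranded DNA of persistence length *P*
and contour length *L*₀ is anchored to the surface at both ends, a
distance *D* apart, and pulled at its midpoint perpendicular to the
anchor line. At midpoint displacement *x* the chain's end-to-end length
is *L* = 2√((D/2)² + x²) and its tension follows the Marko–Siggia
worm-like-chain interpolation

    F_DNA = (kBT/P) [ 1/(4(1 − L/L₀)²) − 1/4 + L/L₀ ].

The two arms of the V each pull on the ring at half-angle α
(tan α = 2x/D), so the load on the ring is F_ring = 2 F_DNA sin α.

**Two-DNA geometry.** When the ring couples the surface-tethered DNA to
a second, bead-proximal chain (extension L₁, tension F₁), mechanical
equilibrium plus geometry give a five-equation system: two WLC laws, the
force balance F₁ = 2 F₂ sin α, the closure (L₂/2) sin α + L₁ = x and
tan α = 2(x − L₁)/D. The last two equations eliminate L₂ in closed form,
L₂ = √(D² + 4(x − L₁)²) — the surface chain forms the same V as the
single-tether case with its apex displaced by (x − L₁) — leaving one
strictly increasing scalar equation in L₁.

**Disengagement kinetics.** The ring opens with the Bell rate
k(F) = k₀ exp(δF/kBT): k₀ (s⁻¹) is the spontaneous interface-opening
rate at zero force and δ (nm) the mechanical displacement parameter.
Per time step dt the simulator draws a uniform variate r and a candidate
waiting time t_detach = −ln(1 − r)/k(F); the ring disengages in the first
step with t_detach ≤ dt, and the current ring tension is recorded as the
rupture force. This literal draw-and-compare scheme is equivalent in law
to a Bernoulli step with p = 1 − exp(−k dt) and is kept for fidelity to
the stated algorithm.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| P | 50 nm | DNA persistence length |
| L₀ | 16.32 µm | λ-DNA contour length (surface tether) |
| L₀ (bead side) | 2.45 µm | 7.2 kb plasmid captured as the second DNA |
| v | 0.16 µm/s | pulling velocity |
| D | Normal(8.8, 0.5) µm | anchor separation, redrawn per event |
| dt | 0.01 s | time step (0.1 s retained for convergence checks) |
| kBT | 4.114 pN·nm | thermal energy at 298 K |
| x₀ | 0 | initial midpoint displacement |

The experimental temperature is not part of the protocol description;
kBT = 4.114 pN·nm (298 K) is the room-temperature single-molecule
convention and is configurable. x₀ = 0 only shifts rupture *times*, not
forces, because the tether is slack for the first ~30 s of the ramp.
D is truncated to (0.1 L₀, 0.95 L₀) to exclude unphysical draws; at the
default mean/sd the truncation is never active in practice.

Internally all lengths are nm, forces pN, times s. Configuration files
use explicitly unit-suffixed keys (`velocity_um_per_s`, `delta_nm`) and
convert at the boundary, because the µm/nm mix is the dominant source of
error in this geometry.

## Numerical choices

* **Overstretching.** Extensions within 10⁻⁶·L₀ of the contour length
  raise an error rather than being clamped; silent clamping would
  distort the high-force tail of the rupture distribution. Pulling
  events that reach this limit before rupturing are *censored*: excluded
  from the force sample and counted (`n_censored`), never silently
  dropped.
* **Rate cap.** Bell exponents above 500 are capped with a warning;
  rupture is then certain within one step, so the cap cannot bias
  recorded forces.
* **Two-DNA solver.** The scalar reduction is solved with Brent's method
  (scalar API; residual tolerance 10⁻⁸ on scaled residuals of all five
  equations). Inside the vectorised simulator the root is bisected per
  time step from a warm start: the root L₁(x) advances by at most v·dt
  per step (dL₁/dx ≤ 1, from implicit differentiation), so a bracket of
  width 2 v·dt suffices; 26 bisections resolve L₁ to ~10⁻⁶ nm. The
  engine's forces agree with the Brent solution to < 3·10⁻⁹ pN.
  The only possible "solver failure" is the physical one — a chain at
  its contour length — which is handled as censoring.
* **Bead-proximal contour.** The second DNA captured by the ring is the
  7.2 kb plasmid used in the capture experiments (contour ≈ 2.45 µm at
  0.34 nm/bp). Using a second full-length λ contour instead lowers the
  simulated two-DNA mean rupture force from ~17.5 pN to ~13 pN by
  doubling the stretched contour, which is inconsistent with the
  measured ~16 pN and with the observation that the two-DNA reduction is
  *slight*; the plasmid contour is therefore the default, and per-chain
  parameters remain configurable.
* **Common random numbers.** The engine consumes one uniform variate per
  event slot per step regardless of which events are still running, so
  two simulations with the same seed experience an identical random
  field even at different bond parameters. Every objective evaluation in
  a fit reuses one fixed seed, making the objective surface — and the
  whole search — deterministic.

## Parameter inference

The rupture-force distribution is not differentiable in (k₀, δ), so
fitting minimises the moment distance between observed and simulated
distributions. The default objective z-scores the two terms by the
sampling variances of the observed moments,

    J = (μ_sim − mean F)²/var_mean + (σ_sim − std F)²/var_std,

i.e. the negative log of the likelihood weight used for the confidence
intervals; the raw least-squares form on means and variances is
available as an option. var_mean = s²/n and var_std = s²/(2n) (the
large-sample variance of a sample standard deviation under approximate
normality) are computed from the observed sample and overridable.

**Search.** The (log k₀, δ) box is minimised by two-dimensional golden
search implemented as box contraction: the box is sampled on a 5×5
lattice, re-centred on the best point, and contracted by 0.45 per
iteration in both coordinates until the widths fall below tolerance
(2% in k₀, 0.01 nm in δ). Both coordinates must contract *jointly*: the
simulated mean is, to leading order, the Bell–Evans mode
(kBT/δ)·ln(δḞ/(k₀kBT)), so the objective has a diagonal valley in
(log k₀, δ) along which one-coordinate-at-a-time golden contraction
stalls at pseudo-stationary points (observed directly during
development: a coordinate-wise search on strong-interface data froze at
k₀ ≈ 1.6·10⁻⁶ s⁻¹, δ ≈ 1.0 nm, two orders of magnitude from the
generator, with an objective ~170× above the noise floor).

**Confidence intervals.** The 90% interval for one parameter is read
from the Monte-Carlo-sampled likelihood profile: the parameter is
sampled uniformly around its optimum (k₀ over [k₀/4, 4k₀] on a linear
scale, δ over ±0.25 nm — ranges chosen to comfortably bracket the
published interval widths), a fresh distribution is simulated at each
sample, the weights exp{−(μᵢ−mean F)²/var_mean − (σᵢ−std F)²/var_std}
are normalised, and the central region covering 90% of the area is
returned. All samples are simulated in a single vectorised engine call
with per-event parameters. A subsample bootstrap (`bootstrap_stability`,
sampling without replacement with a fixed fit seed, so dispersion
reflects data variability only) provides an independent stability check.

**Bimodal data.** Samples from hinge-crosslinked complexes mix a ~20 pN
and a ~70 pN population; they are partitioned at a fixed 40 pN threshold
(the antimode between the two modes) and fitted separately.

## Bead-attachment model

Complexes are placed on DNAs according to a sampled occupancy; each
complex nucleates a bead with probability λ; the bead then co-captures
the remaining unassigned complexes of the same DNA — with certainty
inside a 1 µm proximity threshold, with probability λ outside it.
Complexes are visited in random order and belong to at most one bead;
a distal complex that attaches joins the existing bead rather than
founding a new one. These two rules (sequential assignment, join-not-
found) resolve ambiguities the verbal description leaves open and are
fixed so results are reproducible. λ is calibrated by bisection against
an observed mean beads-per-DNA (the statistic is non-decreasing in λ;
the sampling seed is fixed across bisection evaluations). Sampling runs
10,000 steps by default.

## Synthetic data

The experimental rupture datasets are unpublished, so generators emulate
them: named scenarios reproduce the published parameter sets and sample
sizes (head n=89, hinge n=21, head-crosslinked n=24, hinge-crosslinked
50/50 mixture n=25, two-DNA n=41), each a pure function of
specification + seed with a JSON provenance sidecar. Occupancy tables
use Poisson counts and uniform positions along a 16.32 µm DNA — a
neutral stand-in for the unpublished empirical occupancy distribution.
No measurement noise is added by default (the model has none); optional
Gaussian noise supports fitter robustness studies. What the generators
do **not** emulate: bead/trap compliance, Brownian force noise,
x-vs-y force decomposition of the instrument, multi-cohesin tethers,
DNA overstretching at ~65 pN, and re-closure after disengagement —
so passing tests demonstrate internal consistency of the model and
correctness of the inference machinery, not instrument-level realism.

## Problem sizes

Distribution-level checks use 10⁴ events (the scale at which the
published statistics are quoted); mechanistic unit tests use 1.5–4·10³
events, which resolves means to ~0.2 pN. Fits in the test suite and
acceptance script use 1200–1500 simulated events per objective
evaluation: the induced parameter noise (a few percent in k₀, ~1% in δ)
is well inside the published 90% intervals used as the recovery
criterion. The Kolmogorov–Smirnov null-calibration check uses 200
repetitions at n = 400 per sample.

## Known limitations

* The simulated rupture force is the scalar ring tension; instrument
  records decompose force into x/y components, which this model does not
  represent.
* The two-DNA mode treats the captured plasmid as a linear chain of its
  full contour; threading of a covalently closed circle through the ring
  (two load-bearing strands) is not modelled.
* The moment-matching objective uses only the first two moments; shape
  information in the rupture distribution (skewness of the Bell–Evans
  form) is not exploited.
* The bead model is static and combinatorial; it has no kinetics or
  spatial diffusion.
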