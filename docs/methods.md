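# Methods

`vepfield` implements a high-resolution virtual-epileptic-patient (VEP)
workflow: seizure dynamics of the two-variable epileptor, extended to a
neural field on spherical cortical surfaces, are simulated with a
pseudospectral spherical-harmonic method, projected to stereotactic-EEG
(SEEG) sensors, and inverted by maximum-a-posteriori (MAP) optimization to
recover a vertex-level map of tissue excitability, from which the
epileptogenic zone (EZ) is classified by seizure onset times.

## Model

### Epileptor neural field

Every source (cortical grid node or subcortical point node) carries a fast
variable `x` and a slow permittivity variable `z`:

    dx/dt = 1 - x^3 - 2 x^2 - z + I
    dz/dt = (1/tau) [ 4 (x - x0) - z
                      - G * sum_j K_ij (xbar_j - xbar_i)
                      - gamma * (W_hom * S(x, theta)) ]

* `x0` — per-source tissue excitability (dimensionless). An isolated node
  (G = gamma = 0) switches from a stable rest state to the seizing upstate
  when `x0` exceeds a critical value: the rest state sits at the
  intersection of the cubic nullcline `z = 1 - x^3 - 2x^2 + I` with the
  line `z = 4 (x - x0)`, and destabilizes when the intersection passes the
  knee at `x = -4/3`, giving `x0* = -4/3 - (1 - (-4/3)^3 - 2 (4/3)^2 + I)/4
  ≈ -2.06` for `I = 3.1` (within the conventional ≈ -2.1 bound).
  Defaults: EZ tissue `x0 = -1.8`, healthy tissue `x0 = -3.0`.
* `I = 3.1` — external current of the 2D reduction (from the original
  epileptor literature); it reproduces the ≈ -2.1 threshold.
* `G` — global gain on long-range coupling through the region-level
  connectome `K` (nonnegative, zero diagonal). Coupling acts on
  region-average activity `xbar`; we implement *difference* coupling
  `K_ij (xbar_j - xbar_i)`, the standard VEP form, under which a spatially
  uniform state receives no long-range input. A source's own region average
  is its reference, so intra-region coupling vanishes.
* `gamma = 1`, `theta = -1` — gain and threshold of the sigmoid
  `S(q, theta) = 1/(1 + e^-(q - theta))` feeding the short-range coupling.
* Both coupling terms sit inside the `1/tau` bracket of `dz/dt`, following
  the equation's printed grouping; the alternative (outside the bracket)
  would only rescale `G` and `gamma` by `tau`.
* Subcortical regions are single point nodes with the same node dynamics
  but no short-range term (they have no surface neighbourhood); they couple
  to everything through `K`.

Integration is explicit Euler, `dt = 0.05 s`, 600 steps, states stored
every 0.1 s (300 frames). The generative simulation is deterministic; noise
enters only through the observation model and data augmentation. A
dt-halving test bounds the Euler discretization error on smooth runs at a
few percent.

### Pseudospectral short-range coupling

The homogeneous kernel is the Laplacian (exponential) function
`W(d) = e^{-d}/2` of geodesic distance `d` in mm on a sphere of radius
`r = 100 mm`. Because the kernel is sharp (decay length 1 mm versus a
100 mm sphere) and rotationally invariant, the convolution is, to second
order in the kernel width, diagonal in the spherical-harmonic basis:

    W * psi ≈ N psi + SHT^-1[ -D l (l + 1) ] SHT psi

with

    N = r^2 ∮ (1/2) e^{-r thetabar} sin(thetabar) dthetabar dphi ≈ 3.14128
    D = (r^2/4) ∮ thetabar^2 (1/2) e^{-r thetabar} sin(thetabar) ... ≈ 0.00047108

at `r = 100` (both evaluated by adaptive Gauss–Kronrod quadrature of the
colatitude integral, the azimuthal integral being an exact 2π factor; `N`
has the closed form `π r² (1 + e^{-rπ})/(1 + r²)` used as a cross-check).
The operator is applied to the sigmoid-transformed field `S(x, theta)` and
truncated at a configurable degree (default 32 for simulation, independent
of the inference truncation `L_max = 16`). Since `D l (l+1) < N` for all
`l ≤ 32` at `r = 100`, the multiplier stays positive and a positive field
maps to a positive field. A degree-l harmonic is an exact eigenfunction
with eigenvalue `N - D l (l+1)`; a brute-force surface quadrature of the
convolution against a degree-16 random field agrees with the spectral
operator to within 5% relative L2 error (test-suite oracle).

The spherical harmonic transform itself is implemented on a
Gauss–Legendre × equispaced-longitude grid (`L + 1` colatitudes,
`2L + 2` longitudes), on which analysis of band-limited fields is exact
(round trips hold to 1e-14 in practice; the test suite requires 1e-8).
Real orthonormal harmonics are used with `(L + 1)^2` coefficients per map
per hemisphere, stored (l, m)-major (index `l² + l + m`).

### Hemispheres and source space

The two hemispheres are independent unit spheres with independent
transforms — matching per-hemisphere surface inflation — and interact only
through the connectome. Sources are ordered [hemisphere-0 grid nodes,
hemisphere-1 grid nodes, subcortical nodes]. Mesh vertices map to their
nearest grid node by great-circle distance (ties to the smallest node
index); a grid node's region is the majority label of its mapped vertices
(ties to the smallest region id, nearest-vertex fallback for empty nodes).
For sensor geometry the hemisphere spheres are placed tangent at ±100 mm
along the left–right axis, so the two cortical sheets never interpenetrate
(overlapping spheres would let contralateral sources sit next to the same
contacts and become indistinguishable in the gain); distances to sensors
are Euclidean in mm.

### SEEG forward model and features

Monopolar gain: `G_ij = a_i / d_ij²`, with `a_i` the vertex area (one third
of each incident flat-triangle area, at physical radius) and `d_ij` the
Euclidean source-contact distance floored at 1 mm; no tissue-orientation
dependence. Mesh-vertex gains are summed onto each vertex's nearest grid
node (conserving per-sensor gain mass); subcortical point nodes are
weighted by the mean cortical vertex area so both source kinds share a
scale (the model itself gives point nodes no area). Bipolar rows are
absolute differences of adjacent contacts on one electrode, floored at
1e-12 for positivity.

The data feature is SEEG log power (SLP). Predicted:
`alpha * log(G_bip · e^x) + beta` at the 300 stored frames, with `alpha`,
`beta` a global linear transformation estimated with the model. Empirical:
high-pass 10 Hz → sliding-window mean-square power (1 s window, 50%
overlap) → log (floor 1e-10) → low-pass 0.05 Hz → resampling to 300
points. Window length, overlap and filter orders (4 high-pass / 2
low-pass, zero-phase) are conventional choices, configurable. Observed
features are augmented with 50 Gaussian-noise copies (sd 0.1).

## MAP inference

Parameters: three spatial maps — `x(t0)`, `z(t0)`, `x0` — as SH
coefficients up to `L_max = 16` per hemisphere plus per-subcortical-node
scalars, and five global scalars `G, tau, eps, alpha, beta`. At full
resolution (no SHT reduction) the dimensionality is `3 × sources + 5`
(196,667 at 2 × 32,768 cortical vertices + 18 subcortical nodes). With
`L_max = 16` our count is `3 maps × 2 × 289 + 3 × 18 + 5 = 1,793`.

Priors (mean, variance, box):

| parameter | prior | box |
|---|---|---|
| x(t0) | N(-3, 0.5) | [-5, -1.5] |
| z(t0) | N(5, 0.5) | [4, 6] |
| x0 | N(-3, 0.5) | [-5, 0] |
| G | N(1, 5) | [0, 10] |
| tau | U(20, 100) | — |
| eps | N(0.1, 0.1) | [0, 1] |
| alpha | N(0, 1) | [0, 10] |
| beta | N(0, 1) | [-10, 10] |

Box constraints are enforced by smooth logistic squashing: scalars map an
unconstrained variable through `lb + (ub - lb) σ(u)`; spatial maps keep
unconstrained coefficients, and the reconstructed per-source field passes
through a logistic soft bound with unit slope at the box centre. Priors
(truncated normals, unnormalized; flat for `tau`) are evaluated on the
natural bounded scale without a Jacobian correction — MAP on the natural
scale is what truncated-normal priors with boxes imply; the
transformed-scale alternative would add a log-Jacobian term. The
likelihood is Gaussian with one global standard deviation `eps`, summed
over channels, time points and all augmented copies (computed via the
exact sufficient-statistic identity so cost is independent of the copy
count).

Optimization is Adam (learning rate 0.001, betas 0.9/0.999, 5,000 steps by
default, no early stopping) on the unconstrained vector, with exact
reverse-mode gradients propagated by a hand-derived adjoint sweep through
the Euler tape (verified against central finite differences to ~1e-6
relative); the returned MAP point is the best objective value visited
along the trajectory, since late iterates can oscillate along posterior
ridges. Multiple restarts (default 4) run from different initial
conditions and the best objective wins; all seeds and loss traces are
returned.

Restart 0 uses a data-driven initialization. Because SLP is logarithmic, a
channel dominated by spillover from distant seizing tissue rises almost as
much as a channel next to it, so backprojecting the *log-power* rise
smears excitability over everything near a rising channel. The rise is
therefore mapped back to the linear power scale (where increases span
orders of magnitude with distance) and localized by nonnegative least
squares on the bipolar gain — a standard sparse source-localization step.
Region-aggregated NNLS energy seeds the excitability map with a
*subthreshold* bump (maximum -2.2, below the ~-2.06 autonomous-seizure
threshold), so which tissue actually seizes is decided by the
optimization, not the seed; suprathreshold seeds were observed to lock in
spurious seizing regions as local optima. The slow timescale is seeded
from the earliest channel half-rise time (onset latency ~ 0.45 tau for the
epileptor leaving its rest state) and the SLP offset from baseline
matching. The remaining restarts use prior means (pulled just inside
their boxes) plus seeded coefficient jitter.

## EZ classification and validation

Onset time per source: first time `x` exceeds 0 (the depolarized upstate
of the 2D epileptor is positive; the level is configurable) sustained for
at least 2 stored frames. With `t_lambda` the earliest onset, sources with
onsets within tolerance `t_eps` (default 10 s; 30 s in sweeps) are EZ,
later ones propagation, silent ones healthy. Region-level predictions
threshold the percentage of a region's sources labelled EZ (default 20%);
region onsets are either the earliest member onset or, stray-robustly, the
fractional onset — the time by which 20% of the region's sources have
seized, mirroring the vertex-percentage threshold. Resection-style region
masks lift to source resolution by region lookup.

The recommended end-to-end classification (`classify_sampled_regions`, the
workflow default) applies the onset-tolerance rule to fractional region
onsets over *implantation-sampled* candidate regions — the union of the
radius rule and the cortical territory each electrode trajectory
traverses — and broadcasts region labels back to sources. Restricting
candidates is deliberate: tissue with no sensor support contributes
nothing to the likelihood, so its inferred excitability is prior- and
optimizer-noise-driven; phantom seizures there would otherwise both
pollute the prediction and shift the earliest-onset anchor. An SEEG-driven
classification can only speak about tissue the implantation observes.

Validation: precision/recall (precision defined as 0 when nothing is
predicted, the sweep convention), paired t tests across seizures (error on
zero-variance nonzero differences), implantation coverage (a region is
implanted if any source lies within a radius, default 3 mm, of any
contact; sweeps 1–10 mm), and the minimum detectable paired effect size by
root-finding on the noncentral-t power curve (0.89 at alpha 0.05, power
0.8, n = 12).

## Synthetic data

The generator emulates the structural features of a presurgical dataset
without patient data: two level-`m` icosphere hemispheres; a contiguous
parcellation of 72 cortical regions per hemisphere grown from
farthest-point seeds (nearest-seed angular Voronoi, hence connected
patches) plus 9 subcortical point nodes per hemisphere at seeded interior
positions (the 162-region layout); a symmetric, nonnegative,
distance-decaying lognormal connectome with unit row sums; and linear
depth electrodes with 3.5 mm contact spacing descending radially from the
target centroid (cortical targets) or spanning entry-to-node (subcortical
targets). The implantation design mirrors clinical practice and the
identifiability-by-implantation principle: electrodes on the EZ regions
themselves, their immediate neighbours, distal ipsilateral survey regions,
and two contralateral survey electrodes (ruling out contralateral onset
and anchoring otherwise-unobserved tissue).
Ground truth: `x0 = -1.8` in three EZ regions (two adjacent cortical, one
subcortical, mirroring a temporal-plus-thalamus configuration), `-3.0`
elsewhere; initial state `(x, z) = (-2, 5)`; true scalars `G = 1`
(connectome rows sum to 1), `tau = 30 s` so that the EZ onset (~0.45 tau
after start for this geometry) falls mid-window with room for propagation,
`alpha = 1`, `beta = 0`. Observations are the noiseless predicted SLP plus
the 50-copy augmentation.

What the generator does *not* emulate: realistic cortical folding and
region shapes, tractography-based connectome topology, heterogeneous
contact spacing, measurement artifacts, or patient-specific gain
asymmetries. Passing the recovery tests therefore demonstrates that the
inference machinery is correct and well-conditioned under the stated
geometry, not that clinical-grade localization accuracy is guaranteed on
real SEEG.

## Problem sizes and numerical choices

The reference study conditions for recovery runs are a level-4 icosphere
per hemisphere (2,562 vertices each), a degree-16 pseudospectral grid
(578 nodes per hemisphere; 1,174 sources with the 18 subcortical nodes),
70 bipolar channels from 10 eight-contact electrodes, and `L_max = 16`
(1,793 parameters). Recovery runs use the standard 5,000-step Adam
termination with the single data-driven start (the dense coupling matmul
runs in float32 inside the optimizer loop, a ~2x speedup at ~1e-7
relative rounding; generation and verification stay in float64). Tolerances: SHT round trip 1e-8;
kernel-constant quadrature 1e-8 relative; gradient check 1e-4 relative on
randomly probed coordinates; onset detection requires 2 consecutive
frames; bipolar floor 1e-12; minimum sensor distance 1 mm.

Known limitations: explicit Euler only (per the modelling convention; no
higher-order integrators), no conduction delays (instantaneous coupling),
a single global observation noise, point estimates only (no posterior
uncertainty), and the degree-truncation of spatial maps bounds how sharply
an inferred excitability boundary can localize (smoothing can shave
borderline vertices off an EZ, which is visible as sub-unit recall of the
band-limited representation of a piecewise-constant truth). Tissue with no
sensor support is unconstrained by the likelihood: its inferred
excitability reflects the prior and optimizer drift, not data — the reason
the recommended classification restricts EZ candidates to
implantation-sampled regions and any map-recovery statistic should be read
over observed tissue only.
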