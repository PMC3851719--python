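# Methods

This note documents the models, estimators and numerical choices behind
`pullfe`, and what the synthetic experiments do and do not demonstrate.

## The toy pulling model

The physical situation emulated is the forced rupture of a single terminal
base pair whose stability may be enhanced by a stacked ligand.  The
all-atom problem is reduced to one dimension: a "separation-like"
collective variable x (nm) on a landscape U(x) built as a sum of attractive
wells, with a step function n(x) ∈ {2, 1, 0} standing in for the discrete
hydrogen-bond count of the pair.  Frames with n ≥ 1 constitute the bound
ensemble, n = 0 the unbound one.  The mapping from position to count is a
modeling stand-in, not a reconstruction of any geometric hydrogen-bond
criterion.

Two well shapes are available: Gaussian wells
`U = −depth·exp(−(x−c)²/2w²)` and smoothed rectangular wells built from two
tanh edges (center, depth, half-width, edge-softness s).  Rectangular wells
are the default in the packaged experiment because their free energy
approaches `−depth − kT ln(width)` in the stiff-edge limit, which makes
depth calibration nearly linear.

**Ground truth by quadrature.**  For any landscape the exact breaking free
energy is

    ΔF = −kT ln( ∫_unbound e^{−βU} dx / ∫_bound e^{−βU} dx )

computed by adaptive quadrature over the domain, split at the n = 1→0
threshold.  `calibrate_depth` tunes the bound well's depth by bracketing
root-finding until this oracle matches a target within 10⁻³ kJ/mol.  The
packaged apo-like and holo-like systems are calibrated to −2.5 and
+1.9 kJ/mol, so their true ΔΔF (apo − holo) is −4.4 kJ/mol by construction;
the pipeline is then judged by whether it recovers these values from
pulling data alone.

**Pulling protocol.**  A harmonic restraint V(x, λ) = k/2 (x − λ)² with
k = 3.9·10⁴ (kJ/mol)/nm² is dragged from λ = 0 to 0.35 nm at
0.175 nm/ns (2 ns per replica) at 300 K — the stiff-spring, constant-
velocity steering protocol of the system this package emulates.  Initial
positions are independent rejection-sampled draws from the λ₀-restrained
Boltzmann density, mirroring starting points extracted from a long
restrained equilibration; replica i of an ensemble uses seed base+i, and a
(landscape, protocol, seed) triple determines every output bit.

**Integrator.**  Overdamped Euler–Maruyama,
`x ← x − βD∇(U+V)dt + √(2Ddt)·η`.  Stability and accuracy are governed by
the dimensionless step a = βDk·dt (the fraction of the trap relaxation
completed per step); the scheme is unstable for a > 2 and its stationary
variance is inflated by 2/(2−a).  The defaults D = 6·10⁻⁴ nm²/ps and
dt = 5·10⁻³ ps give a ≈ 0.047 (variance error ≈ 2.4%, invisible next to
the statistical errors), 4·10⁵ steps per replica, and a trap relaxation
time of ≈ 0.1 ps — about 2·10⁴ relaxations per pull, i.e. near-quasi-static
driving with a mean dissipated work of ≈ 0.26 kJ/mol ≈ 0.1 kT.  The edge
softness of the default wells (0.01 nm) keeps the landscape stiffness below
the trap stiffness so the same step bound applies.  Work uses the
potential-difference convention — each λ advance adds
V(x, λ_new) − V(x, λ_old) at frozen x *before* the particle relaxes — under
which the discrete-time Jarzynski identity holds up to integrator error;
force-times-displacement is deliberately not used.

**Frames.**  One analysis frame is recorded every 2000 steps (10 ps,
≈ 100 trap relaxation times), giving 201 nearly independent frames per
replica and λ-spacing (0.00175 nm) far below the trap width (0.008 nm),
so adjacent restraint windows overlap heavily.

## Estimators

**Jarzynski profile.**  F(t) = −kT ln[(1/N) Σᵢ e^{−βW_{i,t}}], endpoint-
anchored, evaluated by log-sum-exp (exact for βW spanning ±10⁴).  Jensen's
inequality F(t) ≤ ⟨W_t⟩ is asserted in the test suite.

**Unbiased frame weights (Jarzynski + WHAM).**  Each recorded frame (i, t)
receives

    w_{i,t} ∝ exp(−β[W_{i,t} − f_t]) / Σ_{t'} N exp(−β[V(q_{i,t}, λ_{t'}) − f_{t'}])

with f_t the Jarzynski free energy of slice t (no self-consistent WHAM
iteration).  The numerator's exp(+βf_t) factor normalizes each slice's
exponentially weighted samples before pooling; by the nonequilibrium
identity ⟨δ(x − x_t) e^{−βW_t}⟩ = e^{−β(U+V_t)}/Z₀ the pooled estimator is
then unbiased for the equilibrium density.  Omitting the factor (pooling
un-normalized slices) distorts the recovered landscape by roughly a factor
of two in free energy — a failure mode checked directly against the
quadrature oracle during development.  A stride parameter may decimate the
denominator slices (a constant factor that cancels in normalization); all
tests run at stride 1.

**Projection and state ΔF.**  Profiles over any per-frame CV are
−kT ln(Σ_bin w), minimum-anchored, with empty bins reported as NaN (never
interpolated); profiles are equivalence classes under constant shifts.  The
breaking free energy is −kT ln(Σ_unbound w / Σ_bound w); "formation" is its
exact negative.  ΔΔF = ΔF_apo − ΔF_holo, negative when the ligand
stabilizes the paired state.

**Uncertainty.**  Standard errors come from a nonparametric bootstrap that
resamples whole trajectories (B = 200 by default, seeded): frames within a
replica are correlated, so frame-level resampling would be anticonservative
and is not offered.  The full weighting pipeline is re-run per resample;
resamples that lose a state are dropped and counted, and more than 20%
failures raises an error instead of reporting a misleading se.  The point
estimate is always the full-sample value.  ΔΔF errors combine the two
systems' standard errors in quadrature.  Convergence is flagged when
se ≤ kT, Kish ESS ≥ 10 (over per-trajectory aggregated weights) and no
single trajectory holds more than half the total weight; the last flag
reproduces, qualitatively, the known pathology of rare low-work
realizations dominating exponential averages.

## Nearest-neighbor duplex model

ΔG°37 of a fully paired RNA duplex = duplex initiation + Σ dinucleotide
stacking terms + a terminal penalty for each helix end closed by an
AU/UA/GU/UG pair + a symmetry correction for self-complementary duplexes.
Only Watson–Crick and G·U wobble pairs are allowed; loops, bulges, dangling
ends and terminal mismatches are out of scope (the motivating comparison is
a pure helix-extension difference, for which those terms cancel anyway).

Two Turner parameter revisions ship as TSV tables with provenance headers
(`turner1999`, `turner2004`, as distributed with ViennaRNA 2.x at
0.01 kcal/mol resolution; kcal → kJ at 4.184).  The two revisions coincide
on every term a fully paired duplex uses, so they give identical numbers
here; `turner2004` is the default and its name is printed with every
result.  The tables were verified against RNAeval (dangles disabled) at
build time, and the test suite keeps an RNAeval cross-check on random
duplexes.  For the 9-bp P1 stem versus its 10-bp AU-extended form the model
gives ΔΔG°37 = −0.90 kcal = −3.77 kJ/mol: the added 5'AA/3'UU stack, with
the terminal-AU penalties cancelling between the two ends.  Tables that
carry the stacking entries at full published precision (−0.93 kcal for the
AA/UU stack) would give −3.89 kJ/mol instead; the difference is parameter-
set rounding, not model structure.

## What the synthetic experiments show — and what they do not

The toy generator reproduces the *statistical* structure of a stiff-spring
steered-MD experiment: independent equilibrium-seeded replicas, broadly
spread work profiles, exponential averaging, an a-posteriori discrete CV
and a two-system comparison with calibrated ground truth.  It does not
reproduce any feature of the atomistic system: no force field, no solvent,
no 3-D geometry, no real hydrogen-bond criterion, no multidimensional
barrier.  Passing tests therefore validate the estimators and their error
bars, not the biophysical numbers; the per-system targets (−2.5,
+1.9 kJ/mol) enter only through the calibration of the synthetic
landscapes.

## Problem sizes and defaults

The packaged experiment uses 512 replicas per system, 201 frames each,
B = 200 bootstrap resamples — about 90 s on one CPU with the numba-compiled
integrator (the bootstrap reuses a precomputed bias matrix, reducing each
resample's WHAM denominator to a matrix-vector product).  Unit and property
tests run on smaller ensembles (24–128 replicas, often at 2–8× pulling
speed), sized so the whole suite finishes in a few minutes.

## Known limitations

* The bootstrap se can undershoot the replicate-to-replicate spread by up
  to ~2× for small N or fast pulling (heavy-tailed exponential averages);
  the test suite checks it stays within a factor 2 of the spread of
  independent replicates.
* The reweighted ensemble only covers the region the restraint visits;
  partition regions far outside the pulled range contribute to the
  quadrature truth but not to the estimate.  With the default landscapes
  this coverage mismatch is ≲ 0.5% of either state's weight.
* Euler–Maruyama discretization biases the sampled distribution at O(a);
  at the default a ≈ 0.047 this is negligible, but users raising D, dt or
  the landscape stiffness should keep βD·k_total·dt well below 1 (the
  simulator raises on divergence, not on slow corruption).
* Forward pulling only: no bidirectional (Crooks/Bennett) estimators, no
  2-D surfaces, no self-consistent WHAM iteration.
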