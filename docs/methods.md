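# Methods

`rhpmap` models the preparation and conformation of random heteropolymer
(RHP) ensembles built from four methacrylates — MMA (`M`), EHMA (`E`), OEGMA
(`O`, side-chain Mn ≈ 500 Da) and NHSMA (`N`) — through four connected
stages: reactivity-ratio estimation, kinetic Monte Carlo sequence simulation,
composition accounting, and single-chain self-consistent field theory (SCFT).
This note records the models, their assumptions, the parameters that matter,
and the choices made where the design was genuinely open.

## Terminal-model Monte Carlo copolymerization

The simulator (`rhpmap.simulate`) treats a batch copolymerization as a
sequence of propagation events on an exact integer monomer pool.  Under the
terminal model, a chain ending in monomer *i* adds monomer *j* with
probability proportional to `count_j / r_ij`, where `r_ij = k_ii / k_ij` is
the reactivity ratio.  Only ratios are experimentally measurable, so
homopropagation constants are taken equal across monomers — the minimal
closure, under which selecting the propagating chain uniformly at random
among living chains is the exact event schedule.  Conversion (consumed
fraction of the pool) is the clock; no explicit radical concentrations or
chain-transfer exchange kinetics are modelled.

All chains initiate at conversion zero (fast chain-transfer pre-equilibrium
of a living polymerization), giving a narrow, Poisson-like chain-length
distribution: `mean_dp_target` sets the pool size as
`n_chains * mean_dp_target / target_conversion`.  An optional termination
channel kills the growing chain after a propagation event with hazard
`h(x) = h0 · exp(−hazard_decay · x)`; `h0` is calibrated so the expected dead
fraction at the target conversion equals `dead_chain.fraction` (survival
`exp(−Σ h)` with events spread uniformly over conversion; the calibration is
first-order — measured dead fractions agree with the request to a few
percentage points).  The decaying hazard encodes the experimental observation
that dead chains form predominantly at low conversion, when primary radicals
are abundant.  `hazard_decay` defaults to 5 (the hazard drops ~30-fold over a
70% conversion run); dead chains stop growing but remain in the ensemble.

Two conservation laws hold exactly, not statistically: monomers consumed
from the pool equal the summed chain contents (integer identity), and at
100% conversion with no dead chains the ensemble composition equals the
realized feed bit-for-bit.

The binary simulator is validated against the Mayo–Lewis closed form
`F1 = (r12 f1² + f1 f2) / (r12 f1² + 2 f1 f2 + r21 f2²)`.  Two transients
must be removed before the comparison is meaningful at 3 Monte Carlo
standard errors: each chain's first unit is drawn from the feed (not by
terminal-model kinetics) and the terminal-state Markov chain needs a few
units to relax, so the measured fraction excludes each chain's first 10
units; and even at 2% conversion the feed drifts, so the closed form is
evaluated at the mid-window feed (first-order drift correction).

## Reactivity-ratio estimation (excess-monomer method)

With one monomer (`ex`) in large excess, essentially all chain ends are
ex-terminal and `d[M_ex]/d[M_j] = r_{ex,j} [M_ex]/[M_j]`, which integrates to
the zero-intercept law `ln([M_ex]₀/[M_ex]) = r_{ex,j} · ln([M_j]₀/[M_j])`.
`JaacksModel.fit` runs one through-origin OLS per minor monomer on the
log-transformed residual fractions, unweighted; timepoints where a minor
monomer's residual falls below 5% are excluded (the log transform amplifies
noise without bound there).  Four experiments — each monomer in excess in
turn, at the 20:1:1:1 design — assemble the full 4×4 matrix.  Ratio pairs
that would be measured by separate binary experiments go through the same
estimator applied to a binary dataset; there is no special code path.

The method is exact only in the infinite-excess, zero-conversion limit.  At
a 20:1:1:1 design a few percent of chain ends are not ex-terminal, producing
a systematic bias of up to roughly 9% on the strongest ratios;
`jaacks_bias` measures it by simulation and verifies that it shrinks as the
excess ratio grows.  Standard errors: the default is the analytic
through-origin OLS SE; a pairs bootstrap over timepoints is available and is
the honest choice for these serially correlated cumulative-conversion data.
Either SE describes noise-driven scatter around the estimator's own
noiseless limit — it cannot and should not absorb the finite-excess bias,
which is why the SE-calibration test targets that limit rather than the
generating ratio.

The default reactivity matrix anchors the two measured NHSMA cross ratios
(`r_N/E = 2.0`, `r_N/M = 0.7`) and fills the remaining ten entries with
stand-ins constrained to the measured trends (all within 0.4–2.0,
`r_*/MMA < 1`, `r_EHMA/OEGMA` and `r_NHSMA/OEGMA > 1`); they are inputs to
exercise the pipeline, not measurements.

## Composition accounting

`rhpmap.composition` converts between the observables of a synthesis
campaign.  Volatile-monomer loss (e.g. ~20% of MMA evaporating during
degassing) is applied to the feed before any conversion arithmetic:
`f_i' ∝ f_i (1 − loss_i)`.  Conversions from pre/post signal integrals use
`x_i = 1 − post_i / (pre_i (1 − loss_i))`; compositions of polymerized units
use `F_i ∝ f_i x_i`.  Both are exact inverses of the synthetic generators at
zero noise, and applying them to a simulated ensemble's own conversions
reproduces its direct sequence-count composition to machine precision.

Purification is modelled as composable chain filters: a molar-mass cutoff
(dialysis; default MWCO 3000 Da, end groups excluded from chain mass by
default) and an HLB window (antisolvent precipitation proxy).  Which tail of
the hydrophobicity distribution precipitation removes depends on the solvent,
so the window's direction is user configuration, defaulting to a no-op.  The
filter is an exact partition — counts and monomer balance are conserved —
and the composition shift is reported in percentage points.  Ideal chain-end
depolymerization regenerates exactly the living chains' monomer content, so
the depolymerization readout equals the living-subpopulation composition by
construction; the living and dead compositions recombine exactly to the
ensemble total.  HLB of a chain is the mole-fraction-weighted mean of
monomer HLB values — the only convention under which a homopolymer's chain
HLB equals its monomer value at any length, which is what makes the
poly(MMA) = 8.45 and poly(OEGMA) = 11.42 benchmarks exact.

## Single-chain SCFT

`rhpmap.scft` solves one coarse-grained chain of N statistical segments
(length `b`, default 0.7 nm; monomer volume `v`, default `b³`) in an
implicit selective solvent on a spherically symmetric radial grid.  Chain
statistics obey the modified diffusion equation
`∂q/∂s = (b²/6)∇²q − w_{m(s)} q`, with the field selected at each contour
position by the monomer identity there.  The substitution `u = r q` reduces
the spherical Laplacian to a plain 1-D second derivative with Dirichlet
boundaries, which a type-I discrete sine transform diagonalizes exactly;
contour stepping is Strang splitting (half-step field, exact spectral
diffusion, half-step field) with `ds = 0.25` monomer units.  Free diffusion
is therefore exact to spectral truncation, which is what makes the
ideal-chain benchmark attainable at 2%.  A Crank–Nicolson stepper was
considered and rejected: the sine basis handles the Dirichlet geometry that
usually forces finite differences, and is both faster and more accurate here.

Fields derive from the Flory–Huggins free energy density
`f = (1−φ_p)ln(1−φ_p) + Σᵢ χᵢ φᵢ (1−φ_p)` (per reference volume `v`),
giving `wᵢ = −ln(1−φ_p) − χᵢ φ_p − Σⱼ χⱼ φⱼ`, referenced to zero in pure
solvent.  The solvent translational entropy supplies the excluded-volume
repulsion and places the homopolymer theta point at χ = 1/2 (dilute
expansion `w = (1−2χ)φ_p`).  A quadratic compressibility penalty was tried
first and abandoned: alone it contributes no second-virial repulsion, which
drives the theta point to χ = 0⁺ and destabilizes deep quenches.  Because
the contact density of a continuous chain diverges at a pinned monomer, a
few cells near the origin legitimately exceed φ = 1; the log is continued
linearly (C¹) above φ = 0.95 so repulsion always dominates there.
`excluded_volume=False` together with χ = 0 removes all interactions — the
exactly ideal chain used as the reference limit.

Translational symmetry is broken by pinning the chain's contour midpoint at
the origin (point-source launch built in mode space, pre-diffused half a
substep).  Self-consistency iterates density → field → mix with simple
mixing (0.1) for a 25-step warm-up, then Anderson acceleration (history 5)
with a blow-up safeguard, to a field-residual rms below 1e−5 within at most
2000 iterations; typical chains converge in 40–150 iterations.  The
partition value is contour-invariant at convergence (drift below 0.1%, which
also bounds the density normalization ∫ρ dV = N).

**Radius of gyration.**  A single pinned frame cannot report Rg directly:
the second moment about a pinned midpoint is N b²/4 for an ideal chain, not
the N b²/6 of the center-of-mass frame.  `rhpmap` instead uses the exact
pair identity `Rg² = (1/2N²) Σ_{s,s'} ⟨(r_s − r_{s'})²⟩`: after convergence
the field is frozen and the density second moment is evaluated for eight
mirror-symmetric pin positions along the contour;
`Rg² = ½ ⟨M2(pin)⟩_pins`.  This estimator is exact in the ideal limit
(errors: midpoint-rule pin sampling −1/(4K²) on Rg², launch smear
+b² ds/12 — both ≪ 1%).  For deeply collapsed globules the frozen mean-field
frame suppresses the pin's wander relative to the cloud, compressing Rg by a
bounded constant factor (at most √2 in the uniform-ball limit); scaling
exponents and ensemble orderings are unaffected, and reported Rg values
should be read with that convention in mind.  The mirror-symmetric pin set
makes Rg exactly invariant under sequence reversal.  `rg_of_profile` is a
separate plain-second-moment utility for centered density profiles (e.g. a
uniform ball gives R√(3/5)).

**Solvent maps.**  Per-monomer χ values come from affine maps on HLB:
water `χ = 2.6 − 0.2·HLB` (quality improves with HLB), pentane
`χ = −0.5 + 0.15·HLB` (the reverse).  Slopes and intercepts are calibration
parameters of the coarse-grained model — chosen once so that chains of ~57
units span roughly 1–3 nm and the four designs separate in water — not
predictions from chemistry.  With these defaults the water χ values are
M 0.91, E 1.58, O 0.32, N 0.05: OEGMA-rich chains sit near theta (large,
variable Rg) while hydrophobic-rich chains collapse, reproducing the
designed ordering.  The radial box auto-sizes to `3.2 b √(N/2)` with 255
interior points; solves for N ≈ 57 take well under a second, and a
non-convergence rate above 5% in an ensemble sweep fails the run loudly.

## Synthetic data

`rhpmap.synthetic` generates every input the pipeline consumes.  Measurement
noise is multiplicative lognormal (signal integrals are positive and their
repeatability error proportional); the default 2% relative sd mirrors
typical quantitative NMR integration repeatability and is a stand-in, not a
measured value.  Zero-noise generators are exact inverses of the
corresponding analysis operations, asserted in tests.  The four named feed
designs increase the hydrophobic (MMA+EHMA) fraction monotonically from
RHP1 (10/20/45/25, the published design, NHSMA by difference) to RHP4;
RHP2–4 compositions and the per-design target conversions (0.6–0.9) are
synthetic stand-ins constrained by the design rules (OEGMA ≥ 10% for water
solubility; EHMA, NHSMA < 50% against precipitation during synthesis).
Default fixture scale is 2000 chains of mean length 57 — the reference
ensembles used 100,000 chains, and the generators accept that scale; the
desk scale keeps the full test suite under two minutes while leaving Monte
Carlo errors far below every tolerance asserted.

What the generators do *not* emulate: NMR spectra (baselines, peak overlap),
GPC traces, incomplete depolymerization, penultimate-unit kinetic effects,
and batch-to-batch reproducibility structure.  Tests passing on synthetic
data therefore validate the estimators' and trackers' internal consistency
and the simulator's statistical mechanics — not instrument-level systematics
of real campaigns.

## Known limitations

- Equal homopropagation constants across monomers (only ratios are
  measured); a monomer with an atypically fast `k_ii` would distort the
  event schedule.
- The dead-chain hazard shape (exponential in conversion) is the simplest
  monotone choice consistent with early-biased termination; only its sign
  structure, not its shape, is validated.
- Single-chain mean-field theory has no center-of-mass fluctuations; the Rg
  convention above compresses deep-globule values by a bounded factor.
- 1-D radial symmetry cannot resolve anisotropic single-chain morphologies;
  only sizes, not shapes, are computed.
- χ maps are calibration knobs; absolute Rg values in nm are meaningful
  relative to that calibration, while orderings and scaling exponents are
  robust to it.
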