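# Methods

This note records the models emuflux implements, the assumptions behind
them, the defaults that matter, and the choices made where the design was
genuinely open. The test suite and `scripts/acceptance.py` compute every
quantitative claim referenced here.

## Steady-state flux model

All methods share one state space: net reaction fluxes v with
`S·v = 0` over internal metabolites and bounds `lb ≤ v ≤ ub`. Boundary
metabolites (feed sources, excreted products) are excluded from the
balance rows. Reversible reactions additionally carry a nonnegative
*exchange* flux; the package fixes the standard decomposition
`forward = exchange + max(net, 0)`, `backward = exchange + max(−net, 0)`,
so `forward − backward = net` and `min(forward, backward) = exchange`.
Exchange fluxes scramble isotope labels without net conversion and are
therefore observable only through labeling, never through stoichiometry.

FBA and FVA are plain linear programs solved with scipy's HiGHS backend.
FVA at fraction f constrains `c·v ≥ f · optimum` and minimizes/maximizes
each flux in turn; every reported range contains the FBA point by
construction (it is clipped in if solver noise puts it outside by <1e-9).

## Labeling simulation (EMU method)

Carbon fate is specified per reaction as an atom transition, e.g.
`accoa(ab) + oac(cdef) --> cit(fedbac)`; carbon conservation (letter
multiset equality) is enforced at parse time. Molecules with a two-fold
symmetry axis (succinate, fumarate in the TCA fixture) are represented by
duplicate transitions with equal fractional weights, one per orientation —
a documented convention; the weights of a reaction's transitions must sum
to 1. Reversible reactions contribute a second, mirrored transition
weighted by the backward flux.

The forward problem is solved by EMU decomposition: starting from the
target fragments, the minimal closure of carbon subsets is traced backward
through the transitions. For each EMU size s (ascending), the unknown MDVs
satisfy a linear balance `A_s X_s = b_s`: the diagonal of `A_s` is minus
the total production flux of the EMU's metabolite, single same-size
sources enter `A_s`, and feed EMUs or convolutions of smaller solved EMUs
enter the right-hand side. Condensations couple sizes strictly downward,
which is what keeps each stage linear. A zero-production EMU makes the
stage singular and is reported by name rather than silently inverted.

Two independent cross-checks ship as first-class code paths:

* a *coupled* solver that iterates the full EMU balance without size
  partitioning (Jacobi fixed point to 1e-14); the suite requires agreement
  with the cascade to 1e-10;
* a *brute-force isotopomer* solver tracking all 2^n positional
  isotopomers per metabolite (fixed point to 1e-14, guarded to a total of
  2^16 states). It is exact and serves as the oracle: the acceptance run
  requires EMU-vs-oracle agreement below 1e-8 across random balanced flux
  states of the TCA toy; observed agreement is at rounding level.

Simulated MDVs are normalized and must be nonnegative to −1e-9 (tighter
violations raise); labeling depends only on flux ratios, and the suite
asserts invariance under global flux rescaling.

## ¹³C MFA fit

The fit minimizes the variance-weighted squared mismatch between measured
and simulated fragment MDVs. The equality constraints are eliminated
analytically: reactions with `lb == ub` (measured fluxes) are written as
extra equality rows, and any feasible flux vector is `v = v0 + N·z` with N
a null-space basis of the stacked system. The optimizer (SLSQP, ftol
1e-12, ≤300 iterations) works on z plus the exchange fluxes of reversible
reactions (default bounds [0, 100] on the uptake-normalized ratio scale,
configurable and pinnable per reaction), with the remaining box bounds as
linear inequalities. Multistart uses points of the flux polytope obtained
by mixing random-objective LP vertices with Dirichlet weights; 10 restarts
by default, best SSR wins, and equal-SSR optima differing by >1e-3 in any
flux raise a degeneracy flag. With every flux pinned the fit degenerates
to a forward simulation, and the residuals are the pure simulation
mismatch.

**Error model.** Reported MDVs are normalized to unit sum, which projects
the raw per-component noise onto the simplex and correlates the
components: for observed vector s and per-component sds d, the induced
covariance is `Σ = (I − s·1ᵀ) diag(d²) (I − 1·sᵀ)`, singular exactly along
the normalization direction. The default fit (`error_model="normalized"`)
whitens residuals with the pseudo-inverse square root of Σ (generalized
least squares); `error_model="independent"` is the classical diagonal
weighting `Σᵢ((obsᵢ−predᵢ)/sdᵢ)²`. The distinction is consequential: on
renormalized synthetic data the diagonal model's 95% profile intervals
undercover (the coverage simulation in the suite shows this directly),
while the whitened model restores nominal coverage. Measurement sds are
floored at 0.003 (typical MS precision) to avoid zero-weight divisions.

**Confidence intervals (¹³C FVA, ELVA).** A flux value (or an external
EMU's mass fraction, for ELVA) is deemed compatible with the data when the
best achievable SSR at that value stays within `χ²(confidence, df = 1)` of
the global minimum — the standard profile-likelihood construction with one
degree of freedom per scanned quantity. Interval searches start from the
best fit and run the same SLSQP machinery with the SSR bound as a
nonlinear constraint; stoichiometrically pinned quantities get zero-width
intervals without a search.

## Two-scale ¹³C MFA

The labeling SSR is computed on the carbon-mapped core exactly as above,
but the optimization variables are the *genome-scale* net fluxes (plus
core exchanges), constrained by the full genome-scale stoichiometry; a
mapping table sends each (possibly lumped) core reaction to the
genome-scale reactions whose net fluxes sum to it. Two identities anchor
the implementation and are asserted end-to-end: with core == genome-scale
the result equals the plain ¹³C fit (to 1e-3, two optimizers), and adding
a pinned biomass drain on a core metabolite shifts the balancing core flux
by exactly the drain.

## Knockout predictions

MoMA solves the strictly convex QP `min ‖v − v_ref‖²` over the knockout
polytope (trust-constr with exact gradient/Hessian); ROOM minimizes the
number of reactions leaving the window `ref ± (δ·|ref| + ε)` as a
big-M MILP over binary indicators (scipy HiGHS, 60 s default time limit,
incumbent returned with a flag on timeout). Defaults δ = 0.03, ε = 0.001
follow the method's original publication. Infeasibility after a knockout
is reported as a lethal-knockout error.

## Natural-abundance correction

A fragment is its full elemental formula plus the number of measured
backbone carbons; the remainder (derivatization groups, heteroatoms) forms
the envelope whose natural heavy isotopes contaminate the spectrum. The
correction matrix's column m is the envelope's mass distribution shifted
by m backbone labels, truncated to the measured window and renormalized —
hence column-stochastic, and the identity when all abundances are zeroed.
Correction solves the matrix equation by nonnegative least squares (plain
inversion can go negative on noisy data); an NNLS residual above 0.1 flags
raw data inconsistent with the fragment. Natural ¹³C in the *unlabeled
backbone positions themselves* is deliberately not corrected: with the
enriched tracers these methods use, that second-order term is far below
the measurement floor, and leaving it out keeps the matrix exactly
column-stochastic. The isotope table ships IUPAC representative values
(H, C, N, O, P, S, Si) and is overridable per call; the fragment database
is an editable CSV (`name, abbreviation, formula, n_carbons,
formula_no_backbone`), validated for internal consistency on load.

## PCAP

PCA runs on the column-centered, by default unit-variance-scaled
strains-by-proteins matrix (log transform available, off by default since
abundances may be zero-anchored); the sign ambiguity is fixed by making
each loading vector's dominant entry positive. Target ranking uses the
component whose scores correlate most with production and orders proteins
by loading magnitude, reporting the correlation sign so
increase/decrease recommendations are explicit. Note a structural limit:
unit-variance scaling erases pure amplitude signals, so a *single*
informative protein is only discoverable with scaling off; coordinated
multi-protein signals (the realistic pathway case) are what scaled PCA
recovers.

## Synthetic-data generators and what they do (not) show

All test inputs are generated in code, deterministically per seed.

* **TCA toy**: the classic 9-reaction benchmark for EMU-based MFA
  (acetyl-CoA + aspartate in, glutamate + CO₂ out; symmetric succinate and
  fumarate; one reversible interconversion with exchange 50 on an
  uptake-100 scale; feed 50/25/25 unlabeled/[2-¹³C]/[1,2-¹³C] acetyl-CoA,
  aspartate unlabeled). Pinning only the uptake leaves one free net flux
  (the glutamate/TCA split r4) plus the exchange — the two-parameter fit
  scenario used throughout. A known identifiability fact of this design,
  reproduced exactly by the engine: with unlabeled aspartate the
  oxaloacetate pool is palindromic, so the fumarate-side exchange flux has
  *no* effect on any labeling and cannot be identified; recovery claims
  therefore concern net fluxes.
* **Measurements**: simulated MDVs of a four-fragment central-metabolite
  panel (glutamate, succinate, citrate, oxaloacetate) plus Gaussian noise,
  truncated to [0,1] and renormalized, with the noise sd reported as the
  error column — emulating normalized MS readouts. Real data additionally
  carry non-Gaussian, fragment-dependent errors and incomplete panels;
  passing recovery/coverage tests shows the estimator and intervals are
  correct under the stated noise model, not that real experiments achieve
  these precisions.
* **Soil community**: a lumped glycolysis+TCA network per carbon source
  (glucose, pyruvate), two tracer variants each sharing one flux state,
  with the biomass/respiration split planted by the target carbon-use
  efficiency (CUE = biomass C-flux / total consumed C-flux). It emulates
  the inputs and observables of two-tracer community experiments, not any
  specific community's topology.
* **Proteomics**: a 3×3×3 factorial screen (promoter × induction strength
  × induction time, 27 strains × 20 proteins) where one latent pathway
  expression level drives three planted proteins (swing 6 abundance units
  against sd-1 noise, the scale of induction systems) and the titer.

## Problem sizes and runtimes

The suite runs simulation studies at sizes chosen to keep the full run in
a few tens of seconds on one CPU while leaving statistical headroom:
20 random flux states for oracle agreement, 20 random truths for
noiseless recovery (tolerance 1e-4; achieved errors are orders tighter),
50 noisy replicates for 95%-interval coverage (bar: ≥90% covered), and
20 seeds for the χ² scale of the minimized SSR. The acceptance script
reruns all of these from scratch at the same sizes.

## Known limitations

* Steady-state labeling only; no isotopically nonstationary MFA.
* Carbon is the only tracked element (no ²H/¹⁵N tracers).
* The SBML subset ignores kinetic laws, events and rules; gene–protein–
  reaction mappings are out of scope (knockouts are reaction-level).
* The brute-force oracle is limited to ~2^16 isotopomer states by design.
* SLSQP with multistart is adequate for core-scale fits (tens of
  reactions); genome-scale *fitting* beyond the two-scale toy pattern has
  not been profiled here.
* LC/GC/CE-MS label-data containers differ only in platform metadata;
  platform-specific corrections beyond the elemental envelope are not
  modeled.
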