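# Methods

## Scope and data flow

The package models a steady-state ¹³C tracer experiment on the central
metabolic pathway (CMP) of a glucose-grown bacterium, plus the two
companion analyses of such a study: specific-rate estimation from batch
cultures and gene-set transcriptome comparisons.  The stages compose as

    atom-mapped network ──> EMU decomposition ──> MID simulation
            │                                         │
    culture time course ──> specific rates ──> flux constraints
            │                                         │
            └────────────> flux fit (RSS) ──> chi-square test, grid CIs

with an expression branch (normalization → Mann–Whitney / volcano) that is
independent of the flux machinery.

## Atom-mapped networks

Reactions carry one lowercase letter per carbon; a letter must occur
exactly once on each side, which is what `validate_atom_balance` checks.
Metabolite roles partition the species: `balanced` metabolites obey
S·v = 0, `substrate` species are carbon sources whose isotopic composition
is an input, and `sink` species absorb effluxes.  Carbon-free cofactors can
be declared with 0 carbons and role `sink`; only carbon is balanced.
Reversible reactions are parameterized as net + exchange with
forward = max(v, 0) + exch and backward = max(−v, 0) + exch, the standard
MFA convention.  Symmetric metabolites (succinate/fumarate-like) are
represented by duplicating the reaction with the two alternative atom maps
at half flux each; the bundled presets do not need this.

The free-flux dimension is the dimension of the affine solution space of
{S·v = 0} ∪ {equality constraints}, computed from matrix ranks, plus one
exchange parameter per reversible reaction.  Whether a published model-df
count includes exchange fluxes varies between tools, so
`free_flux_dimension(..., include_exchange=False)` exposes the other
convention.

## EMU simulation and its oracle

`decompose` traces target EMUs backwards through every producing reaction
direction (Antoniewicz-style): the carbons of a product occurrence map to
source EMUs grouped by substrate *occurrence*, so a condensation that uses
the same metabolite twice yields two independent source EMUs.  Simulation
solves one linear system per EMU size, in increasing order; same-size
cycles (reversible reactions) are exact because the whole layer is solved
at once, and condensation sources are convolutions of smaller, already
solved EMUs.  EMUs are ordered lexicographically (metabolite, then
indices) so that the linear systems — and therefore results — are
bit-reproducible.  A zero-production EMU makes the layer singular and
raises a degenerate-flux error naming the nearest EMU rather than
returning garbage.

Natural ¹³C abundance *inside* the network is off by default: the input
labeling states the substrate composition explicitly (a `natural`
component with a per-position ¹³C probability is available), and
natural-isotope effects of the measurement are handled separately by the
correction matrix.  This keeps simulation and measurement concerns apart.

`enumerate_isotopomers` is the verification oracle: it solves the full
positional-isotopomer balance over all 2ⁿ states of every balanced
metabolite.  Because condensations make that balance bilinear, it iterates
the normalized production map to a fixed point (tolerance 1e−14 on the
sup-norm change); transition matrices are precomputed per reaction so the
iteration is a handful of small mat-vecs.  The oracle shares no code with
the EMU path beyond the network parser, and refuses networks with more
than 12 balanced carbons (configurable), which both presets respect.  The
agreement requirement in the tests is 1e−9; observed agreement is ~1e−14.

## Measurement model

Fragments are data, not code: a fragment names its precursor metabolite(s),
the backbone carbons retained, and the element counts of its non-backbone
atoms (TBDMS-style derivatization groups).  The correction matrix M is a
banded convolution matrix whose kernel is the natural mass-shift
distribution of those atoms (IUPAC abundances; ships as an editable YAML);
`observed = M · backbone` and the inverse problem is solved by nonnegative
least squares with renormalization.  Correction matrices are
column-substochastic because the observed window truncates the heavy tail.
The bundled fragment library is synthetic — its precursors live in the
preset networks — and is labeled as such; a real study must supply its own
library.  Measured MIDs may miss up to 0.02 of total fraction (truncated
heavy channels) before renormalization; the default per-channel SD when a
table has none is 0.003 mass-fraction units, which matters because it
scales the RSS.

## Specific rates

Concentration is regressed against the cumulative trapezoidal integral of
biomass (the standard linearization of d[c]/dt = ±rate·X), and μ is
the log-linear slope over an explicit, user-chosen exponential window — no
automatic phase detection, because phase selection is a judgment call the
analyst should own.  Trapezoidal quadrature was chosen as the standard for
sparse OD series; at 15-min sampling of a μ = 0.46 h⁻¹ culture it biases
rates by ≈0.1%, well inside the 2% recovery requirement, and the bias
vanishes as the grid is refined (tested).  OD→DCW conversion is a required
explicit factor, never assumed.

## Flux fitting

The constrained flux space is parameterized as v = v₀ + N·θ with N a null
space basis of the stacked equality system; exchange fluxes are extra box-
bounded parameters (default bound 20 mmol g-DCW⁻¹ h⁻¹).  Residuals are
(sim − meas)/sd by default; an unweighted mode exists and is recorded in
the fit output, because a published "residual sum of squares" can mean
either and the chi-square scale only works out for SD-weighted residuals.
Inequality bounds (irreversibility) are enforced by smooth hinge penalty
residuals (scale 1e3), which keeps the problem inside a trust-region
least-squares solver; optima are interior in all bundled scenarios, so the
penalties are inactive at solutions.  Multistart: the first start is the
Chebyshev center of the feasible polytope (via linear programming), the
rest are seeded Gaussian perturbations scaled by the polytope's inradius;
everything is deterministic given (seed, n_starts).

Goodness of fit: RSS ≤ χ²₁₋α(n_data − n_free), with n_data the number of
mass channels entering the fit and n_free the number of fitted parameters
(null-space directions + exchange fluxes).

## Grid-search confidence intervals

The CI of a net flux is profile-likelihood-shaped: the flux is pinned on a
grid (initially 21 points spanning ±3 linearized SEs, expanded by step
doubling), all remaining free fluxes are re-optimized at each value —
warm-started from both the global optimum and the neighboring grid point's
solution (continuation) — and the CI is {value : RSS(value) ≤ RSS* + Δ}
with Δ = χ²₀.₉₅(1) = 3.84.  Endpoints are refined by bisection to 1e−3 of
the flux magnitude; an endpoint that runs into a flux bound is reported
bound-censored.  On an exactly quadratic surface this reproduces the Wald
interval v̂ ± 1.96·s to the bisection tolerance (tested against the closed
form).  Two strains differ significantly in a flux when their closed 95%
CIs are disjoint; touching endpoints count as overlap.

## Expression statistics

Normalization scales each sample to a mean of exactly 500.  The one-sided
Mann–Whitney U p-value is the inclusive exact tail P(U ≥ u_obs), enumerated
over all C(m+n, n) reassignments of the pooled values (midranks for ties)
when m+n ≤ 16, and the tie-corrected, continuity-corrected normal
approximation otherwise.  The inclusive convention makes the fully
separated 3-vs-3 case p = 1/20 = 0.05; its flip side is that two identical
groups give p = (1 + P(U = u_obs))/2 > 0.5 rather than 0.5 — a mid-p
convention would give 0.5 there but 0.025 for the separated case, and the
inclusive tail is the standard exact-test definition, so it wins.  The test
direction is always an explicit argument; nothing infers it from the data.

The volcano rule classifies up when log₂FC ≥ 1 ∧ P < 0.05 and down when
log₂FC ≤ −1 ∧ P < 0.05 (the downregulation threshold is the symmetric −1).
Per-gene p-values come from a plain two-sample t-test on log₂ signals;
no empirical-Bayes variance moderation is applied, and the docstring flags
this so users comparing against moderated pipelines know the difference —
with 2–3 replicates, unmoderated t-tests are noisier per gene, which
affects per-gene DE calls but not the set-level rank tests.  Quartiles use
linear interpolation (numpy default).  Genes in both the CMP and AbrB sets
are excluded from either set's statistics.

## Synthetic data: what it does and does not emulate

`TOY1` is the minimal two-branch network (one split, one cleavage) used for
hand-checkable examples; `TOY_CMP` is a 12-balanced-carbon caricature of
central metabolism: glycolysis-like A↔B (reversible, with a positional
swap), a decarboxylating PPP-like branch, a pyruvate-dehydrogenase-like
step, acetate overflow, an anaplerotic carboxylation, a condensation into a
C4 pool and a biomass drain.  The anaplerotic reaction is load-bearing: a
lone reversible reaction whose map is a pure permutation is invisible to
MIDs (the round trip is the identity), so a second producer of B is what
makes the exchange flux observable.  The default tracer is 50%
[1,2-¹³C]/50% unlabeled substrate — a designed choice that separates the
branch split and the exchange; published tracer recipes vary and this one
is the package's own, not taken from any specific study.

Culture defaults are a glucose minimal-medium batch: μ = 0.46 h⁻¹, glucose
uptake 5.9, acetate production 2.7, succinate production 0.2
mmol g-DCW⁻¹ h⁻¹, sampled every 15 min over 6 h.  MID noise is additive
Gaussian per channel (default SD 0.003), clipped at zero and renormalized.
Expression tables are log-normal with per-set log₂ shifts (AbrB regulon −1
between conditions, metabolic sets ≈ +0.5) at replicate SD 0.3 and
3 replicates, with 10 dual-membership genes to exercise the exclusion rule.

Known consequence of the noise model: renormalizing each fragment to sum 1
makes the channel errors correlated (each fragment's residuals sum to
zero), while the RSS treats channels as independent.  The fitted RSS is
therefore systematically below its nominal degrees of freedom and — more
importantly — the 95% profile CIs cover the truth at ≈91% rather than 95%
in the replicate study (45/50 at the fixed test seeds, at the stated ≥90%
requirement exactly).  This is a property of the stated noise model, not of
the optimizer; it is the kind of mild anticonservatism real MID data shows
for the same reason.  Passing the synthetic recovery study therefore
demonstrates correct mechanics and approximate calibration, not exact
frequentist coverage — and says nothing about instrument drift, peak
overlap or inter-batch effects, which the generator does not model.

## Problem sizes and numerical choices

The test suite and the acceptance script use: 50 random flux/labeling
draws per preset for the oracle comparison (tolerance 1e−9), 50 replicates
× 20 starts for the recovery study, and exact Mann–Whitney enumeration for
all m, n ≤ 8 against a pairwise-counting brute force.  These sizes were
chosen so the whole pipeline re-verifies in well under a minute per stage
on a single core while keeping the binomial noise of the coverage estimate
within a few percent.  Linear systems use LAPACK solves without explicit
regularization; singular EMU layers raise; the isotopomer oracle errors
out rather than returning an unconverged fixed point; `brentq` bisection
tolerances and the 1e−3 CI endpoint tolerance are stated where they apply.
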