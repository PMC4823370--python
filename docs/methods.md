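# Methods

## Natural-abundance correction of mass isotopomer distributions

A GC-MS isotopologue intensity vector of a derivatized metabolite fragment
mixes the tracer signal with the natural heavy-isotope background of every
atom in the fragment. For a fragment with elemental formula *F* and *n*
tracer-traceable backbone carbons observed over mass shifts 0…K, the
forward model is linear, `y = C x`: column *j* of `C` (shape (K+1)×(n+1))
is the natural isotope pattern of *F* with *j* carbons pinned as ¹³C —
computed as the pattern of *F* minus *j* carbons, shifted down by *j*
rows. Per-element shift distributions are multinomials obtained by
repeated discrete convolution of the single-atom pattern; the fragment
pattern is the convolution across elements.

Isotope abundances (versioned `iupac-2013`): ¹³C 0.0107, ²H 0.000115,
¹⁵N 0.00364, ¹⁷O 0.00038, ¹⁸O 0.00205, ²⁹Si 0.04685, ³⁰Si 0.03092,
³³S 0.0075, ³⁴S 0.0425; P is monoisotopic. Light-isotope abundances are
the complements.

The backbone MID is recovered by **non-negative least squares** rather
than matrix inversion: inversion can return negative fractions on noisy
data, while NNLS keeps the estimate physical; the result is renormalized
to the simplex and the relative residual is kept for QC. K defaults to
n + 3, which captures the Si-driven tail of TBDMS fragments without
requiring the full scan range. All-zero intensity vectors are rejected,
not zero-filled.

Two enrichment conventions are provided because "% of pool enriched with
¹³C" is ambiguous in the field: the **atom-level** fraction
`Σᵢ i·mᵢ / n` (default) and the **labeled-molecule** fraction `1 − m₀`.
For the uniformly-labeled-vs-unlabeled mixtures the study's tracers
produce in practice, the two coincide; they differ for partially labeled
molecules. All recovery checks are run under the atom convention.

Known estimator property: under multiplicative channel noise, the NNLS
non-negativity constraint gives a small *positive* bias on enrichments
that are exactly zero (≈0.3–0.5 % absolute at 5 % CV). An unlabeled
control therefore reads ~0.3 %, not 0, with noisy data; it reads < 1e-8
on clean data. This is documented rather than suppressed.

The shipped fragment library covers the study panel with TBDMS (M−57)
fragment formulas (pyruvate as its methoxime-TBDMS fragment); the
profiling branch of the workflow is TMS-based but carries no isotope
arithmetic, so only the labeling fragments are listed.

## Positional label-propagation simulator

Shift-only bookkeeping cannot express diagnostics that depend on *which*
carbon leaves as CO₂, so each pool holds a full probability distribution
over its `2ⁿ` binary labeling vectors (pools capped at 6 carbons; state
spaces ≤ 64). Reactions are atom maps: every product carbon comes from
exactly one substrate carbon or from an external unlabeled source, and
every substrate carbon is either mapped or explicitly released — label is
conserved by construction and the network validator enforces it.

Key mapping choices (standard biochemistry, required for the diagnostic
patterns):

- PDH releases pyruvate C1; acetyl-CoA = pyruvate C2 (carbonyl) + C3
  (methyl).
- Citrate synthase: acetyl attacks the OAA carbonyl; aconitase
  stereospecificity is encoded by taking the **oxidative IDH CO₂ from the
  OAA-derived central carboxyl** (OAA C1), and α-ketoglutarate
  C1…C5 = OAA C4, OAA C3, OAA C2, acetyl-methyl, acetyl-carbonyl.
- α-ketoglutarate dehydrogenase releases αKG C1 (also OAA-derived), so
  both first-turn CO₂ losses are OAA carboxyls and the acetyl carbons are
  retained into succinate.
- Succinate and fumarate are symmetric: their distributions are averaged
  with the end-to-end carbon reversal at every update (mass-preserving
  positional scrambling).
- Reductive IDH runs the oxidative map backwards with the added carboxyl
  taken unlabeled; pyruvate carboxylase adds unlabeled CO₂ as OAA C4.
- CO₂ and the one-carbon pool are fixed unlabeled (open system, no
  ¹³CO₂ refixation beyond the explicit carboxylation reactions).
- Glutamate ↔ αKG transamination and glutamine ↔ glutamate are
  label-identity maps; aspartate mirrors OAA; serine takes 3-PG C1–C3 and
  glycine takes serine C1–C2 (C3 to the one-carbon pool). PEP → pyruvate
  is modeled in the net (forward) direction only.

Branch-point flux splits are fractions of each pool's production
(glycolytic vs unlabeled pyruvate `g`; glutaminase vs transaminase
glutamate sourcing `q`; PDH-derived vs unlabeled acetyl-CoA; pyruvate
carboxylase vs malate dehydrogenase at OAA; oxidative IDH vs glutamate
anaplerosis at αKG; citrate synthase vs reductive IDH; medium uptake vs
glutamine synthetase at glutamine; 3-PG vs import at serine).

Propagation is deterministic fixed-point iteration (Gauss–Seidel sweeps
in the flux direction). "Repeated cycling" is available both as
steady-state mode (stop when the largest distribution change < 1e-10;
the fixed point is independent of sweep order, which the tests verify by
permuting it) and as a turn limit, where `turns=1` is the first
condensation/cycle turn; the diagnostics that refer to "first turn" use
the turn limit and the "up to M+6" claims use steady state. Under deep
cycling with glucose/PDH-only labeling the simulator reports citrate M+1
exactly zero at every turn — the structural analysis shows no path can
produce it — rather than suppressing small values.

## Media exchange and satellite attribution

Concentrations come from integral tables (CPMG acquisition, phasing and
baseline handling are upstream and out of scope):
`conc = (center+satellites)/TSP · (9/protons) · TSP_conc · 600/550`, the
dilution factor reflecting the 550 µL + 50 µL TSP sample preparation.
Net exchange is `(end − fresh)·volume/protein` (µmol/mg protein;
negative = consumed); metabolites absent from fresh medium (lactate,
alanine, formate, glutamate) are pure release. Release-per-glucose
ratios divide by |glucose exchange| and are flagged undefined when
glucose is not net-consumed. Medium volume is a required configuration
value (default 2 mL/well). Satellite attribution subtracts the
single-site natural ¹³C background (1.07 % at the observed carbon, not a
molecule-wide correction, because the satellites report one position);
both the raw ¹³C fraction and the background-corrected tracer fraction
are reported, since reported "~80 %" source fractions do not state which
convention was used — at 80 % the two differ by < 1 point.

## Profiling normalization and statistics

Profiling intensities are divided by the internal-standard intensity and
protein mass, making the pipeline invariant to per-sample instrument
response. Missing cells are back-filled with half the minimum observed
value of that metabolite (logged and flagged): a behavioral substitute
for re-integration of quantitation ions from raw chromatograms, which
this package does not consume. Group summaries are percent of the
reference line (NSC-34) with delta-method SEM for the ratio of means.

Statistics mirror the study design: one-way ANOVA per metabolite, Tukey
HSD for the three pairwise line contrasts, BH-FDR across metabolites
within one measurement family (pool sizes / enrichments / exchanges).
Whether FDR should wrap the ANOVA p or the Tukey contrasts is ambiguous
in such designs; the default here adjusts the ANOVA p across metabolites
and leaves Tukey contrasts adjusted only within metabolite, and the
report flags this choice. All-equal degenerate groups return F = 0,
p = 1. Note that BH *adjusted* p-values are not a fixed point of
re-adjustment (step-up multiplies by n/rank); the meaningful invariants —
adjusted ≥ raw, order preservation, permutation equivariance, calibrated
type-I error — are what the tests assert.

## Synthetic-data generator

The generator emulates the study design: three lines × two tracers,
n = 4 media replicates (n = 8 for the lactate-release experiment),
n = 5 labeling replicates, n = 6 profiling replicates; 25 mM
[U-¹³C₆]glucose or 1 mM [U-¹³C₅]glutamine, 1 mM unlabeled medium
pyruvate, serum-free, 2 mL/well, ~0.2 mg protein/well. Every configured
truth is a reported group value (annotated in source); absolute
baselines, which the study reports only as percentages, are arbitrary
units. Noise is multiplicative mean-one lognormal — 5 % CV on measured
intensities and exchanges, 10 % on protein, plus a 20 % injected
internal-standard variation that normalization must remove — chosen as
typical instrument repeatability since only SEM bars are reported.
Media noise acts on the exchange before conversion to concentration, so
a 25 mM glucose baseline does not drown the difference measurement.
Glutamine consumption defaults to −4 µmol/mg: the 1 mM × 2 mL well
contains only 2 µmol, which bounds what any line can consume.

True MIDs for the labeling tables are two-component mixtures: an
unlabeled pool plus a uniformly labeled pool whose positions are ¹³C
with the tracer purity (0.99/position, applied in the forward model
only), weighted so the atom-level enrichment equals the configured truth
exactly. The mechanistic simulator is deliberately *not* flux-fitted to
reproduce the printed pool enrichments — that would be full ¹³C-MFA,
out of scope — so the generator's truths are exact by construction and
the simulator supplies patterns, not magnitudes. Consequences for
interpretation: passing recovery tests demonstrates that the correction,
attribution and normalization pipeline is unbiased under this noise
model at the study's replicate numbers; it does not validate the noise
model itself against real instruments, nor flux identifiability.

What the generator does not emulate: chromatographic artifacts
(co-elution, detector saturation), peak-shape/integration error
structure, natural-abundance variation between reagent lots, batch
effects, or biological covariance between metabolites (all noise is
independent across channels and samples).

## Validation scale

Parameter-recovery checks run 200 independently seeded synthetic studies
at the study replicate numbers (seconds per study; about a minute in
total), with exact-arithmetic checks (round-trip identity to 1e-8,
enumeration oracles for ≤ 12-atom fragments, structural zeros in the
simulator) alongside. Recovery is asserted within 3× the mean
per-experiment SEM at the study n — the precision a single experiment of
that size would quote.
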