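# sirmkit

A stable-isotope-resolved metabolomics (SIRM) toolkit for cell-culture
tracer studies, built around the workflow used to characterize central
carbon metabolism in a motor-neuronal ALS model: the NSC-34 cell line and
its transfectants stably expressing wild-type or G93A-mutant human SOD1,
cultured under serum deprivation with [U-¹³C₆]glucose (25 mM) or
[U-¹³C₅]glutamine (1 mM).

It is aimed at researchers analyzing GC-MS isotopologue data and ¹H NMR
media spectra from such experiments, and provides:

- **Natural-abundance correction of mass isotopomer distributions (MIDs).**
  For a derivatized fragment with elemental formula *F* and *n* traceable
  backbone carbons, the observable isotopologue pattern is `y = C x`, where
  column *j* of the correction matrix `C` is the natural heavy-isotope
  pattern of *F* with *j* carbons pinned as ¹³C (²⁹Si/³⁰Si of the TBDMS
  groups dominate the M+1/M+2 background). The backbone MID `x` is
  recovered by non-negative least squares and renormalized to the simplex;
  the ¹³C fractional enrichment is `Σᵢ i·xᵢ / n` (atom convention) or
  `1 − x₀` (labeled-molecule convention).
- **An exact positional ¹³C label-propagation simulator** over an
  atom-mapped glycolysis/TCA/amino-acid network. Each pool carries a full
  distribution over its `2ⁿ` carbon-labeling vectors, so the classic
  pathway diagnostics are exact: citrate M+2→M+6 (never M+1) from glucose
  via pyruvate dehydrogenase, M+4 (never M+3) from glutamine entering
  oxidatively through α-ketoglutarate, M+3/M+5 from pyruvate carboxylase,
  and M+5 from reductive carboxylation of glutamine-derived
  α-ketoglutarate.
- **Media exchange analysis from NMR integrals**: TSP-referenced
  quantification, signed consumption/release in µmol per mg protein,
  per-glucose molar ratios, and ¹³C-satellite source attribution
  (`tracer fraction = (f₁₃ − 0.0107)/(1 − 0.0107)`).
- **Profiling normalization** (internal standard + protein), half-minimum
  back-filling, percent-of-reference summaries with delta-method SEM.
- **Group statistics**: one-way ANOVA, Tukey HSD post hoc contrasts, and
  Benjamini–Hochberg FDR across metabolites within a measurement family.
- **A seeded synthetic-data generator** whose true group values are the
  reported study values, so the whole pipeline can be exercised and
  validated end to end without any deposited raw data.

## Worked example

Generate a synthetic study and analyze it end to end:

```sh
sirmkit synth  --seed 7 --out study
sirmkit report --study study --out report
```

which prints (abridged):

```json
{
  "lactate_release_umol_per_mg": {
    "NSC-34": 9.73, "WT-NSC": 18.21, "G93A-NSC": 26.24
  },
  "glucose_consumption_umol_per_mg": {
    "NSC-34": -28.29, "WT-NSC": -36.11, "G93A-NSC": -40.41
  },
  "lactate_from_glucose_pct": {
    "NSC-34": 80.53, "WT-NSC": 79.81, "G93A-NSC": 79.62
  },
  "pep_enrichment_glucose_pct": {
    "NSC-34": 89.78, "WT-NSC": 89.94, "G93A-NSC": 90.14
  },
  "serine_pool_pct_of_NSC34": {
    "NSC-34": 100.0, "WT-NSC": 262.33, "G93A-NSC": 168.01
  }
}
```

Reading the output: lactate release rises from the untransfected line
through the wild-type transfectant to the mutant (here +44 % G93A vs WT,
near the configured +46 % truth at this seed's n = 8); ~80 % of released
lactate carries tracer carbon under [U-¹³C₆]glucose; ~90 % of the
phosphoenolpyruvate pool is glucose-derived after natural-abundance
correction of the TBDMS fragment spectra; and the serine pool of the
wild-type transfectant sits at ~264 % of the untransfected control.
`report/` also contains the per-sample exchange, source-fraction,
corrected-MID and percent-of-reference tables as CSV.

The simulator is available directly:

```python
from sirmkit import PathwayConfig, build_default_network, propagate, mid_of
state = propagate(build_default_network(), PathwayConfig(tracer="glucose", turns=1))
mid_of(state["citrate"]).fractions   # -> [0, 0, 1, 0, 0, 0, 0]: pure M+2
```

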