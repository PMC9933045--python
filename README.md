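# tandemid

Tandem mass-isotopologue analysis for ¹³C/¹⁵N stable-isotope tracer
metabolomics.

When cells are cultured on D-¹³C₆-glucose or L-¹⁵N₂-glutamine, the mass
isotopologue distribution (MID) of each downstream metabolite — the vector
of fractions M₀..Mₙ over mass shifts — records how much of its pool was
newly synthesised from the labeled substrate. MS² adds a second dimension:
a fragment retains a known subset of the precursor's tracer atoms, so the
joint (precursor shift, fragment shift) distribution — the *tandem MID* —
separates positional isotopomers that are indistinguishable at the intact
level. `tandemid` implements the full desk-side analysis for this kind of
experiment, built around the glutathione de novo synthesis network
(glucose → glutamate / serine / glycine → GSH → GSSG) in healthy versus
rotenone-stressed mid-brain neurons:

- **Correction** — natural-abundance and tracer-purity correction of
  precursor and fragment isotopologue peak areas. The forward model is
  column-stochastic and exact (column *j* is the convolution
  Binom(*j*, purity) ⊛ Binom(*n−j*, abundance)); inversion is non-negative
  least squares with renormalisation, so noise never produces negative
  fractions.
- **Enrichment** — mean isotopic enrichment ME = Σᵢ Mᵢ·i/n, labeled
  fractions 1−M₀, and atom-weighted moiety enrichment
  ME = Σ_f ME_f·n_f / Σ_f n_f for fragments that tile the molecule (e.g.
  glutathione's glutamate moiety F1 and glycine–cysteine moiety F2).
- **Tandem deconvolution** — positional-isotopomer weights at a given
  precursor shift, solved jointly over all declared fragments by
  min ‖A·w − b‖² s.t. w ≥ 0, Σw = 1, with an honest identifiability flag
  when fragments cannot separate the candidates. The canonical case: the
  m+1/m+2 ratio of the glutamate c2–c5 fragment splits M+2 glutamate into
  its 1,2-¹³C₂ (pyruvate-dehydrogenase route) and 3,4-¹³C₂
  (pyruvate-carboxylase route) isotopomers.
- **Pathway report** — protein-normalised ¹²C/¹³C (or ¹⁴N/¹⁵N) channel
  pools, GSH/GSSG ratios, combined labeled fractions of GSH+GSSG, and
  per-metabolite enrichment summaries with two-sided Welch tests at
  p < 0.05.
- **Synthetic data** — a seeded forward simulator of the whole study
  (ground-truth isotopomer distributions, natural-abundance/purity
  convolution, lognormal peak noise, per-sample protein content), so every
  estimator is testable by parameter recovery.

## Worked example

Simulate the two-group study (five replicates per group plus unlabeled
controls) and run the full pipeline:

```bash
tandemid simulate --seed 1 --out sim
tandemid run --peaks sim/peaks.csv --metadata sim/metadata.csv --out results
```

`results/enrichment_summary.csv` then contains (abridged):

```
   metabolite  me_mean_healthy  me_mean_rotenone  p_value  significant  no_incorporation
          GSH         0.204521          0.091535 0.000001         True             False
    glutamate         0.591735          0.394960 0.000062         True             False
      glycine         0.075031          0.058544 0.009881         True             False
     cysteine         0.000553          0.000680 0.814083        False              True
```

Glutamate is ~59% ¹³C-enriched in the healthy group and GSH ~20% — the
glutathione pool is roughly two-thirds newly synthesised from labeled
glutamate — while cysteine shows no incorporation (it is supplied from the
medium, not made from glucose). Rotenone cuts both enrichments roughly in
half, and the drop is significant.

`results/tandem_report.csv` resolves the glutamate M+2 isotopologue into
its positional isotopomers per sample:

```
   sample   group metabolite  precursor_shift isotopomer  fraction  identifiable
healthy_1 healthy  glutamate                2      c1+c2  0.154890          True
healthy_1 healthy  glutamate                2      c3+c4  0.071554          True
```

i.e. ~68% of the M+2 pool entered the TCA cycle via pyruvate
dehydrogenase and ~32% via pyruvate carboxylase in this sample.
`results/ratios.csv` gives per-channel GSH/GSSG area ratios (healthy
labeled-channel mean 6.4, rotenone 1.7 — the oxidative-stress signature).

The same works from Python:

```python
from tandemid import default_config, generate_study, correct_study, recover_group_parameters

config = default_config("C")
study, truth = generate_study(seed=1, config=config)
corrected = correct_study(study, config)
print(recover_group_parameters(corrected, config, "healthy"))
# {'phi': 0.698..., 'f_syn': 0.653..., 'glutamate_me': 0.591..., 'gsh_me': 0.204...}
```

Input formats, the YAML chemistry-config schema and all defaults are
documented in the module docstrings and in `docs/methods.md`.

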