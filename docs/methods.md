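# Methods

## The measurement model and its correction

A metabolite with *n* tracer-element atoms (e.g. 5 carbons in glutamate, 10
in glutathione, 20 in GSSG) has a true tracer-labeling distribution
x = (x₀..xₙ): the fraction of molecules with exactly *j* nominally labeled
atoms. What the instrument integrates is distorted by two independent,
per-atom binomial processes:

- every *unlabeled* tracer position is heavy with the natural-abundance
  probability *a* (defaults: ¹³C 0.0107, ¹⁵N 0.00364; overridable);
- every *nominally labeled* position is heavy only with the tracer's
  isotopic purity *p* (0.99 for ¹³C₆-glucose, 0.98 for ¹⁵N₂-glutamine).

The expected observed MID is m = F·x with column
F[:, j] = Binom(j, p) ⊛ Binom(n−j, a). This construction is exact — it
agrees with enumeration of all 2ⁿ atom states to machine precision — and
deliberately *not* the product of the separate natural-abundance and purity
matrices: composing those as plain matrices would let an atom that failed
labeling (probability 1−p) pick up natural abundance a second time, an
O(a·(1−p)) ≈ 10⁻⁴ error that is invisible in noisy data but fails exact
round-trip checks. The single-effect builders are still exposed for
inspection and export.

Two resolution modes exist. The default, `high_resolution_tracer_only`,
assumes the mass analyzer resolves tracer-element isotopologues from
isobaric contributions of other elements — appropriate for TOF-class
instruments. `low_resolution_full_formula` additionally convolves the
nominal-mass isotope patterns of all non-tracer atoms of the molecular
formula (H, N, O, S, P tables built in); the convolution is truncated at
shift *n* and each column renormalised so the matrix stays
column-stochastic, which slightly redistributes the (tiny) probability mass
beyond shift *n* rather than dropping it.

Inversion solves min‖F·x − m‖² with x ≥ 0 (scipy NNLS) and renormalises to
Σx = 1. Raw matrix inversion is never used: under noise it produces
negative fractions. Negative measured areas (baseline-subtraction
artifacts) are clamped to zero with a logged warning; a relative residual
above 5% (configurable) sets a warning flag on the result rather than
raising, since real co-elution artifacts should be surfaced, not fatal.

Fragment spectra are corrected independently of the Q1 precursor selection,
using a matrix built from the fragment's own tracer-atom count (and
fragment formula in low-resolution mode). An exact precursor-conditioned
fragment correction would need the joint atom-level model; the independence
approximation is the package's chosen forward and inverse model, so
noise-free simulations invert exactly, and the approximation is consistent
across simulation and analysis.

## Enrichment

Mean enrichment ME = Σ_{i=1..n} Mᵢ·i/n is the expected fraction of labeled
tracer atoms per molecule; it is scale-invariant in the raw areas and
monotone under moving isotopologue mass upward. The labeled fraction is
1 − M₀. For fragments declared as a partition of the parent's tracer atoms
(glutathione F1 = glutamate moiety, F2 = glycine–cysteine moiety; 5 + 5
carbons, or 1 + 2 nitrogens), the atom-weighted moiety enrichment
Σ_f ME_f·n_f / Σ_f n_f equals the intact enrichment whenever fragments and
precursor sample the same molecule population — an identity the test suite
checks exactly on noise-free truth and within noise after the full
pipeline. Report tables print enrichment as integer percent using floor
(21.5% prints as 21); `enrichment_percent(..., rule="round")` switches to
rounding. Whether published integer enrichments are floored or rounded is
generally not stated; floor reproduces the canonical 39%/4% → 21% moiety
example self-consistently.

## Tandem deconvolution

For precursor shift *j* with candidate positional isotopomers s₁..s_m, each
fragment *f* predicts a deterministic shift |s ∩ atoms(f)|. The stacked
indicator system A·w = b (rows: fragment × fragment-shift; b: observed
corrected conditional fragment MIDs) is solved on the weight simplex by
NNLS with a strongly weighted (10⁴) equality row for Σw = 1, then
renormalised; with consistent noise-free data this is exact to ~10⁻¹⁵.
Identifiability is reported as rank([A; 1ᵀ]) ≥ m; rank deficiency (e.g.
exhaustive C(n, j) candidate enumeration, or two candidates with identical
predicted shifts in every declared fragment) never raises — weights are
still returned, flagged non-unique. Candidates default to declared
biochemical sets: for glutamate M+2 the two first-turn TCA entries, 1,2-¹³C₂
via pyruvate dehydrogenase and 3,4-¹³C₂ via pyruvate carboxylase. The c4–c5
fragment adds the structural constraint that neither candidate can produce
an m+2 fragment peak; observed mass there shows up as solver residual.

## Group analytics

Channel pools split a metabolite's protein-normalised area into an
unlabeled pool M₀·area and a labeled pool (1−M₀)·area — the pre-existing
versus de-novo-synthesised material after correction. GSH/GSSG ratios are
taken within the same channel; a zero denominator yields a missing value,
never infinity. The combined labeled fraction of GSH+GSSG weights each
metabolite's 1−M₀ by its corrected area. Group differences use a two-sided
Welch (unequal-variance) t-test at α = 0.05 with no multiple-testing
adjustment by default, mirroring per-panel significance marks at n = 5
replicates; `enrichment_summary(..., adjust="bh")` enables
Benjamini–Hochberg. Zero-variance identical groups map the undefined t
statistic to p = 1 (no evidence of difference). Metabolites whose pooled
labeled-group mean ME is below 1% are flagged "no incorporation" — the
expected behaviour of cysteine under either tracer and of glycine under
¹⁵N. The de novo synthesis fraction of GSH is estimated as the ratio of its
glutamate-moiety enrichment to free-glutamate enrichment,
f̂_syn = ME_F1 / ME_glu.

## The synthetic study

The simulator emulates a two-group neuron tracing experiment: a healthy
group and a rotenone-like (complex-I-inhibited) group, five replicates
each, plus one unlabeled control culture per group. Ground truth is defined
at positional-isotopomer level:

- **Glutamate** (and ketoglutarate): mass at M+0, M+2 and M+5. The M+2 mass
  splits φ : (1−φ) between the 1,2- and 3,4-labeled first-turn isotopomers
  (healthy φ = 0.70, PDH-dominant). The M+5 component represents molecules
  assembled entirely from labeled carbon at isotopic steady state — with
  only first-turn M+2 species the mean enrichment could never exceed 2/5,
  whereas observed glutamate enrichments in glucose-traced neurons reach
  ~60%; the healthy default (M+2 = 0.25, M+5 = 0.50) gives ME = 0.60
  exactly. Multi-turn positional scrambling is deliberately not modelled:
  candidate isotopomer sets are first-turn.
- **Serine** M+3 fraction 0.11, **glycine** M+2 fraction 0.07 (de novo
  serine pathway); **cysteine** always unlabeled (medium-supplied).
- **GSH**: a fraction f_syn (healthy 0.67) is de novo — its glutamate
  moiety samples the free-glutamate distribution and its glycine moiety the
  free-glycine distribution, cysteine moiety unlabeled — and the rest is
  pre-existing, unlabeled. f_syn = 0.67 reproduces intact GSH ME ≈ 0.21 and
  an F1 moiety enrichment ≈ 0.40; the implied F2 enrichment is ≈ 2%,
  slightly below typical observed values (~4%), a tension inherent in
  combining a 7% glycine enrichment with these pool sizes.
- **GSSG** is the glutathione disulfide dimer: its MID is the
  self-convolution of the GSH MID (20 C / 6 N). The oxidized share (healthy
  1/6, rotenone 0.40) sets pool sizes so the healthy total-area GSH/GSSG
  ratio is ~10 and the rotenone one well below it.
- **¹⁵N mode**: glutamate-N labeled at 0.23, serine at 0.05, glycine and
  cysteine unlabeled; only the glutamate-moiety nitrogen of de novo GSH is
  labeled, giving GSH/GSSG ¹⁵N enrichment ≈ 5%.

The rotenone preset lowers glutamate labeling (ME ≈ 0.39), φ (0.55), f_syn
(0.45) and the glutathione pool, and raises the oxidized share — reduced
TCA entry, reduced de novo synthesis, oxidative stress.

Measurement: true MIDs (and true per-precursor-shift fragment conditionals)
pass through the forward correction matrices, are scaled by per-metabolite
base abundance × per-sample protein content (normal, mean 38 µg, CV 0.10,
truncated at zero), and multiplied by lognormal noise with CV 0.10 per
integrated peak (multiplicative, since peak-area noise scales with signal).
Everything derives from one `numpy` generator seed; identical seeds give
bit-identical tables.

What the simulator does *not* emulate — and what passing recovery tests
therefore do not establish about real data: chromatographic or spectral
interference, co-elution, detector saturation, multi-turn TCA isotopomer
scrambling, non-stationary labeling kinetics (isotopic steady state is
assumed), and any difference in ionisation response between GSH and GSSG
(area ratios are treated as pool ratios).

## Numerical and design choices

- Tolerances: MID vectors must sum to 1 within 1e-9; correction matrices
  are column-stochastic within 1e-12; the simplex-equality weight in the
  tandem solver is 1e4.
- Deterministic ordering everywhere: isotopomer enumeration is
  lexicographic; report rows follow declaration order.
- Problem sizes in the test and acceptance runs — 1000 round-trip vectors
  per tracer-atom count, 20 simulated studies for noise-level parameter
  recovery, 1000 Monte-Carlo resamples for the significance-flag
  calibration — were chosen to bound the relevant Monte-Carlo standard
  errors well below the tolerances being asserted while keeping a full run
  in the tens of seconds.
- Atom labels (c1..cn, gc1..gc10, gn1..gn3) are declared positional names,
  not assertions about IUPAC numbering; the config carries them verbatim
  and fragments refer to them.
- The pipeline's stages are pure functions over the study table; the CLI
  (`simulate`, `correct`, `enrich`, `tandem`, `report`, `run`) is a thin
  layer over them, and reruns on identical inputs are byte-identical.

## Known limitations

- Fragment conditional MIDs are corrected under the precursor-independence
  approximation described above; for very high natural-abundance elements
  or low-purity tracers a joint correction would differ measurably.
- High-resolution mode ignores isobaric fine structure (¹⁸O, ³⁴S) entirely;
  low-resolution mode handles it only at nominal-mass granularity.
- GSSG positional isotopomers are not tracked (only its MID, as the GSH
  self-convolution); tandem deconvolution of GSSG fragments is therefore
  out of scope.
- The Welch test with n = 5 per group has limited power; the significance
  flags are calibrated for type-I error, not power.
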