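# Methods

This note records the modelling choices, defaults and known limitations of
`splicebalance`, in the order data flows through the package.

## Synthetic assay generator

The generator emulates a massively parallel splicing reporter assay with a
known additive ground truth, so that preprocessing, training and
interpretation can all be validated by parameter recovery.

**Windows.** Each reporter is a uniform-random 70-nt exon flanked by the
fixed decanucleotides `GGCGUGGAUG` / `GACGGCAUGG` (arbitrary fixed context,
chosen once; they contain none of the default rule's motifs), giving the
90-nt model window.

**Ground-truth rule.** The default rule plants
- three inclusion 6-mers — `GAAGAA` (strength 2.0, uniform position
  profile), `CACACG` (1.6, 5'→3' ramp 0.5→1.5), `UCCUCA` (1.2, mid-exon
  peak) — loosely modelled on purine-rich enhancer-like elements;
- three skipping 6-mers — `UAGGGU` (2.0, uniform), `CUCUCU` (1.6, ramp),
  `ACUAAC` (1.2, peak) — loosely modelled on hnRNP/PTB-like and
  branch-point-like elements;
- a stem-loop feature: every helix of 5–7 stacked pairs contributes 2.5
  strength units to skipping;
- a G-poor feature: an exon with any 30-nt window containing ≤ 2 G's
  contributes 2.0 units to skipping, once.

Strengths are in the link's arbitrary units.  The true Δ strength of an
exon is obtained by scanning its final sequence/structure (so chance
occurrences of a motif count exactly like planted ones), and
`PSI_true = σ(ν·Δ + η)` with ν = 1, η = 0.  Per-exon planting
probabilities are 0.08 per motif, 0.15 for a stem, 0.10 for a G-poor
stretch — roughly five-fold enriched over the chance occurrence rate of a
6-mer in a random 70-mer, chosen once so that about half the exons carry
at least one feature while featureless exons (PSI ≈ 0.5) remain the mode,
as in a weak-splice-site reporter.

**Read noise.** `n_inclusion ~ Binomial(depth, PSI_true)` with the
remainder skipping; a Poisson number of "other" outcome reads (intron
retention etc.) at 2% of depth exercises the preprocessing filters.  The
real assay's PCR/sequencing error processes are *not* modelled, so passing
recovery tests shows correctness of the pipeline under binomial noise,
not robustness to library artifacts.

**Structure annotation.** By default the dot-bracket string marks exactly
the planted stem pairs ("planted" mode), so the structure channel and the
truth sidecar agree.  A Nussinov-style maximum-pairing folder (min hairpin
loop 3, 5'-most tie-breaking) is included and tested for synthetic use
(`structure_mode="fold"`), but maximum pairing on a random 90-mer pairs
far more bases than an energy-based folder would; no parity with
thermodynamic folding is claimed, and real-data use expects externally
predicted structures as input.

## Preprocessing

Implements the published filter chain: barcode→exon resolution (exon
variants seen with a single DNA read under a barcode are discarded as
sequencing errors; ambiguous barcodes dropped; barcodes with < 2 DNA reads
dropped), replicate merging by category-wise summation, then retention of
barcodes with ≥ 60 total reads, no Esp3I/BsmBI site (`CGTCTC`, either
strand, exon or barcode) and inclusion+skipping ≥ 80% of reads.  The
60-read threshold is applied to the total across *all* outcome
categories.  Coordinates are 0-based half-open; the variable exon occupies
[10, 80) of the window; DNA input is normalised T→U.  The 80/20
train/test split uses a seeded permutation with |train| =
round-half-away-from-zero(0.8·N).

## Model

Architecture as in the README.  Conventions fixed here:
- convolution is cross-correlation (no kernel flip), valid mode; position
  index = 0-based window start;
- channel orders: sequence (A, C, G, U); structure ('(', '.', ')');
  structure-SCM input [seq(4), struct(3), wobble(1)];
- the basal strength B is an explicit learnable scalar added to Δ before
  the tuner (not folded into the tuner bias), so balance plots can show a
  B bar and cross-assay correction can adjust it;
- the full tuner's hidden widths default to (10, 10) with tanh
  nonlinearities; its monotonicity is not enforced, only audited post hoc
  over the observed Δ range.

## Training

Mean Bernoulli KL (measured‖predicted, predictions clipped to
[1e−6, 1−1e−6]) plus `λ_act · (mean per-record ℓ1 of post-softplus
strengths)` and `λ_smooth · Σ‖Δβ‖²` (first differences along the position
axis).  Defaults: λ_act = 1e−3, λ_smooth = 1e−3, Adam, learning rate
1e−2, batch 128, epochs 150/100/20 per stage; the learning rate is held
for 70% of a stage then decayed exponentially to 10%.  Stage 2
warm-starts the sequence SCMs; stage 3 initialises the full tuner to
reproduce Tuner′ exactly (zero output weights, residual = ν, bias = η),
so stage-3 predictions are initially identical to stage 2's.

Three scheduling devices, all engineering responses to observed
optimisation pathologies of softplus-sum motif models, are on by default
and documented here because they matter for reproduction:

1. **k-mer-seeded kernels.**  Sequence kernels initialise to the one-hot
   pattern of a uniformly random 6-mer (weight 1.0) plus N(0, 0.1) noise,
   with position bias starting at −3.  Diffuse Gaussian kernels first
   learn mononucleotide composition (softplus near 0 is locally linear,
   and a linear SCM can only see composition), smear motifs over several
   alignments, and often lock into a register shifted by one base —
   sharp random kernels instead refine by single-base moves.
2. **Per-record filter dropout (p = 0.1).**  A filter on one side whose
   spurious matches are cancelled by a twin filter on the other side is a
   stable local optimum; random silencing of filters per record makes
   such co-adapted pairs costly and prunes them.
3. **Shift-refinement moves.**  Every 10 epochs in the second half of a
   stage, each sequence filter's kernel is tested translated by ±1–2
   positions (vacated rows filled with each candidate base at the
   kernel's typical weight; position bias counter-shifted; a scalar bias
   offset re-calibrated per candidate), and a translation that clearly
   lowers the subsampled training KL (by > 0.2%) is adopted.  This is a
   discrete local search across the translation degeneracy that gradient
   descent cannot cross; it is what makes self-overlapping motifs (G-runs,
   CA-repeats) land on their exact register.

Determinism: single-threaded training from a fixed seed is exactly
reproducible; multi-threaded BLAS may differ in the last bits.

**Hyperparameter selection** follows the two-criterion scheme: grid
points (λ_act, λ_smooth) are evaluated by held-out KL and by sparsity —
the mean minimum number of activations per exon whose truncated Δ
achieves KL below a threshold (default 0.05 nats; activations re-added
greedily in decreasing magnitude, starting from B alone) — and among
points meeting both cutoffs the largest λ_smooth wins (ties: larger
λ_act, then grid order), falling back with a warning to the best-KL point.

## Interpretation

- **Balance plots** sum each filter's strength map over positions; the
  signed bar sum (B included) reproduces Δ exactly, to floating-point.
- **Filter clustering** uses correlation distance between per-exon
  total-strength vectors, average linkage, threshold 0.3; near-constant
  vectors become singletons; config allows manual merging (e.g. stem
  variants differing only in loop length).  The strongest member
  represents each cluster.
- **Logos**: for 6-wide sequence filters, all 4096 6-mers are scored and
  the position-frequency matrix of those with positive best
  position-adjusted pre-activation (max over positions of z + β > 0) is
  reported — "positive activation" must be defined pre-softplus, since
  post-softplus strengths are always positive.  For 30-wide filters,
  enumeration is intractable, so an enrichment/depletion log-ratio matrix
  compares the top-scoring dataset windows with background.
- **Per-nucleotide relevance** redistributes each window's post-softplus
  strength onto the window's positions proportionally to
  |x·α| (ε-stabilised, ε = 1e−6).  This magnitude-proportional rule
  conserves the filter total exactly and is stable when the raw strength
  z crosses zero, where a signed z-proportional rule would explode; the
  price is that inhibitory evidence appears with positive weight.
- **Mutant design**: stem mode requires exactly one helix in the record,
  mutates a mid-stem pair (each arm separately, then both
  compensatorily), refolds with a supplied folder (toy folder by
  default) and re-scores; G-poor mode makes one C→G substitution at the
  centre of the most-activating window.  Proposals changing any other
  filter by more than 10% of the target filter's change (configurable)
  are marked rejected.  Substitutions only.
- **Artifact rule-out**: feature-positive vs feature-negative groups are
  compared by one-sided Mann-Whitney U tests on raw inclusion and
  skipping counts; "bona fide" = inclusion down *and* skipping up,
  "artifact-like" = inclusion down with skipping unchanged; groups under
  10 records are inconclusive.

## Cross-assay adaptation

Position-bias columns are resampled to a new window length with a
normalised Lanczos kernel (a = 3) under proportional endpoint-to-endpoint
position mapping, edge-clamped; resampling is exact at the native length
and reproduces constants at any length.  The per-assay basal correction
ΔB is fitted by bounded golden-section search (interval ±10, tolerance
1e−4) on mean KL with all other parameters frozen, and is never accepted
if worse than ΔB = 0.  External assays must supply their own dot-bracket
structures; the package does not fold real data.

## Problem sizes

The package's recovery benchmark trains stages 1–2 with 8 filters/SCM on
20,000 exons at depth 200 (≈ 10 minutes on one CPU); the acceptance
script runs a 6,000-exon twin of the same pipeline so a full
reproduction stays in a coffee break.  The interpretation conservation
laws are exercised on hundreds of random exons; numeric oracles on
hundreds of random small instances.

## Known limitations

- The generator's distributional choices (binomial reads, planting rates,
  piecewise-linear profiles) are stand-ins for testing, not claims about
  any real assay.
- Recovery of *planted* rules under binomial noise does not demonstrate
  discovery power on genomic data, where features overlap protein-coding
  and other constraints.
- The toy folder maximises pairings and will over-pair long random
  sequences; real-data workflows should supply structures from an
  energy-based predictor.
- Training is CPU NumPy; it is deliberately sized for desk-scale data
  (tens of thousands of records), not for datasets orders of magnitude
  larger.
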