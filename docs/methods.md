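# Methods

`trfstress` analyses serum small-RNA cohorts in which transfer-RNA fragments
(tRFs) are the unit of interest and the scientific question is whether *tRF
families* — fragments sharing genome origin (nuclear vs mitochondrial),
parental tRNA amino acid, and cleavage type — shift coherently between a
stress and a control group. This note describes the models and procedures,
the choices made where the design was open, and what the synthetic cohorts
do and do not establish.

## Family keying

A fragment's family is the triple (origin, amino acid, cleavage type); the
five cleavage types are 5′-tRF, 5′-half, i-tRF, 3′-half and 3′-tRF, ordered
5′→3′. Families are totally ordered (origin, then amino acid
alphabetically, then cleavage type) so all outputs are deterministic.
Fragment length is always taken from the sequence or an explicit length
column — never from the coordinates inside a tDR-style name, which use
structural (Sprinzl-like) numbering and can disagree with the physical
length by a nucleotide or more. Fragments whose parental tRNAs disagree on
origin or amino acid are assigned by the annotation table's primary record
with a logged warning. The minimum family size for trend testing defaults
to 2: a sign test over one member carries no information. Smaller families
are retained in all reports, flagged untestable.

## Differential expression (simplified NB Wald)

The DE stage exists to supply signs and significance to the family trend
test; it is deliberately a simplified negative-binomial Wald test rather
than a faithful DESeq2 reimplementation, and the pipeline accepts an
externally produced DE table (e.g. a DESeq2 export) in the same schema for
real-data runs.

* **Prefilter** — keep features with count ≥ 10 in at least
  `smallest_group_size` samples (default 6, the smallest study group).
* **Normalization** — median-of-ratios size factors over features positive
  in every sample. Note the estimator acquires a small (≈2%) skewness bias
  at serum-level dispersions, and when a large fraction of the
  transcriptome moves in one direction (as in the mitochondrial-decline
  condition) the compositional shift makes unchanged features drift
  slightly in the opposite direction. This is a property of count-based
  normalization generally, not of this implementation, and it is visible in
  the synthetic runs as weak apparent "up" trends in unplanted families.
* **Dispersion** — per-feature method-of-moments from within-group pooled
  variances of normalized counts (shot noise `mu * mean(1/s)` subtracted),
  clipped to [1e-8, 10], then shrunk on the log scale halfway toward a
  robustly reweighted parametric trend `phi(mu) = a0 + a1/mu`. The 0.5
  shrinkage weight trades stability at n≈10–20 per group against bias;
  type-I calibration at the study design is checked empirically (null
  p ≤ 0.05 fraction ≈ 5–6%).
* **GLM** — with a two-level group factor, intercept and effect decouple
  into one log-mean per group; each is fit by vectorized Fisher scoring of
  the NB score equation with size-factor offsets. A group with all-zero
  counts gets a moderated estimate (0.5 pseudo-total), is flagged, and its
  p-value is set to NA and excluded from the FDR.
* **Wald test** — z = Δlog-mean / SE with SE from the per-group Fisher
  information; BH FDR within each contrast independently. Contrasts are
  stress vs control combined and within each sex; the combined fit does not
  include sex as a covariate (separate per-sex fits serve that purpose).

Because the likelihood sees raw counts, log2FC estimates are only
asymptotically invariant to rescaling one sample's library (the size factor
absorbs the rescaling exactly; the MLE shifts by a few hundredths of a
log2 unit at n = 35).

## Family trend test

For each family, `n` counts members with a finite nonzero log2 fold change
and `k_down` those with a negative one; zero or undefined fold changes are
dropped (a sign test cannot orient them). The test is the exact binomial
against p = 1/2, two-sided by the central method
`min(1, 2·min(P(X≤k), P(X≥k)))` — under the symmetric null this equals the
minimum-likelihood method and is trivially oracle-testable. One-sided
variants are available by configuration. BH FDR runs across testable
families within a contrast; a family is called *down* (or *up*) when
FDR ≤ 0.05 and more (or less) than half its members fell. Members are
treated as independent; intra-family correlation is not modelled, so the
binomial p-values are optimistic exactly as in any sign-test reading of
correlated fold changes.

Super-family trends (all-MT vs all-Nuc, per cleavage type, per amino acid)
reuse the same machinery over a coarsened key.

## Length analysis

Per group, the mean over samples of total normalized expression at each
length 16–50 nt, plus the fraction of signal inside the 16–28 nt miR-length
window. For the group comparison each family × sample is summarized as the
expression-weighted mean member length (weights are size-factor-normalized
counts — the weighting is a documented choice, as is any per-sample
summary feeding a rank test), and a tie-corrected Kruskal–Wallis test runs
across the four stress-by-sex groups with BH FDR across families. All
values tied yields H = 0, p = 1 rather than an error.

## Cholinergic scoring

Candidate RNAs are 17–28 nt long; predictions qualify at score ≥ 80 after
collapsing duplicate RNA–gene pairs to their maximum score (collapse first,
then filter — the order is a documented choice). The cholinergic score sums
gene weights over qualifying targets: core genes weigh 5, peripheral 1. An
RNA is designated cholinergic (CholinotRF / CholinomiR) when it targets at
least one core gene or at least five peripheral genes. The score is
additive and the designation monotone: adding a qualifying target never
revokes it. The weighted 102-gene list is a runtime input;
`data/example_cholinergic_genes.csv` ships a small illustrative list marked
non-authoritative. Enrichment uses scipy's two-sided Fisher exact test
(odds ratio reported as the sample OR with a Haldane 0.5 correction when a
cell is zero; a zero margin gives p = 1 and an undefined OR) and the
upper-tail hypergeometric for overall target enrichment.

## Classification

Features are log2(normalized count + 1); standardization happens inside
cross-validation on training folds only. The classifier is an SVM with an
RBF kernel whose width is the median pairwise training distance (linear
kernel by configuration), C = 1, no inner hyperparameter tuning (nested
tuning is unstable at 17–35 samples). Out-of-fold decision scores from
leave-one-out CV are pooled into a single ROC; AUC uses the rank
(Mann–Whitney) formulation with half credit for ties, and threshold metrics
are evaluated at decision score 0.

Two small-sample subtleties drove design choices:

* **Fold-imbalance correction.** Every LOOCV training fold has one fewer
  sample of the held-out class. Without correction the SVM intercept tracks
  that imbalance and out-of-fold scores of uninformative data collapse to
  an *anti-learning* AUC near 0. `class_weight='balanced'` (the default)
  compensates; it slightly overcorrects, leaving a mild optimistic drift
  (pure-noise mean AUC ≈ 0.57 rather than 0.50).
* **Permutation calibration.** Significance comes from class-size-
  preserving label permutations with the add-one estimate
  p = (1 + #{AUC_perm ≥ AUC_obs}) / (1 + B), BH-corrected across marker
  sets. Because labels enter neither standardization nor the kernel, the
  per-fold Gram matrices are precomputed once and reused for every
  permutation — an exact speedup that makes the 10,000-permutation default
  feasible (B = 199–999 is used in desk-scale runs). The permutation null
  absorbs the balanced-weight drift (and any marker-selection optimism
  shared by the permuted datasets), which is why the permutation p, not the
  raw AUC, is the reported evidence. Under the null the p-values are
  approximately uniform; for degenerate inputs (e.g. duplicated points with
  contradictory labels) the raw AUC is tie-break-driven and only the
  permutation p is meaningful.

## Cholinesterase kinetics

Activities come from Ellman-assay traces: 21 one-minute absorbance readings
(436 nm) per sample under three conditions — uninhibited (total ChE),
iso-OMPA (BChE inhibited → AChE activity), BW284c51 (AChE inhibited → BChE
activity). The catalytic rate is the OLS slope over the full window by
default (a sub-window is configurable), in mOD/min scaled by the dilution
factor (default 1:20 for plate data; the generator emits dilution 1 so its
rate parameters are on the output scale). A constant trace has rate 0 with
R² = 1 by the zero-residual convention. Negative rates are reported and
flagged, not clipped — blank-corrected slopes can dip below zero under
noise. No blank subtraction is applied by default (an optional per-plate
blank input exists); unit conversion to nmol/min/mL requires a
user-supplied extinction coefficient.

The additivity diagnostic |total − (AChE + BChE)| / total is reported per
sample. Outlier removal uses the 1.5·IQR fences with quartiles by linear
interpolation between order statistics (so {2, 4, 6, 8, 100} → Q1 = 4,
Q3 = 8, upper fence 14, dropping 100). Group comparisons are two-sided
Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired dyads), exact for
small tie-free samples, with BH FDR over comparison batches. Dyad ratios
(newborn/mother) require both rates positive; ratios are tested against 1
by signed-rank on the log scale. tRF–activity association uses Spearman
correlation with BH FDR across tested pairs.

## Synthetic cohorts

The generator reproduces the study conditions so every stage is testable
without the original sequencing data:

* **Design** — four newborn stress-by-sex groups of 6 (F-stress),
  8 (M-stress), 11 (F-control), 10 (M-control); perceived-stress scores
  drawn as integers ≤ 10 for controls and ≥ 19 for the stress group (only
  the group label is used downstream). A mother cohort with its own
  catalog-overlap parameter is available.
* **Catalog** — 45 families totalling 565 fragments by default, drawn from
  distinct family keys with ~40% mitochondrial share; lengths are normal
  around cleavage-type peaks (5′-tRF 18.5, i-tRF 23.5, 3′-tRF 31.5, halves
  34–36 nt) plus a small family-specific offset, clipped to 16–50 nt.
* **Counts** — negative binomial with a log-uniform mean grid (5–500),
  dispersion phi(mu) = 0.1 + 1/mu (decreasing with mean, typical of serum
  small-RNA data), and log-normal library-size factors (sigma = 0.3).
  Planted effects are per-family: each member's true log2FC is negative
  with probability `fraction_down`, applied in stress samples of the
  affected subgroup (all/females/males). The truth table (per-contrast
  true log2FC, base means, true size factors) is emitted so recovery tests
  consume only generator outputs.
* **Predictions** — gene universe of 2,000; a 102-gene cholinergic list
  (15 core, 87 peripheral); planted cholinergic fragments (10% of
  length-eligible ones, with 4:1 odds toward MT origin, mirroring the MT
  enrichment of cholinergic-targeting fragments) receive a core-gene target
  at score ≥ 80, while unplanted fragments draw targets outside the
  cholinergic list so rule recovery is exact by construction.
* **Kinetics** — three 21-point linear traces per sample with additive
  Gaussian noise and non-negative absorbance; condition slopes are
  AChE+BChE, AChE, and BChE.

What the synthetic data does *not* emulate: sequence-level realism,
intra-family expression correlation (members are conditionally independent
given the planted sign), batch or plate effects, zero inflation beyond the
NB, and realistic target-prediction score structure (background predictions
avoid cholinergic genes by construction, so the overall target-enrichment
p-value is uninformative on synthetic bundles). Passing tests therefore
establish correctness and calibration of the *procedures*, not effect sizes
in real serum data.

## Problem sizes and determinism

Simulation studies use deliberately modest replicate counts chosen as a
reasonable desk-scale compromise: 100–200 cohorts for null FDR control,
40–50 for power, 5,000–6,000 features for DE calibration, B = 199–999
permutations with 50–200 datasets for classifier calibration. Every
generator and every pipeline stage is a pure function of (parameters,
seed); rerunning `simulate` + `run` with one seed reproduces result files
byte for byte. Floating-point output is written at 10 significant digits.

## Known limitations

* The binomial trend test inherits the independence assumption discussed
  above; its extremely small p-values on large coherent families should be
  read as strong ordering evidence, not literal error probabilities.
* The simplified NB Wald stage is mildly anti-conservative (null
  p ≤ 0.05 ≈ 5–6% at n = 12 vs 12) and is not a DESeq2 replacement; import
  a DESeq2 table for publication-grade per-feature inference.
* Compositional normalization bias (above) can paint unchanged families
  with weak opposite-direction trends when a large transcriptome fraction
  truly moves; interpret family directions jointly with the global picture.
* The classifier's raw AUC is optimistic at these sample sizes; only the
  permutation-calibrated significance should be interpreted.
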