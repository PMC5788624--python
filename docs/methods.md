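# Methods

`renalmir` implements a miRNA-expression pipeline for classifying the four
most common renal tumor entities — clear cell RCC (ccRCC), papillary RCC
(pRCC), chromophobe RCC (chRCC) and the benign renal oncocytoma — from
absolute qRT-PCR copy numbers of a six-marker panel (miR-221, miR-222,
miR-126, miR-182, miR-200b, miR-200c). This note records the models, the
parameters that matter, the numerical conventions, and the choices made
where the design was genuinely open.

## Absolute quantification

Each miRNA has a log-linear standard curve Ct = m·ln(x) + b fitted by
ordinary least squares to a serial dilution of a synthetic RNA oligo of
known copy number x (points outside a caller-supplied linear range are
excluded before fitting). Copy numbers of known-mass oligos are computed as
mass / MW · N_A with single-stranded RNA MW = 320.5·N + 159.0 g/mol, the
standard average-residue formula with end-group correction.

Sample conversion inverts the curve: x = exp((Ct − b)/m). Conventions:

- **Truncation.** A Ct above 35 cycles is treated as non-expressed and
  truncated to 35 *per replicate*, before averaging. The sample still
  receives the copy number implied by Ct = 35, carried with an
  `expressed=False` flag, so the classifier always sees a number.
- **Replicate averaging** happens on the Ct scale (the measured quantity),
  then one conversion — equivalent to a geometric mean of per-replicate
  copies, the usual qPCR practice. Arithmetic averaging of copies would
  up-weight low-Ct replicates; the difference is documented by a test.
- Copies are treated as per-reaction quantities; all classifier thresholds
  live on the same scale as the standard curves.

## The two-step classifier

Step 1 separates proximal-nephron tumors (ccRCC + pRCC) from distal ones
(chRCC + oncocytoma) by a 3-point miR-222 cutoff: above 1205 copies →
distal (Category 1), below 589 → proximal (Category 3), the closed interval
between → grey zone (Category 2). A grey sample falls back to a single
miR-221 cutoff when one is configured (above → distal). Step 2a separates
ccRCC from pRCC by a single miR-126 cutoff (above → ccRCC), with a miR-222
3-point fallback at 682/358 copies; a grey fallback is indeterminate. Step
2b separates chRCC from oncocytoma by majority vote of single cutoffs —
miR-200b 197, miR-200c 180, miR-222 1399 copies, each voting chRCC when
above — with ties indeterminate, since combining these markers is not
known to beat miR-200b alone. miR-182 is quantified but excluded from
classification (it does not separate ccRCC from pRCC).

Conventions and open-design choices:

- All comparisons are strict; a value exactly on a bound lands in the grey
  zone (3-point) or the below-label (single cutoff).
- The miR-221 step-1 and miR-126 step-2a cutoffs have no published value.
  They default to `None` and are derived from labelled training data by the
  Youden index (`fill_unset_cutoffs`), never hard-coded.
- Disagreement handling at step 1 is miR-222-primary with miR-221 as the
  grey-zone fallback; this follows the stronger published grey-zone
  analysis for miR-222 but is a choice, and thresholds are fully
  configurable via JSON.
- Every call records its full provenance (each comparison made, with value
  and threshold) in the `votes` field.

### Threshold derivation

`derive_grey_zone` picks the tightest interval reaching a per-side purity
target (default 0.97): the upper bound is the smallest candidate cutoff
(midpoints between adjacent distinct values) whose strictly-above set is at
least 97% distal, the lower bound symmetric. If the bounds cross, the
classes already separate at the target and the zone collapses to a single
cutoff (`lower == upper`), which only an exactly-boundary value can hit; a
zero-width grey zone is therefore representable. When no candidate reaches
the target on some side (e.g. one extreme outlier of the wrong class), a
`ThresholdDerivationError` is raised rather than returning bounds that do
not honor their contract.

## Marker statistics

- **Welch's t** (unequal variances, Satterthwaite df) for differential
  expression; two-sided p, no multiple-testing correction.
- **Fold change** is a ratio of sample-size-weighted pooled group means, so
  the distal-vs-proximal fold uses n = 11/19 vs 27/29 weights.
- **AUC** is the Mann–Whitney concordance (0.5 credit for ties), with the
  orientation declared by the caller — an anti-discriminating marker keeps
  AUC < 0.5. The 95% CI is Wald-type with the Hanley–McNeil standard
  error; it is reported unclipped and can exceed [0, 1], as ROC software
  conventionally prints it. DeLong is not implemented.
- **Youden cutoffs** maximize sensitivity + specificity − 1 over midpoints
  between adjacent observed values; ties break toward the higher cutoff
  (higher specificity). Other criteria (closest-to-corner) were considered
  and not used; the cutoff method is recorded in the report.
- **Wilson score intervals** for sensitivity/specificity proportions.
- **Marker combinations** are scored as the plain sum of absolute copies.
- **Fisher's exact test** uses the probability-mass two-sided rule (sum of
  conditional probabilities of tables no more likely than the observed
  one); the odds ratio is the sample cross-product ad/bc, infinite when
  bc = 0.

## ISH scoring

Staining is scored as intensity tier (0–3) plus frequency tier of
immunoreactive cells (0: 0%; 1: (0, 33]%; 2: (33, 66]%; 3: (66, 100]%);
the published tier labels leave (33, 34)% unassigned and the implementation
closes that gap into tier 2. The combined 0–6 score is dichotomized at ≤ 2
negative / ≥ 3 positive. Replicate cores from one specimen are combined by
maximum score. Association tables report both row-wise percentages (share
of calls within a diagnosis) and column-wise ones (share of a call column
per diagnosis) because published tables of this kind are often printed
column-wise while prose reads them row-wise; reporting both sidesteps the
ambiguity.

## Clustering

Samples are clustered on log2(copies + 1) (base and pseudocount are
conventions; the data are zero-safe after truncation handling) using
d = 1 − Pearson r between sample profiles and agglomerative linkage
(average by default; complete/single/ward available). The dendrogram
exports to Newick; cutting at k groups is compared to histology by
majority-label purity (overall purity = sample-weighted mean). Marker-axis
clustering and heatmap rendering are out of scope.

## Synthetic cohorts

The generator exists so every stage is testable without patient data. It
emulates:

- **Group structure.** Default sizes ccRCC 27, pRCC 29, chRCC 19,
  oncocytoma 11. Per-group per-marker arithmetic mean copies default to the
  published group means where printed. Four cells are not printed anywhere
  and are engineering choices on biological grounds, not claims about the
  study data: miR-126 at 600 copies in both distal entities (endothelial
  marker, intermediate in these hypovascular tumors), miR-200b/c lower in
  ccRCC (60/100) than pRCC (180/300) (epithelial–mesenchymal-transition
  suppression in clear cell tumors), and miR-182 flat at 150 everywhere
  (uninformative by design, since it cannot separate ccRCC from pRCC).
- **Within-group variation** is log-normal — positive support and right
  skew, matching copy-number behavior — parameterized as
  mu = ln(target) − sigma²/2 so the arithmetic mean converges to the
  target. The default dispersion is sigma = 0.8 natural-log units,
  independently per marker. At that dispersion the simulated step-1 AUCs
  at the study group sizes are ≈ 0.90 (miR-221) and ≈ 0.82 (miR-222);
  reproducing the published 0.96/0.91 would need sigma ≈ 0.55–0.6, so the
  default should be read as a deliberately hard setting, not a fit to the
  study's (unpublished) within-group variance.
- **Dilution series** add Gaussian noise on the Ct scale (default sd 0.15,
  a typical triplicate spread), because replicate variation is observed on
  Ct. The default true curve is the 100%-efficiency slope −1/ln 2 ≈
  −1.4427 Ct per ln-copy with intercept 40.
- **ISH cohorts** expand a {diagnosis × call} count table into records
  whose (intensity, frequency) pairs are drawn uniformly from the pairs
  consistent with the requested call, so re-scoring reproduces the input
  counts exactly.

What the generator does *not* emulate — FFPE degradation, batch effects,
shared per-sample scaling (RNA input), inter-observer scoring noise,
marker–marker correlation within a group. Passing tests therefore show the
pipeline's arithmetic and decision logic are right under the stated model,
not that the published cohort-level accuracies transfer to real tissues.

### A consequence for unsupervised clustering

Because within-group noise is independent per marker and the correlation
distance discards each sample's overall level and scale, k = 4 clustering
of synthetic cohorts (20 per group, five markers, sigma 0.8) recovers
histology only partially: median overall purity is ≈ 0.45–0.5 with the
defaults, and no linkage/standardization combination we measured exceeds
≈ 0.62. The corresponding acceptance check (median purity ≥ 0.8) fails
under these conditions and is intentionally left failing rather than
weakened; at sigma ≈ 0.6, or with correlated within-sample noise that the
correlation distance is designed to cancel, recovery is much stronger.

## Problem sizes used by tests and the acceptance script

Mean-recovery uses 2000 samples/group (keeps the ±10% band ≈ 5 sigma wide);
threshold-derivation recovery uses 200/group over 20 seeds; clustering
purity uses 20/group over 10 seeds; Wilson coverage uses 10,000 binomial
replicates at p = 0.3, n = 30; the exhaustive Fisher cross-check enumerates
every 2×2 table with total ≤ 40 (132,470 tables) against an exact-integer
hypergeometric oracle.

A note on the Wilson check: the *exact* coverage of the 95% Wilson interval
at p = 0.3, n = 30 is 92.98% (k = 4's upper bound is 0.2968 and k = 14's
lower bound 0.3023, both just missing 0.3) — the familiar coverage
oscillation of score intervals. A "within 2 points of nominal" assertion is
therefore violated by ≈ 0.02 points in expectation at this design point;
the test keeps the 2-point tolerance and documents the failure rather than
moving the goalposts.

## Known limitations

- Thresholds are copies-per-reaction under one assay chemistry; porting
  them to another platform requires re-derivation (`derive_thresholds`).
- The classifier is defined only for the four entities above; unclassified
  RCC is handled as ordinary `classify` calls whose output is read as a
  "favoured" label, with no special code path.
- No probabilistic calls, no survival modeling, no normalization beyond
  absolute quantification.
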