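# Methods

## The kernel-MCC differential-expression statistic

For one gene with log2 expression values x₁…x_N and binary group labels
(case / reference), the statistic is the Matthews Correlation Coefficient of
a leave-one-out kernel-density classifier:

* For each sample *i*, Gaussian KDEs are fitted separately to the case and
  reference values **excluding sample i**, each with its own bandwidth
  recomputed on the reduced training set (Silverman's rule of thumb,
  h = 0.9·min(σ̂, IQR/1.34)·m^(−1/5); Scott's rule is available). When a
  spread measure vanishes the other is used; fully constant data gets a
  floor bandwidth of 1e-6.
* Sample *i* is predicted *case* when the case-conditional density at xᵢ
  exceeds the reference-conditional density by more than a relative guard of
  1e-12; ties and sub-guard differences predict *reference*. The guard is
  part of the classifier definition: it makes exact ties and
  floating-point-order noise resolve identically in the implementation and
  in any literal re-implementation, and biases borderline calls toward the
  majority class, i.e. toward the null.
* The MCC of the N predictions against the true labels is the gene's
  statistic; a gene passes when MCC > 0.105 **and** |l2fc| > 0.58, where
  l2fc is the case-minus-reference mean (inputs are already log2; no
  pseudocount).

Three design points deserve emphasis:

* **No class priors.** With ~7 cases against ~740 references, multiplying
  class-conditional densities by priors would make the all-reference
  classifier optimal for essentially every gene and the statistic
  identically 0. The unweighted likelihood comparison is what gives the
  statistic power; it is deliberate and documented here rather than a bug.
* **Leave-one-out rather than held-out splits.** With so few positives any
  random split is unstable; LOO makes the statistic a deterministic function
  of the data. Resubstitution would inflate the case density at its own
  points and is not used for the statistic.
* **Degenerate genes.** Zero variance in both groups yields constant
  predictions, hence MCC = 0 (a zero denominator factor maps to 0 by the MCC
  convention), and the Welch route reports p = 1 for equal means. Zero
  variance with unequal means is perfect separation and reports p = 0.

The classical route is a two-sided Welch *t*-test on the log2 values with
p < 0.05 and linear fold change > 1.5 (|l2fc| > log2(1.5) ≈ 0.585). The fold
gate is tolerance-inclusive at double precision, so a gene at exactly
1.5-fold passes. No multiple-testing correction is applied by default —
the thresholds are calibrated jointly with the fold gate (the measured null
discovery fraction is ≪ 1%) — Benjamini–Hochberg q-values are available via
`fit(fdr=True)`.

## Dose–response scoring

Responses (% inhibition) are clamped to [0, 100] for fitting and scoring;
raw values are preserved in the plate table. The curve model is the 4PL on a
log10-dose axis, y(ℓ) = b + s/(1 + 10^{h(m−ℓ)}) with span s ≥ 0 (so
bottom ≤ top and h > 0 canonically), m = log10 EC50.

* `fit_4pl` — single-curve nonlinear least squares with a deterministic
  multi-start (EC50 at every observed dose × hill ∈ {0.5, 1, 2}); used where
  per-curve precision matters (noise-free round trips recover generating
  parameters to 1e-4 relative).
* `fit_4pl_batch` — the plate-scale engine: a coarse grid over
  (m, log10 h) with the linear parameters profiled out in closed form,
  refined by vectorised Levenberg–Marquardt on all four parameters across
  every curve simultaneously. A 527 × 149 panel fits in a few seconds on one
  core. On under-sampled near-step curves (~1% of adversarial draws) it can
  settle in a nearly-equivalent local basin whose DSS differs by a few
  points; this does not affect compound ranking, and the single-curve path
  is the precision reference.

The **Drug Sensitivity Score** is DSS1-style: the area of min(y, 100) above
an activity threshold t (default 10%) over the tested log10-dose window,
normalised so a full-response curve scores 100:

DSS = 100·∫ max(min(y, 100) − t, 0) dℓ / ((100 − t)(ℓ_max − ℓ_min)).

The threshold and saturation crossings are solved analytically and the 4PL
antiderivative b·ℓ + s/(h·ln10)·ln(1+10^{h(ℓ−m)}) used in closed form
(agreement with adaptive quadrature ≤ 1e-6 relative). The integration window
is each drug's own tested min/max dose, since panels differ per drug.

**Selective scores**: sDSS(drug, sample) = DSS − mean DSS over the reference
samples with data for that drug; missing cells (smaller panels for scarce
specimens) are simply absent from the mean. Compounds are ranked by the mean
sDSS over case samples — the mean, not the median, because the case group
has ~4 samples — with ties broken by mean case DSS then compound id, and a
coverage flag below 2 scored case samples.

## Promoters, peaks, qPCR and rewiring

Coordinates are 0-based half-open throughout; touching intervals do not
overlap. Promoters are [TSS − 2000, TSS + 500) on the + strand and the
mirror [TSS − 500, TSS + 2000) on −, clipped at zero; with duplicate gene
names the longest transcript's TSS wins. Both window sizes are arguments and
recorded in run metadata — "promoter" has no canonical width. A gene is
*bound* when any peak overlaps its promoter by ≥ 1 bp (binary presence; peak
strength belongs to the upstream peak caller). Assignment uses one interval
tree per chromosome and is defined — and tested — to agree exactly with
brute-force all-pairs intersection. Chromosome naming is strict: peaks and
promoters whose names differ only by a `chr` prefix raise an error naming
the offenders, with an explicit harmonisation flag to normalise both.

qPCR: ΔCT = mean Ct(target) − mean over housekeeping targets of mean Ct;
relative expression 2^(−ΔCT); ΔΔCT renormalises to a control condition
(control ≡ 1, knockdown efficiency = 1 − 2^(−ΔΔCT)). Fold enrichment per
locus is 2^(Ct_IgG − Ct_antibody) against the matched IgG condition, then
expressed relative to a designated control sample (which maps to 1).

A gene is **rewired** when all four hold: it passes the diagnosis DE
criterion upward; it is significantly downregulated (p < α and
l2fc < −log2(1.5), classical route on replicate-level data) in
inhibitor-treated case cells; it is **not** so downregulated in treated
reference-cohort cells; and it is **not** so downregulated under the control
drug. The same one-sided criterion is used on all three treated tables —
mirroring the case criterion symmetrically — so "no change on the control
drug" means "fails the downregulation rule", a deliberate operationalisation
recorded in the report parameters. Bound∩DE is the promoter-bound set
intersected with the diagnosis DE pass set in either direction. Subset
invariants (rewired ⊆ up-at-diagnosis, bound∩DE ⊆ bound, lost ⊆ bound) are
asserted on every report construction.

## The synthetic-data generator

The generator's defaults are the study design the package is built around,
not tuning knobs: 7 case vs 741 reference samples; 104 up- and 62
down-spiked genes with gene-level effects drawn once from N(±1.5, 0.3²) log2
units over a per-gene baseline uniform on [3, 10] with N(0, 0.5²) log2
noise; a 527-compound panel (4 case-selective) screened in 4 case + 145
reference samples on a 5-point ladder spanning 1–10⁴ nM with 5% response
noise; 36 rewired genes among the spiked-up set; 801 promoter-bound genes of
which 10 (drawn from the rewired set) are also diagnosis-DE; treated
expression with 2 samples × 3 replicates per condition. 2000 genes is the
desk-scale transcriptome — large enough that sub-percent null discovery
fractions are measurable, small enough that the full pipeline runs in
seconds. The effect-size spread of 0.3 keeps essentially every spiked gene
above the fold cutoffs while avoiding a single degenerate effect size; the
replicate structure of the treated comparisons is exposed as a parameter
because a 2-sample design alone cannot support a two-group test.

Every generator draws from its own seeded substream, so outputs are
bit-identical under a fixed seed and independent of call order; truth labels
(spiked/selective/rewired/bound sets, generating effect sizes and true DSS
values) are emitted alongside for recovery measurement.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: count-level properties of RNA-seq (library size,
overdispersion, mean–variance trends — values are Gaussian on the log2
scale), correlated genes or batch structure, dose–response deviations from
the 4PL (hook effects, plate artefacts), peak-strength variation or fuzzy
peak boundaries, and clinical covariates. Recovery rates measured here are
upper bounds on what identically-tuned thresholds would achieve on real
cohorts.

## Numerical choices

* Bandwidth floor 1e-6 log2 units; density tie guard 1e-12 relative.
* Welch p-values: NaN from degenerate inputs are mapped by the rules above;
  p-values are never adjusted before gating unless requested.
* 4PL bounds: bottom ∈ [−30, 120], span ∈ [0, 200], EC50 within two decades
  of the tested range, hill ∈ [0.05, 10]. Unconverged fits score DSS 0 with
  a warning.
* DE tables are sorted by descending |l2fc| with gene id as the
  deterministic tie-break; rankings use mergesort throughout, so equal keys
  preserve a reproducible order.
* The DE pass fraction can be computed with `lazy_kmcc=True`, which skips
  the kernel statistic for genes already failing the fold gate; because the
  kernel call is a conjunction of both cutoffs the resulting flags are
  provably identical, only the kernel_mcc column of skipped genes is NaN.

## Known limitations

* The 0.105 MCC cutoff is treated as a fixed constant; no permutation
  calibration is performed (the measured null pass fraction at the default
  design is ~0.1%).
* The kernel statistic is quadratic in the reference-cohort size per gene
  (the LOO bandwidths are recomputed per holdout); ~750 samples × 2000 genes
  runs in ~10 s on one core, but 10× larger cohorts would want the lazy
  gate or subsampling.
* sDSS centering uses the reference-cohort mean; a robust variant (median)
  is a one-line change but intentionally not the default for 4-sample case
  groups.
* User-supplied peak files are trusted to be called consistently between
  conditions; binding loss is presence/absence, not differential signal.
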