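# Methods

This document records the statistical model behind each pipeline stage, the
default parameters and where they come from, and the numerical choices and
known limitations discovered while validating the implementation on
synthetic data.

## Data model and coordinates

All methylation values are beta values: per-probe methylated fraction in
[0, 1], probes x samples. Testing happens on the M-value scale,
M = log2(beta / (1 - beta)), which stabilises variance near the extremes.
All internal genomic coordinates are 1-based inclusive; BED files are
written 0-based half-open, and `methdmr.io` is the only place that
conversion happens.

## Probe quality control

A probe is removed when

* more than 11 samples have a missing beta value, or
* more than 5 samples have a detection P value above 0.001.

The "more than 11" rule is the Bonferroni-corrected binomial criterion: for
n samples, a per-probe missingness rate r, and n_probes simultaneous tests,
`missingness_threshold` returns the smallest k such that
`n_probes * P(Binomial(n, r) >= k) <= alpha`. The worked example (n=10,
r=0.5, one probe, alpha=0.05) gives k=9 because
P(X >= 9) = 11/1024 ~ 0.0107 < 0.05 while P(X >= 8) ~ 0.0547. The
ProbeFilter's "auto" mode sets max_missing = k - 1 (remove anything
reaching the improbable count).

## Covariate normalisation

Each probe's beta values are adjusted by a per-probe quasi-binomial GLM with
logit link on chip, chip position, sex, age, age^2, sex x age and
sex x age^2. The adjusted value is the probe mean plus the response
residual (beta - fitted mean), clipped into [1e-6, 1 - 1e-6]. This removes
technical and demographic trends while keeping values on the beta scale.

Fitting tens of thousands of independent GLMs is done by a batched IRLS
(`methdmr._glm.batched_logit_irls`) sharing one design matrix across probes
with per-probe missingness masks, in chunks of 4000 probes. statsmodels'
GLM is the per-probe oracle in the test suite, never the implementation.
Collinear design columns are dropped by pivoted QR with a warning.

A linear predictor beyond |eta| = 15 is flagged as quasi-separation: beta
values clipped into [1e-6, 1 - 1e-6] can produce |logit| at most ~13.8, so
only a runaway fit exceeds that bound.

## Cell-composition correction (reference-free)

Whole blood is a mixture of leukocyte subtypes, and case/control
composition differences masquerade as probe-level signal. The corrector
(`ReFACTor`, K=5 components, t=500 sites):

1. standardises each probe across samples,
2. ranks probes by distance to their rank-K SVD reconstruction and keeps
   the t best-explained (cell-type-informative) sites,
3. computes K principal-component scores over those sites,
4. regresses the scores out of every probe (intercept + residual, clipped).

Near-constant probes (beta variance < 1e-4) are excluded from site
selection because standardising them is unstable.

### A degeneracy worth knowing about

If the true mixture has exactly K cell types, the standardised mixture
structure spans only K-1 dimensions (proportions sum to one). A K-component
corrector then has one spare component free to lock onto whatever sparse
structure remains — including genuine case/control signal, which it will
silently remove. In an early synthetic configuration with 5 simulated cell
types and K=5, the spare component correlated 0.78 with case status and
post-correction lambda collapsed to ~0.006 with zero recovery of spiked
regions. The generator default is therefore six cell types with a
blood-like Dirichlet concentration (9, 3, 2, 1.5, 1, 0.5), matching the six
major leukocyte subtypes (granulocytes, CD4+ T, CD8+ T, B, monocytes, NK)
at roughly 53/18/12/9/6/3 percent. With six types, no spiked probe enters
the selected site set and component/status correlations stay below 0.12.

### Over-correction

If the composition shift between cases and controls is very large, the
components become so status-correlated that regressing them out strips
chance case/control differences genome-wide, deflating lambda well below 1
(0.72-0.79 was observed at a 0.10 proportion shift). The confounded
synthetic scenario therefore uses a 0.05 shift on the first two cell types,
which yields clear inflation before correction (lambda 1.4-1.7) without
pathological deflation after (0.91-1.00).

## Per-probe association

Each probe is tested by logistic regression with case status as the
outcome: deviance of (status ~ cohort) minus deviance of
(status ~ cohort + M), referred to chi-square with 1 df. The Wald
coefficient (log-odds per M unit) and its SE are reported descriptively.
Constant probes get P = 1 with a flag; quasi-separated probes keep their
LRT P but are flagged and their Wald coefficient set to +-inf.

Calibration diagnostics:

* inflation factor lambda = median observed chi-square / 0.4549 (the
  chi-square(1) median);
* Q-Q bands from the exact Beta(i, n - i + 1) distribution of uniform
  order statistics.

The genome-wide significance default is P < 1.09e-7. Note a source
discrepancy: the method description's headline threshold is 1.09e-7 while
its methods text also uses 1e-6; the stricter value is the default and
both are accepted by the config.

### Lambda under the full pipeline

On fully realistic synthetic data (chip effects, cell-type structure,
two-stage residualisation) the corrected scan stabilises at lambda
~1.07-1.15: small-sample LRT anticonservatism plus residual confounding
and the extra effective degrees of freedom consumed by two residualisation
passes. A raw scan on the same data swings 0.79-1.17 per seed from chance
chip/composition imbalance. On clean null data (homogeneous tissue, no
chip effects) the scan is calibrated: lambda 1.00-1.05, type-I error
0.053-0.057 at alpha 0.05. The null-calibration acceptance scenario uses
the clean configuration because it is the one that isolates the test
machinery; the confounded scenario exercises the correction separately.

## Sliding-window DMRs

One 1 kb window is anchored at every probe position, spanning
[pos, pos + 999] and holding every probe starting in that span. Per-window
probe P values are combined by Fisher's method (-2 sum ln p ~ chi-square
with 2k df). Fisher's method assumes independence; adjacent correlated
probes make window P values anti-conservative, which is inherent to the
approach.

Window P values are converted to Storey q-values: pi0 estimated by a cubic
fit to pi0(lambda) over the grid 0.05..0.95 (the qvalue smoother),
Benjamini-Hochberg (pi0 = 1) below 100 windows. Windows with q < 0.05 are
merged into maximal overlapping runs.

### Region extent

Two trims define the reported region coordinates:

1. **Window padding.** A merged run of windows extends up to 999 bp of
   probe-free sequence past the last CpG; the extent is trimmed to the span
   of member CpGs.
2. **Unsupported boundary CpGs.** A window anchored up to 999 bp before a
   differential run is itself significant (it contains differential
   probes), so the raw member union includes flanking CpGs showing no
   difference. Boundary members with per-probe P > 0.05 are trimmed from
   both edges, keeping the contiguous supported core. A DMR is an interval
   of CpGs exhibiting the difference, not of the windows that detected it;
   without this trim, reported spans for compact (~1 kb) regions exceed
   twice the true span purely from detection-window slop.

Region P is Fisher's method over the (deduplicated, trimmed) member
probes; region FDR is the best member window's q; direction is the strict
majority sign of member delta beta (case minus control), "ambiguous" on a
tie.

### Region-level empirical FDR is not window-level FDR

Selecting windows at q < 0.05 leaves ~5% of selected windows false. True
windows collapse into few merged regions (tens of windows per region)
while false windows land as isolated singletons, so the *region-level*
false fraction converges to roughly (false windows) / (false windows +
true regions) — around 0.3-0.5 in the spiked scenarios — even though the
window-level FDR is controlled at 5%. An idealized run with perfect
uniform null P values reproduces this (empirical region FDR 0.29-0.43 with
100% recovery), so it is a property of the FDR-then-merge procedure
itself, not of the implementation. Controlling region-level FDR at 10%
would require window-level FDR near 0.6%. Consumers who need region-level
error control should rank by region P or require a minimum member count.

## Bump hunting

The second, independent DMR caller:

1. probes are chained into clusters (inter-probe gap <= 1000 bp);
2. a linear model methylation ~ case + age + sex gives per-probe adjusted
   case-control coefficients (missing values mean-imputed);
3. coefficients are smoothed within clusters by a running median (k=5,
   truncated at edges; clusters under 3 probes unsmoothed);
4. maximal same-sign runs beyond a cutoff (default: 99th percentile of the
   absolute smoothed coefficient) become candidates scored by area;
5. case/control labels are permuted within sex x cohort strata B times;
   a candidate's FWER is the fraction of replicates whose genome-wide
   maximum null area reaches its area.

## Enrichment

* Feature enrichment: two-sided Fisher's exact test of DMR-member CpGs
  against the full array background per annotation level (island relation,
  gene feature, DNase hypersensitivity), BH-corrected across levels.
* Gene-set over-representation: regions map to nearest genes
  (overlap first, else closest, ties kept); each GMT set is tested by the
  hypergeometric upper tail against the array's nearest-gene background;
  sets overlapping the list in fewer than 2 genes are excluded;
  BH-corrected. Worked check: drawing 3 of 3 listed genes from a 10-member
  set in a 100-gene background gives P = C(10,3)/C(100,3) = 120/161700
  ~ 7.42e-4.

## Synthetic data generator

Defaults mirror the study design: 67 cases + 67 controls, cases split
28 adult / 39 adolescent, controls matched on cohort, sex and age (+-2
years); chips of 12 samples with randomised assignment and a small
per-chip shift (sd 0.004); baseline betas from a three-component mixture
(low/mid/high); heteroscedastic noise sd = 0.02 * 2 * sqrt(mu(1-mu));
~0.2% missing and ~0.2% detection failures. Probe positions are clustered
(15% of gaps are 2-20 kb jumps) with spatially coherent island blocks.

Spiked regions (`choose_spike_regions`) are runs of consecutive probes
with every internal gap <= 1000 bp — without that constraint a "12-probe
region" can span a multi-kilobase probe void that no 1 kb-resolution
method could report as one region, making the ground truth ill-defined.
Spike effects are added to cases only and clipped into [0, 1]; signs
alternate so hyper- and hypomethylated regions are balanced.

The ID-Migraine-style case rule (`classify_id_migraine`): two or three
affirmative items classify a respondent as a case.

## Known limitations

* Fisher's method over correlated neighbouring probes is
  anti-conservative at the window level (documented above); the Storey
  step operates on those optimistic P values.
* Region-level empirical FDR is not controlled by window-level FDR
  (see above).
* The corrected scan on fully realistic data carries lambda ~1.1;
  consumers comparing against a calibrated-null expectation should use
  the clean-null configuration.
* The permutation FWER with B=100 has granularity 0.01 and is only
  suitable for liberal screening; B=1000 is the analysis default.
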