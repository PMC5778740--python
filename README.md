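# methdmr

Differential DNA-methylation analysis for case/control array studies:
probe-level quality control, covariate normalisation, reference-free
cell-composition correction, per-probe logistic association, and two
independent DMR (differentially methylated region) callers — a 1 kb
sliding-window Fisher's-method scan and a bump hunter with permutation
FWER — plus genomic-feature and gene-set enrichment. A seeded synthetic
data generator with spike-in ground truth makes every stage testable end
to end.

## The science in brief

Illumina-style methylation arrays report a beta value per CpG probe and
sample (methylated fraction, 0 to 1). Case/control differences at single
probes are small and noisy; the signal of interest is usually a *region*
of adjacent CpGs moving together. Between the raw betas and the regions
sit three well-known hazards this package addresses explicitly:

* **Technical structure** (chip, chip position) and demographics (sex,
  age) shift betas probe-by-probe. Each probe is adjusted by a
  quasi-binomial logit GLM and replaced by its mean plus response
  residual.
* **Cell composition.** Whole-blood methylation is a mixture over
  leukocyte subtypes; if cases and controls differ in composition, every
  composition-sensitive probe looks associated. A reference-free
  corrector (ReFACTor-style: low-rank site selection, then PCA, K=5
  components over t=500 sites) regresses the mixture surrogates out.
* **Multiplicity and calibration.** Per-probe tests are logistic LRTs
  (status ~ cohort vs status ~ cohort + M-value, 1 df). Calibration is
  monitored by the inflation factor lambda (median chi-square / 0.4549)
  and exact Beta order-statistic Q-Q bands. Windows are combined with
  Fisher's method, converted to Storey q-values, and merged at 5% FDR.

The two DMR callers are deliberately different (P-value combination vs
effect-size smoothing with label-permutation FWER) so their overlap is
evidence, not circularity. See `docs/methods.md` for the full model,
parameter provenance, numerical choices, and honest limitations —
including why region-level empirical FDR is *not* controlled by
window-level FDR, and a subtle degeneracy where a cell-composition
corrector with as many components as true cell types can silently absorb
genuine signal.

## Worked example

Simulate a study-scale dataset (67 cases + 67 controls split over adult
and adolescent cohorts) with two known differential regions, then run the
whole pipeline:

```bash
methdmr simulate --n-probes 5000 \
    --spike chr2:1428359-1431525:0.15 \
    --spike chr2:2719535-2723963:-0.15 \
    --seed 7 --out-dir data
methdmr all --data-dir data --out-dir results --seed 7
```

Printed output:

```
wrote 5000 probes x 134 samples to data
lambda=1.063; 4 DMR(s); 26 bump candidate(s)
```

`results/dmr.tsv` (the sliding-window caller's merged regions):

```
chrom	start	end	direction	p	fdr_q	n_probes	genes
chr1	25576	25576	hypermethylated	0.00010380071187194524	0.016764669650500694	1	GENE00000
chr1	421943	421943	hypomethylated	1.0167040346599967e-05	0.01605579245009944	1	GENE00004
chr2	1428359	1431525	hypermethylated	0.0	5.28023227406968e-149	12	GENE00060
chr2	2719535	2723963	hypomethylated	0.0	3.0825996927231795e-183	12	GENE00069
```

Both spiked regions are recovered at exactly the ground-truth coordinates
(`data/truth.bed`), with the correct direction and all 12 member CpGs;
the two singleton calls are the expected false positives of window-level
FDR selection (see `docs/methods.md` on region-level FDR). The run also
writes `association.tsv`, `windows.tsv`, `bumps.tsv`, `dmr.bed`,
enrichment tables, `diagnostics.json` (lambda, genome-wide hits, config
hash) and `run_info.json`.

Each stage is also available separately (`methdmr qc`, `correct`,
`associate`, `dmr`, `bumps`, `enrich`) and as a library:

```python
from methdmr.simulate import generate_manifest, simulate_dataset
from methdmr.pipeline import PipelineConfig, run_analysis

ds, truth = simulate_dataset(generate_manifest(10_000, seed=1), seed=1)
bundle = run_analysis(ds, PipelineConfig(bootstrap_b=100))
print(bundle["inflation"].lambda_, len(bundle["regions"]))
```

## Testing and reproduction

```bash
pytest -q                      # full suite: unit, property, acceptance
pytest -q --ignore=tests/test_acceptance.py   # fast subset (~20 s)
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The acceptance script runs the pipeline's main computations — analytic
constants, null calibration, spiked-region recovery, confounding removal,
cross-method concordance — with every random stream derived from
`--seed`, and writes each headline quantity with its sample size as JSON.

One acceptance test is expected to fail by design:
`test_spiked_dmr_recovery` asserts region-level empirical FDR <= 0.10,
which the window-FDR-then-merge procedure cannot deliver (the measured
value is ~0.3 even with mathematically perfect per-probe P values);
recovery and direction clauses pass. The analysis is in
`docs/methods.md`; the assertion is kept rather than weakened because the
property is the honest statement of what a region-level consumer needs.

All tests and the acceptance script use only synthetic data generated in
process; nothing is downloaded.

## Layout

```
src/methdmr/
  datatypes.py     dataclasses and the dataset container
  simulate.py      seeded generator with spike-in ground truth
  preprocessing.py QC filter, beta/M transforms, covariate normaliser
  celltype.py      reference-free composition correction
  association.py   per-probe logistic LRT, lambda, Q-Q bands
  windows.py       sliding windows, Fisher, Storey q, region merge
  bumphunter.py    clusters, smoothing, bumps, permutation FWER
  enrichment.py    feature and gene-set enrichment
  pipeline.py      orchestration, config, file outputs
  io.py            TSV/BED/GMT readers and writers
  cli.py           command-line front end
docs/methods.md    model details, parameter provenance, limitations
scripts/acceptance.py  headline-quantity runner
tests/             unit, property (hypothesis) and acceptance suites
```
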