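# ewas-hypogen

A hypothesis-generating epigenome-wide association toolkit: use DNA
methylation as a *screen* for candidate risk factors of a binary condition,
then test those candidates directly in cohort data.

## The idea

Classical EWAS treats confounding as a nuisance. This package deliberately
leverages it. The two-phase approach:

1. **Hypothesis generation.** Run a minimally adjusted epigenome-wide scan
   with case status as the exposure and CpG beta-values as the outcome,
   adjusting only for age and surrogate variables that capture technical
   batch structure — *not* for lifestyle or environmental covariates. A CpG
   that differs between cases and controls because of a shared upstream
   exposure (say, smoking, which both shifts methylation and raises the
   odds of the condition) will surface as a hit. Look the hit CpGs and
   their resident genes up in an EWAS catalog of published CpG–phenotype
   associations: the traits previously reported at those sites are the
   candidate risk factors.
2. **Hypothesis testing.** Map each harvested trait onto a measured cohort
   variable and fit unadjusted and covariate-adjusted logistic regressions
   of the condition on that variable, with descriptive case/control
   summaries, an eligibility screen for sparse cells, and z-scored
   continuous exposures so effect sizes are per standard deviation.

The worked examples are two adolescent menstrual-health conditions —
dysmenorrhea (severe menstrual cramps) and heavy menstrual bleeding (HMB)
— for which the package ships fixtures encoding the published summary
tables and hit-CpG trait lists. The underlying individual-level cohort data
are managed-access, so everything individual-level here is synthetic.

## What's in the box

| Module | Purpose |
| --- | --- |
| `simulate` | Synthetic beta-matrix generator with planted direct, confounded, batch and null probes, plus a ground-truth record |
| `cases` | Questionnaire-based case/control/less-severe status derivation with comorbidity and timing exclusions |
| `qc` | Probe filtering (sex chromosomes, SNP/control probes, detection failures), per-probe Tukey-fence outlier blanking, cross-reactive-probe flagging |
| `sva` | Permutation (parallel-analysis) estimate of the surrogate-variable count and iteratively reweighted surrogate variable computation |
| `ewas` | Vectorised per-probe OLS scan, genomic inflation lambda, QQ data, strict suggestive-threshold hit selection (`EWASScan` / `EWASResults`) |
| `catalog` | Offline TSV and REST catalog backends, CpG- and gene-level trait harvesting, Fisher-exact trait enrichment |
| `cohort` | Case/control summary tables, fewer-than-five eligibility rule, logistic regression battery |
| `pipeline` | One-config orchestration of all stages plus three sensitivity variants, with deterministic outputs and a run report |

## Worked example (Python)

```python
import pandas as pd
import ewas_hypogen as eh
from ewas_hypogen import catalog

# synthetic data with 10 planted confounder-driven probes among 1,000
config = eh.SimulationConfig(n_samples=300, n_probes=1000, seed=5)
beta, pheno, annotation, truth = eh.generate_dataset(config)
status = pd.DataFrame({
    "status": pheno["condition"].map({1: "case", 0: "control"}),
    "first_report_wave": float("nan"), "reason": "",
})

scan = eh.EWASScan.from_phenotypes(beta, pheno, status)
results = scan.fit()
print(results.summary())
```

```
EWAS scan results
  probes analysed : 1000
  covariates      : intercept, case, age
  surrogate vars  : 0
  inflation lambda: 1.203
  hits (p < 1e-05): 30

                beta        se    ci_low   ci_high             p    n  degenerate
probe_id
cg00000007  0.052264  0.002235  0.047866  0.056663  2.645093e-69  300       False
cg00000003  0.050844  0.002294  0.046330  0.055359  6.551523e-65  300       False
...
```

```python
hits = results.select_hits()
store = catalog.TSVCatalogStore(eh.generate_catalog_fixture(truth, annotation))
hypotheses = catalog.harvest_traits(hits, annotation, store, "condition")
print(list(hypotheses.traits()))
```

```
['smoking']
```

The scan, knowing nothing about the generator, recovers the planted
upstream exposure as the candidate phenotype.

## Worked example (command line)

```bash
ewas-hypogen simulate --out demo --seed 5 --n-samples 300 --n-probes 1000
ewas-hypogen run --config demo/config.yaml
```

with `demo/config.yaml`:

```yaml
beta: demo/beta.tsv
annotation: demo/annotation.tsv
pheno: demo/pheno.csv
outdir: demo/out
conditions:
  condition:
    status_column: condition
catalog_path: demo/catalog.tsv
variable_map:
  smoking: smoking
seed: 5
```

prints

```
condition: {'cases': 109, 'controls': 191, 'less_severe': 0, 'excluded': 0,
'probes_removed': {'sex': 0, 'snp_control': 0, 'detection': 0},
'probes_retained': 1000, 'outlier_cells': 1, 'n_sv': 2,
'lambda': 0.9167087927398466, 'hits': 30, 'traits': 1,
'tests_run': 2, 'tests_omitted': 0, 'traits_unmapped': 0}
```

and the final association table (`demo/out/condition_associations.tsv`)
contains the hypothesis test of the harvested trait:

```
exposure      model  odds_ratio   ci_low  ci_high            p   n
 smoking unadjusted    2.715304 1.986616 3.711274 3.714216e-10 300
 smoking   adjusted    2.705236 1.978210 3.699458 4.611048e-10 300
```

Other subcommands (`qc`, `sva`, `ewas`, `lookup`, `test`, `sensitivity`)
run individual stages; see `ewas-hypogen --help`.

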