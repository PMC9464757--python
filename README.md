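# dualsubtype

Single- and dual-subtype analysis for 80-gene breast-cancer molecular
subtyping, as a reusable Python library.

Early breast tumors are molecularly subtyped by scoring their expression
profile against three signature gene sets — Luminal (58 genes), Basal (28
genes) and HER2 (4 genes) — with the highest-scoring class taken as the
subtype. Most tumors have one clearly dominant program, but in a small
fraction the top two scores are *statistically indiscernible*: two pathways
are simultaneously active ("dual subtype"), which matters clinically because,
for example, Luminal-HER2 dual tumors respond to HER2-targeted therapy much
less often than pure HER2 tumors. This package implements the full analysis
chain for researchers who want to study that phenomenon on their own or on
simulated cohorts:

- **`simulate`** — synthetic expression cohorts with planted single/dual/
  triple pathway activation, plus coupled clinical annotations (ER/PR/Ki67,
  HER2 IHC/FISH, stage, grade, therapy) and treatment outcomes;
- **`scoring`** — nearest-centroid classification: score(sample, class) =
  Pearson *r* between the sample's profile restricted to the class's
  signature genes and the class centroid; standard call = argmax;
- **`dual`** — Single/Dual/Triple calling from two evidence sources: per-class
  thresholds on the top score difference *d* = *s*₍₁₎ − *s*₍₂₎ found by
  Gaussian-mixture bimodality detection (valley between the modes, with a
  5th-percentile fallback), and a per-sample gene bootstrap whose *flip
  fraction* measures how often resampling the signature genes reverses the
  ranking;
- **`prevalence`** — the dual rate expected in the clinical population,
  by stratified resampling of the cohort to a target clinical-subtype
  mixture (default 70/13/5/12% for HR+HER2−/HR+HER2+/HR−HER2+/HR−HER2−);
- **`burstein`** — four-class re-classification of Basal-involved tumors
  (BLIA/BLIS/LAR/MES) via a shared-panel centroid classifier;
- **`cohort_stats`** — clinical receptor rules (HR+ iff ER or PR ≥ 1%; HER2
  from IHC with FISH reflex at 2+) and the statistical toolkit: chi-square
  tests of independence, Welch *t*-tests, Wilson proportion intervals,
  logistic regression with Wald inference.

## Worked example

```python
import dualsubtype as ds

cfg = ds.SimConfig(n_samples=800, dual_fraction=0.05, seed=3)
expr, truth = ds.generate_expression_cohort(cfg)
singles = truth["true_label_kind"] == "Single"
labels = truth.loc[singles, "true_components"].map(lambda c: c[0])
model = ds.train_centroids(expr, labels, ds.signature_gene_names(cfg),
                           class_order=ds.CLASS_ORDER)
calls, thresholds = ds.classify_cohort_dual(expr, model, B=500, seed=9)
```

which prints (see `examples/03_dual_calling.py`):

```
per-class thresholds on the top difference d:
  Luminal  t=0.901  (bimodal-valley)
  Basal    t=1.135  (bimodal-valley)
  HER2     t=1.517  (bimodal-valley)

call accounting: {'Single': 756, 'Dual': 37, 'Triple': 7}
planted duals detected: 100.0%; false multi-subtype calls on singles: 0.26%
dual labels found: {'Luminal-Basal-type': 23, 'Luminal-HER2-type': 13, 'Basal-HER2-type': 1}
```

The thresholds are the valleys of each class's bimodal *d* distribution
(clean singles sit in a high-*d* mode, multi-program samples in a low-*d*
mode); the call accounting partitions the cohort, and the planted duals are
recovered with a false-call rate far below the 5% bootstrap level. Dual
labels concentrate on Luminal-Basal and Luminal-HER2, as expected for a
Luminal-dominated cohort.

The other capabilities each have a narrative script under `examples/`
(simulation, scoring, prevalence, Burstein re-classification, clinical
statistics, full pipeline). The same pipeline is scriptable from the shell:

```bash
dualsubtype run --config cfg.yaml --out-dir out/
dualsubtype simulate --n 2000 --out-dir data/
dualsubtype stats --table '[[34,13],[59,114]]'
```

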