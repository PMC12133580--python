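# rareaml

Analysis toolkit for **rare-subgroup multi-omics in AML**: when a cytogenetic
subgroup has only a handful of patients (e.g. a fusion-positive subtype with
~7 cases against ~740 reference AMLs), standard cohort statistics are fragile.
`rareaml` implements the three computational stages such a study needs, end to
end, with a fully seeded synthetic-data generator so every stage can be
validated against known ground truth:

1. **Kernel-MCC differential expression** (`rareaml.kernelmcc`).
   For each gene, a leave-one-out Gaussian-KDE classifier separates case from
   reference samples on log2 expression; the Matthews Correlation Coefficient
   of its predictions is the per-gene statistic

   MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)).

   A gene is called on this route when MCC > 0.105 and |l2fc| > 0.58, where
   l2fc is the case-minus-reference mean on the log2 scale. A classical route
   (Welch *t*, p < 0.05 and fold change > 1.5; note log2(1.5) ≈ 0.585) runs
   alongside.

2. **Drug sensitivity scoring** (`rareaml.drugscreen`).
   Per (drug, sample) four-parameter logistic fits on a log10-dose axis,
   y = bottom + (top − bottom)/(1 + (EC50/x)^hill), a DSS1-style Drug
   Sensitivity Score (closed-form area of the fitted curve above a 10%
   activity threshold, normalised over the tested log-dose window), selective
   scores sDSS = DSS − mean reference-cohort DSS, and a per-compound
   group-selectivity ranking.

3. **Regulatory integration** (`rareaml.genomics`, `rareaml.qpcr`,
   `rareaml.rewiring`). Strand-aware promoter windows around TSSs (2 kb up /
   500 bp down by default), peak-to-promoter target assignment on 0-based
   half-open intervals, ΔCT/ΔΔCT qPCR quantification and CUT&RUN-qPCR fold
   enrichment, and classification of **rewired** genes: upregulated at
   diagnosis, selectively lost upon pathway-inhibitor treatment in case cells
   but neither in treated reference cells nor under a control drug, with
   promoter-binding evidence integrated alongside.

The library follows a statsmodels-style shape: a model object built from data
(`DifferentialExpressionModel`, `DoseResponseModel`, `DrugScreenModel`) whose
`fit()` returns a results object carrying estimates, diagnostics, a
`summary()` table and plotting helpers. `rareaml.pipeline` orchestrates the
stages behind a CLI.

## Worked example

```python
from rareaml import SimConfig, simulate_expression, DifferentialExpressionModel

cfg = SimConfig(seed=1)              # 7 cases vs 741 references, 104 up / 62 down spiked
data, truth = simulate_expression(cfg)
res = DifferentialExpressionModel(data.values, data.groups).fit(route="both")
print(res.summary())
```

prints

```
Differential expression (case vs reference)
  route: both   samples: 7 case / 741 reference
  kernel route: MCC > 0.105, |l2fc| > 0.58
  classic route: p < 0.05 (Welch t), FC > 1.5
  genes: 2000   pass: 166 (102 up, 64 down)
```

166 of 2000 genes pass the kernel route at this seed — 163 of them are truly
spiked (sensitivity 98%, FDR 1.8% against `truth`). The per-gene table is
sorted by |l2fc|:

```
gene_id      l2fc  kernel_mcc  p_value  passes_kmcc  passes_classic direction
 G01076  2.400148    0.476158 0.000021         True            True        up
 G00004  2.312516    0.618964 0.000054         True            True        up
 G00201 -2.283614    0.397769 0.000451         True            True      down
```

The drug screen on the same seed (527 compounds, 4 of them case-selective,
4 case + 145 reference samples):

```python
from rareaml import simulate_dose_response, DrugScreenModel
plate, dtruth = simulate_dose_response(cfg)
screen = DrugScreenModel(plate, [f"scase{i:02d}" for i in range(4)],
                         [f"sref{i:03d}" for i in range(145)]).fit()
print(screen.summary())
```

```
Drug screen (selectivity = mean sDSS over case samples)
  drugs ranked: 527   case/reference samples: 4/145
  top 5:
      1. D373  sDSS  69.20  DSS  72.49
      2. D486  sDSS  67.72  DSS  67.93
      3. D025  sDSS  65.76  DSS  66.07
      4. D524  sDSS  65.08  DSS  65.15
      5. D214  sDSS   5.40  DSS  42.27
```

The four spiked selective compounds occupy ranks 1–4 with a wide margin over
the first non-selective drug (sDSS 65+ vs 5.4) — a mean sDSS over case
samples is the selectivity statistic.

The full pipeline (simulate → DE → screen → promoter binding → rewiring) runs
from the shell:

```bash
rareaml run --seed 1 --outdir myrun        # report.json + summary.txt + artifacts
rareaml simulate --seed 1 --outdir inputs  # synthetic inputs + truth.json only
rareaml validate --config cfg.yaml         # structural input checks
```

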