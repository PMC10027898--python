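# pptpp

Analysis of **pre-post thermal proteome profiling (ppTPP)** — pulsed
SILAC crossed with 2D thermal proteome profiling — for experiments
probing what happens to the proteome when mitochondrial protein import
is competitively blocked by a "clogger" construct.

Starting from protein-level TMT reporter-ion tables (IsobarQuant-style
`protein.txt` files), the package computes, per protein, SILAC pool
(pre-existing/light vs newly synthesized/heavy) and timepoint:

- **abundance score** `A = mean log2 FC(clogger/control)` at the two
  coolest gradient points (37, 37.8 degC) — a proxy for protein amount;
- **stability score** `S = sum over the 9 remaining temperatures of
  (log2 FC - A)` — a proxy for a thermal stability shift;
- significance via a weighted, empirical-Bayes **moderated t** with an
  **empirical-null** decomposition of the t-ensemble into p, local fdr
  and tail-area q-values;
- synthesis/degradation rate constants **KS/KD** from exponential fits
  to the 37 degC heavy/light trajectories, and clogger/control ratios
  **dKS/dKD**;
- categorical classes: dK top/bottom-20% abundance classes, +/-0.5
  stability classes, stabilization tiers (light > 2.9, heavy > 0.5),
  Tukey IQR outliers and annotation-group summaries.

A synthetic-data module generates full ppTPP experiments (2 strains x
2 SILAC pools x 4 timepoints x 11 temperatures x 3 replicates) with
known ground truth — sigmoid melting, exponential pool kinetics,
group-specific clogger effects, log-normal noise, per-run batch
offsets, detection-limit censoring — so every stage is testable
without the deposited raw data. See `docs/methods.md` for the model
and all conventions.

## Worked example

Run the whole pipeline on a simulated 300-protein experiment:

```python
from pptpp import PipelineConfig, run_pipeline, quant_io

cfg = PipelineConfig(out_dir="demo", sim={"n_proteins": 300}, seed=7)
out = run_pipeline(cfg)

summary = quant_io.read_tidy(out / "scores_summary.tsv")
gt = quant_io.read_tidy(out / "ground_truth.tsv")
m = summary.merge(gt[["protein_id", "group"]], on="protein_id")
late = m[(m.label == "light") & (m.time_min == 270)]
print(late.groupby("group")[["abundance_score", "stability_score"]].median().round(2))
```

```
                     abundance_score  stability_score
group
mito_import_blocked            -0.80            -0.35
null                            0.01            -0.19
ribosome_stabilized            -0.01             2.77
ups_induced                     0.33            -0.74
```

At 270 min the simulated effect classes separate the way the assay is
designed to read them: proteins whose degradation accelerates under
import stress (`mito_import_blocked`, kd x1.5) lose pre-existing
(light) abundance (-0.80 log2), thermally stabilized ribosomal
proteins (+2 degC Tm shift) stand out in the stability score (+2.77)
with no abundance change, and the null class sits near zero in both.
On the same run, `tests.tsv` contains 198 stability calls at q < 0.05
and `rates.tsv` a median dKD of 1.02 (most proteins are null).

The same pipeline is available from the shell:

```sh
pptpp simulate --n-proteins 300 --seed 7 --out-dir sim/
pptpp run --config pipeline.yaml
```

with subcommands `preprocess`, `score`, `test`, `turnover`, `classify`
for the individual stages. All tables are TSV with `NA` for missing;
re-running with an identical configuration and seed reproduces every
output byte for byte.

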