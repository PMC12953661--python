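# lesionnet

Structural-connectome analysis of cognitive impairment in multicenter
cohorts: lesion-based disconnection indices, FA-weighted graph metrics,
heteroscedastic normative z-scoring, robust group comparisons, univariable
odds-ratio models with a balanced downsampled bootstrap, and
bootstrap-stabilized elastic-net selection — exercised end-to-end on
synthetic multicenter cohorts with known injected effects.

## Modules

| module | what it does |
| --- | --- |
| `lesionnet.synthetic` | multicenter cohorts, metric tables with injected group shifts, toy parcellations/tractograms/lesion masks |
| `lesionnet.connectome` | endpoint assignment, count/FA connectivity matrices, streamline–lesion intersection, intra-/inter-hemispheric disconnection indices, commissural ratio |
| `lesionnet.metrics` | density, mean strength, global efficiency (1/w lengths), Onnela clustering, modularity (exact ≤ 8 nodes, seeded Louvain otherwise), intra-hemispheric efficiency, conservation ratio |
| `lesionnet.normative` | feasible-GLS reference models (sex, age, sex×age, center; per-center residual SDs) and patient z-scores |
| `lesionnet.compare` | chi-square/Fisher/Mann–Whitney, robust (Huber) z-score models, log-LV comparison with delta-method back-transform, quasi-binomial disconnection models, BH-FDR |
| `lesionnet.associations` | sandwich-SE logistic ORs with unit scalings (per 10% LV, per %, per z), interaction tests, balanced downsampled bootstrap |
| `lesionnet.selection` | elastic-net logistic regression (own coordinate-descent solver with unpenalized center indicators), 1-SE tuning, rank-based AUC, bootstrap selection frequencies |
| `lesionnet.pipeline` / `lesionnet.cli` | orchestration, TSV/NIfTI/TCK/JSONL/YAML I/O, run manifest |

Two conventions the literature leaves ambiguous are explicit switches:
the disconnection denominator (class-specific by default, all-assigned via
`class_denominator=False`) and the elastic-net mixing parameter
(`alpha=0.5` default, `alpha_sensitivity` sweep available). The
"conservation ratio over intra-hemispheric efficiency" z-score is the z of
the raw ratio, not a ratio of z's.

## CLI

```bash
lesionnet simulate --seed 1 --out-dir out/
lesionnet zscore --cohort out/cohort.tsv --metrics out/metrics.tsv --out out/z.tsv
lesionnet compare --cohort out/cohort.tsv --metrics out/metrics.tsv --zscores out/z.tsv --out out/table2.tsv
lesionnet associate --cohort out/cohort.tsv --metrics out/metrics.tsv --zscores out/z.tsv \
    --reps 5000 --n-per-group 80 --seed 1 --out out/table3.tsv
lesionnet select --cohort out/cohort.tsv --metrics out/metrics.tsv --zscores out/z.tsv \
    --alpha 0.5 --seed 1 --out out/table4.tsv
lesionnet run-all --seed 1 --boot-reps 500 --out-dir out/
lesionnet build-connectome --tck t.tck --parcellation p.nii.gz --nodes nodes.tsv \
    --lesions l.nii.gz --out-dir conn/
lesionnet metrics --connectome conn/fa.tsv --nodes conn/nodes.tsv --reps 100 --seed 1 --out m.tsv
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 convergence
error.

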