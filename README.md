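# daposcope

Pan-stage analytics for **differentiation-associated pseudogenes (DaPs)**
in oesophageal carcinoma (ESCA): stage-wise expression-pattern set
algebra, enrichment-overlap metrics, binarized Bayesian gene-regulatory
networks, combinatorial patient stratification, APOBEC-centric
mutation-landscape analytics and motif-discovery sequence preparation —
all exercised end-to-end on seeded synthetic data with planted,
recoverable ground truth.

## Who it is for

Researchers dissecting how pseudogene de-regulation tracks tumour stage.
Bulk RNA-seq cohorts with per-sample stage labels (normal, SI–SIV) are
partitioned into genes de-regulated **constitutively** (every stage, one
direction), **stage-specifically** (exactly one stage) or across
multiple stages, and the downstream modules quantify what those patterns
imply for cellular reprogramming, differentiation, network robustness
and the somatic mutation landscape.

## The statistics at the core

For stage sets `GS_i` over `S` stages:

```
Constitutive gene set      = ⋂_{i=1..S} GS_i        (per direction)
Stage-specific set (i)     = GS_i \ ⋃_{n≠i} (GS_i ∩ GS_n)
```

Three summary metrics sit on top of gene-set enrichment:

* **Enriched degree of differentiation** — mean over enrichment modules
  of `G/P`, where `G` counts genes overlapping ≥ 2 retained terms of the
  module's leading-edge analysis and `P` counts the terms containing
  such genes.
* **Degree of pleiotropy** — the same `G/P` average over
  expression-independent (over-representation) enrichment modules.
* **SD/SL reprogramming ratio** — retained stomach/duodenum (adult)
  cell signatures over small/large-intestine (embryonic) signatures; a
  proxy for the rate of reprogramming towards non-oesophageal GI fates.

Per-stage regulatory networks come from median-binarized expression
(0 below/at the gene's median, 1 above), greedy hill-climbing Bayesian
structure search under the BIC score, and a dual Pearson/Spearman
correlation filter with three edge-confidence levels (thin / medium /
thick at |r|, |ρ| ≥ 0.89). Tumour samples are stratified by the Boolean
rule `median(up-DaP states) ≥ 0.5 AND median(down-DaP states) = 0`
(`UDaP_Combo` vs `UDaP_No_Combo`). Mutation analytics cover the six
pyrimidine-normalized substitution classes, tCw/cCw APOBEC motif
fractions, kataegis (≥ 6 substitutions, mean inter-mutation distance
≤ 1 kb), the MATH heterogeneity score
`100 · 1.4826 · MAD(VAF) / median(VAF)`, and NMF mutational signatures
over the 96 trinucleotide channels with cophenetic rank selection.

## Worked example

```python
>>> from daposcope import datasets, genesets, metrics
>>> m = datasets.dap_stage_table()          # 45 DaPs x 4 stages, signed
>>> c = genesets.constitutive_set(m)
>>> len(c), len(c.up), len(c.down)
(14, 4, 10)
>>> sii = genesets.stage_specific_set(m, "SII")
>>> sorted(sii.up)
['DNAJB3', 'DUX4L9', 'FSCN1P1', 'GTF2IRD2P1', 'KRT17P1', 'KRT17P2', 'MAGEA5P', 'TPRXL']
>>> rep = metrics.degree_of_differentiation(
...     datasets.differentiation_overlap_counts("SII"))
>>> round(rep.average, 3)
2.704
```

Of the 45 surveyed DaPs, 14 are de-regulated in every stage (4 up, 10
down) and 31 in exactly one stage; stage II carries the largest
stage-specific up-regulated block (8 genes) and the highest enriched
degree of differentiation (2.704), the signature of its uniquely
reprogrammed tumour landscape.

The full synthetic pipeline (simulate → DE → partition → GSEA → metrics
→ GRN → stratify → mutations → motif prep) runs from the command line:

```bash
daposcope run --seed 0 --outdir run0     # ~2 s, writes run_report.json
```

## Layout

| module | contents |
| --- | --- |
| `synthetic` | seeded generators with planted ground truth (counts, MAF, gene sets, sequences) |
| `dge` | median-of-ratios normalization, rank-sum DE calling with the dual cut-off (padj ≤ 0.05, \|log2FC\| ≥ 1.5) |
| `genesets` | constitutive / stage-specific / multi-stage set algebra, DaP/PiG/DaCG/miRNA classification |
| `enrichment` | minimal GSEA (signal-to-noise ranking, running-sum ES, gene-set permutation NES/FDR), leading-edge overlap, hypergeometric ORA |
| `metrics` | degree of differentiation, degree of pleiotropy, SD/SL ratio, GI fraction |
| `grn` | median binarization, BIC hill-climbing structure search, correlation edge filter, density + six centralities with pseudogene knock-out |
| `stratify` | UDaP_Combo / UDaP_No_Combo Boolean stratification, cohort splitting |
| `mutations` | substitution classes, APOBEC motifs, kataegis, MATH, NMF signatures |
| `motifprep` | TSS-centred (±2000 bp) and sliding (462 bp / 52 bp overlap) windows |
| `pipeline`, `cli` | config-driven orchestration and the `daposcope` command |
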