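# nutrinet

Differential expression/dispersion and miRNA–mRNA co-expression network
analysis for two-group bulk transcriptome contrasts, built around a
fasting-vs-fed skeletal-muscle study design: three RNA biotypes (mRNA,
miRNA, lincRNA) quantified in a fasted group (n = 11) and a fed group
(n = 12), with the goal of finding genes whose **mean** expression or
expression **variability** responds to nutrient supply, the miRNAs that
plausibly drive those changes, and co-expression modules associated with
meat-quality phenotypes.

It is written for computational biologists who want each stage of that
workflow as a tested, reusable Python component — and, because the
original sequencing data are not needed, every stage is exercisable
against a synthetic-data generator that plants a known truth (DE genes,
dispersion shifts, repressor miRNAs with seed-matched targets,
co-expression blocks coupled to traits) and lets you measure recovery.

## What the pipeline computes

1. **Preprocessing** — TMM (trimmed mean of M-values) normalisation,
   counts per million, per-gene capping of outliers beyond 1.5·IQR to the
   10th/90th percentiles, and the expressed-gene filter CPM > 1 in ≥ 50%
   of samples (lincRNAs exempt).
2. **Differential expression** — per-gene negative binomial with variance
   μ + φμ², conditional-ML common/tagwise dispersion (BCV = √φ), exact
   conditional test of the group sums, BH correction; DE at q < 0.05 and
   |FC| > 1.5 (relaxed 1.2 for non-coding RNAs).
3. **Differential dispersion** — per-gene likelihood-ratio test of
   group-specific φ against shared φ (group-specific means and library
   offsets in both models, Cox–Reid adjusted), BY correction.
4. **PCIT network** — for every gene trio the first-order partials
   r_xy·z = (r_xy − r_xz r_yz)/√((1−r_xz²)(1−r_yz²)) give a tolerance
   ε = mean(partial/direct); edge x–y survives unless some z makes
   |r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|. Surviving miRNA→mRNA edges
   need r < −0.5 (miRNAs assumed repressors); mRNA–mRNA edges |r| > 0.7.
5. **Seed validation** — a miRNA→mRNA edge is kept only if the reverse
   complement of mature-miRNA positions 2–8 occurs verbatim in the
   target's 3′-UTR (perfect 7mer-m8 site).
6. **Regulator and hub scoring** — per regulator i over DE genes j:

       PIF_j  = ½(e1_j² − e2_j²)
       DW_ij  = r1_ij − r2_ij
       RIF1_i = (1/n_de) Σ_j PIF_j · DW_ij²
       RIF2_i = (1/n_de) Σ_j [(e1_j r1_ij)² − (e2_j r2_ij)²]

   and the connectivity hub score K_i = x_i / X̄ (edges of gene i over the
   network's mean degree, so mean K = 1).
7. **Modules and traits** — signed adjacency ((1+r)/2)^16, topological
   overlap, average-linkage clustering of 1−TOM with min module size 30
   and eigengene merging at height 0.25; module eigengenes (first PC),
   module–trait Pearson correlation with Student asymptotic p-values,
   per-gene trait significance, scaled Kleinberg hub centrality.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (about 15 s total):

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_differential.py
python analysis/04_network.py
python analysis/05_modules.py
```

`03_differential.py` prints, for the default dataset (580 genes, 11 + 12
samples, biotype BCVs 0.53/0.37/1.15):

```
DE: called 39 of 579 (recall 0.64, FDP 0.08)
synthetic mRNA DE proportion: 7.40%
DD: called 0 (planted 28; power is limited at n = 11/12 with BY correction)

published worked examples, recomputed:
  DE proportion mrna_fasted_fed5h: 1.39%
  DE proportion mrna_fasted_fed7h: 4.06%
  DE proportion mirna_fasted_fed5h: 2.09%
  DE proportion mirna_fasted_fed7h: 9.79%
  mean |FC| of fasted/fed-5h DE miRNAs: 1.94 (~1.9-fold)
```

i.e. 39 genes are called DE (planted truth gives 64% recall at an 8%
false-discovery proportion — power, not correctness, limits recall at
these BCVs), no dispersion shifts survive BY correction at this sample
size, and the published per-contrast summary statistics are reproduced
exactly from their printed inputs. `04_network.py` then reports the
seed-validated network (zero false validations by construction) and
`05_modules.py` the planted-block recovery (ARI ≈ 0.96) with every
coupled trait significantly associated with its module.

The same pipeline is available as a CLI (`nutrinet simulate`,
`nutrinet run-all --config pipeline.yaml`, plus per-stage subcommands;
`nutrinet init-config` writes a template) or as one library call:

```python
from nutrinet import PipelineConfig, run_contrast
result = run_contrast(PipelineConfig(counts="counts.tsv", ...))
```

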