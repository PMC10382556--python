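# driftscan

Population-genetic analysis of multi-breed SNP genotype panels:
diversity and differentiation statistics, LD-based effective population
size, runs of homozygosity, and a composite selection-signature scan
(FST + FLK + xp-EHH combined by DCMS), together with a forward
Wright-Fisher simulator that makes every stage testable without external
data.

## Layout

| module | contents |
| --- | --- |
| `driftscan.genotype_io` | dosage-matrix data model, PLINK text / VCF readers and writers, multi-chip merging on locus intersections |
| `driftscan.qc` | call-rate, MAF and exact-HWE filters, PLINK-style IBD moments, greedy relatedness pruning, sliding-window LD pruning |
| `driftscan.diversity` | allele frequencies, AFD, chord and Reynolds distances, Weir-Cockerham FST (per SNP + multilocus with bootstrap CI), Z(FST), LD-decay curve |
| `driftscan.structure` | PCA on scaled dosages, LOF outlier removal, IBS dissimilarity, average-linkage dendrogram with Newick export |
| `driftscan.ne_estimation` | contemporary LD-Ne from inter-chromosomal pairs (bias-corrected, chromosome-jackknife CI), historical Ne from distance-binned LD |
| `driftscan.roh` | sliding-window ROH detection, length classes, F_ROH, shared-ROH incidence peaks |
| `driftscan.selection_scan` | NJ population tree and kinship, FLK, EHH/iHH/xp-EHH, fractional-rank p-values, MCD correlation, DCMS, robust-normal calibration, BH FDR |
| `driftscan.annotation` | +/-40 kb interval overlap of significant regions with genes/QTL, hypergeometric gene-set enrichment |
| `driftscan.synthetic_data` | forward Wright-Fisher simulator (drift, recombination, sweeps, planted relatives) with PLINK/VCF export and truth records |
| `driftscan.pipeline` / `driftscan.cli` | end-to-end orchestration from one YAML config; `driftscan` console script |

## CLI

```bash
driftscan simulate --out sim_data --seed 1 --populations 2 --ne 100
driftscan demo --out demo_data --seed 0     # 4-population tutorial dataset
driftscan run-all config.yaml               # full pipeline
```

A minimal `config.yaml`:

```yaml
out_dir: results
seed: 1
simulate:
  n_populations: 2
  ne_per_population: 300
  generations_divergence: 12
  n_chromosomes: 2
  n_snps_per_chrom: 400
  sample_sizes: [25, 25]
```

Real data can be supplied instead with `ped:`/`map:` or `vcf:` (phased VCF
enables the xp-EHH stage). QC thresholds default to call rate 0.90,
MAF 0.01, HWE 1e-6, pi-hat 0.25; LD pruning 50/5 with r^2 0.5 (PCA) or
0.3 (relatedness); ROH window 15 / minSNP 20 / threshold 0.05 /
density 1 SNP per 168 kb / max gap 1 Mb / min length 500 kb; annotation
flank 40 kb; FDR 0.05. All are config keys.

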