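# dpcseq

Analysis toolkit for **DPC-seq**: genome-wide mapping of DNA–protein
crosslinks (DPCs) and of their removal by transcription-coupled repair.

Aldehydes such as formaldehyde covalently crosslink proteins — above all
nucleosomal histones — to DNA. DPC-seq isolates protein-conjugated DNA
(KCl/SDS precipitation after denaturing lysis) and sequences it, so read
coverage marks crosslink-bearing fragments. Comparing libraries harvested
right after crosslinking (0 h) with libraries harvested after a recovery
period measures, gene by gene, how fast cells clear these lesions — and
whether clearance tracks transcription (the signature of transcription-coupled
repair, which requires CSB).

The package is aimed at analysts of damage-mapping sequencing data. It covers
the full downstream path from aligned reads to figure-style statistics, plus a
generative simulator with closed-form expectations so that every stage can be
tested without any external dataset.

## What it computes

For a filtered gene universe (longest transcript per gene, overlapping genes
excluded, mitochondrial — and in mouse, sex-chromosome — genes removed):

* **Normalized coverage.** Per-gene counts C_g with two normalizations:
  CPM = C_g / N_mapped × 10⁶, and *reads per gene length per million*,
  S_g = (C_g / L_g) / Σ_h (C_h / L_h) × 10⁶, whose per-sample total is
  exactly 10⁶.
* **Residual ratios.** R_g = CPM_g(t) / CPM_g(0 h): 1 means no removal, → 0
  complete removal. Summaries per TPM bin and per gene-length bin with the
  replicate as the unit of error (mean ± s.e.m., n = 3), TSS-vs-TES 1-kb
  window contrasts, and two-sided unpaired t-tests between conditions.
* **Metagene profiles.** Scale-regions matrices (gene body in 100 bins,
  ±2 kb flanks in 50-bp bins, rows oriented 5′→3′) and averaged profiles,
  including detection of the promoter nucleosome-free (NFR) dip.
* **Removal kinetics.** The simulator deposits crosslinks with nucleosomal
  (147-bp core / linker) periodicity, depletes active promoters, and removes
  them with per-position hazard
  k_b + γ·k_max·TPM/(TPM+K)·exp(−d_TSS/λ_w);
  the expected per-gene residual has a closed form (exponential-integral
  E1 per segment) which `estimate_removal_parameters` inverts to recover
  (k_max, λ_w, k_b) from coverage data.

## Worked example

The numbered scripts under `analysis/` reproduce the whole study on
synthetic data (about four minutes in total):

```
python analysis/01_simulate.py        # 12 libraries, 2,000 genes, seed 1
python analysis/02_quantify.py        # counting + normalization + QC
python analysis/03_residual_ratios.py # binned repair statistics
python analysis/04_metagene.py        # promoter-dip profiles
python analysis/05_fit_removal.py     # kinetic parameter recovery
```

`analysis/03_residual_ratios.py` prints, among other tables:

```
mean residual ratio by TPM bin (WT, 4 h / 0 h):
   bin  n_genes     mean      sem
 0.1-1      345 0.985993 0.002436
  1-10      610 0.756963 0.002651
10-100      327 0.506784 0.002473
 >=100       59 0.457622 0.003938

TSS vs TES windows, genes >= 200 kb (TPM >= 30): TSS 0.066 +/- 0.024
vs TES 0.759 +/- 0.024 (p = 3.58e-05)
```

Reading: residual DPC signal falls monotonically with expression (transcribed
genes clear crosslinks faster), and in very long genes the TSS-proximal
kilobase is cleared long before the TES-proximal one — removal spreads from
the TSS. `05_fit_removal.py` then recovers k_max = 0.81/h and λ_w = 11.8 kb
from the wild-type libraries (truth 1.0/h and 10 kb) and a CSB-deficient
k_max of 6.8% of wild type (truth: genotype factor 5%).

A `dpcseq` console command exposes the same steps
(`dpcseq simulate | quantify | residual | metagene | report`) for running on
real BED/BAM inputs with a YAML sample sheet.

## Layout

```
src/dpcseq/        library (annotation, coverage, metrics, metagene,
                   simulate, pipeline, cli)
analysis/          numbered narrative drivers writing to results/
tests/             pytest suite incl. end-to-end acceptance checks
docs/methods.md    model, parameter and design documentation
```
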