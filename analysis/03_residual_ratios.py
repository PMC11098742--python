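"""Residual-ratio statistics: the repair-kinetics readout.

Computes per-gene 4 h / 0 h residual ratios for wild-type and CSB-deficient
libraries and summarizes them the way the assay is read out: four TPM bins,
seven gene-length bins among TPM >= 100 genes, the TSS-vs-TES 1-kb-window
contrast across gene-length bins, and a WT-vs-dCSB test in the top TPM bin.
Writes tidy tables under results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from dpcseq.annotation import (BinningScheme, assign_bins,  # noqa: E402
                               length_bins_default, tpm_bins_default)
from dpcseq.coverage import count_overlaps, load_reads  # noqa: E402
from dpcseq.metrics import (residual_ratio, spearman_residual_tpm,  # noqa: E402
                            summarize_by_bin, tss_tes_residual,
                            unpaired_t_test)
from dpcseq.annotation import geneset_from_bed6  # noqa: E402


def main() -> None:
    bundle = ROOT / "scratch" / "sim_bundle"
    if not bundle.exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    genes = geneset_from_bed6(bundle / "genes.bed",
                              tpm=pd.read_csv(bundle / "tpm.tsv", sep="\t")
                              .set_index("gene_id")["tpm"].to_dict())
    reads = {}
    for bed in sorted((bundle / "reads").glob("*.bed")):
        cond, t_part, rep_part = bed.stem.rsplit("_", 2)
        reads[bed.stem] = load_reads(bed, condition=cond,
                                     time_h=float(t_part[1:-1]),
                                     replicate=int(rep_part[3:]))
    counts = {k: count_overlaps(rs, genes) for k, rs in reads.items()}

    def rts(cond):
        return [residual_ratio(counts[f"{cond}_t4h_rep{r}"],
                               counts[f"{cond}_t0h_rep{r}"])
                for r in (1, 2, 3)]

    wt, dcsb = rts("WT"), rts("dCSB")
    rho, n = spearman_residual_tpm(wt[0], genes, tpm_min=0.1)
    print(f"Spearman rho(residual, TPM) over {n} genes with TPM >= 0.1: "
          f"{rho:.3f}")

    out = ROOT / "results"
    rows = []
    tpm_scheme = tpm_bins_default(4)
    len_scheme = BinningScheme("length", length_bins_default().edges,
                               min_tpm_filter=100.0)
    for cond, r in (("WT", wt), ("dCSB", dcsb)):
        for scheme, kind in ((tpm_scheme, "tpm"), (len_scheme, "length")):
            bins = assign_bins(genes, scheme)
            s = summarize_by_bin(r, bins, bin_order=scheme.labels)
            s.insert(0, "condition", cond)
            s.insert(1, "binning", kind)
            rows.append(s.drop(columns="replicate_means"))
    summary = pd.concat(rows, ignore_index=True)
    summary.to_csv(out / "03_residual_bins.tsv", sep="\t", index=False,
                   float_format="%.4g")
    print("\nmean residual ratio by TPM bin (WT, 4 h / 0 h):")
    print(summary.query("condition == 'WT' and binning == 'tpm'")
          [["bin", "n_genes", "mean", "sem"]].to_string(index=False))
    print("\nmean residual ratio by gene-length bin, TPM >= 100:")
    print(summary.query("binning == 'length'")
          [["condition", "bin", "n_genes", "mean", "sem"]]
          .to_string(index=False))

    # top-TPM-bin WT vs dCSB
    bins = assign_bins(genes, tpm_scheme)
    top = tpm_scheme.labels[-1]
    def top_means(r):
        s = summarize_by_bin(r, bins, bin_order=[top])
        return [m for m in s["replicate_means"].iloc[0] if not np.isnan(m)]
    t = unpaired_t_test(top_means(dcsb), top_means(wt))
    print(f"\nWT vs dCSB in TPM {top}: t = {t.statistic:.2f}, "
          f"df = {t.df}, p = {t.pvalue:.2e}")

    tt = tss_tes_residual([reads[f"WT_t4h_rep{r}"] for r in (1, 2, 3)],
                          [reads[f"WT_t0h_rep{r}"] for r in (1, 2, 3)],
                          genes,
                          BinningScheme("length", length_bins_default().edges),
                          tpm_min=30.0)
    tt.drop(columns="replicate_means").to_csv(
        out / "03_tss_tes_residuals.tsv", sep="\t", index=False,
        float_format="%.4g")
    last = tt[tt["bin"] == ">=200 kb"].set_index("kind")
    print(f"\nTSS vs TES windows, genes >= 200 kb (TPM >= 30): "
          f"TSS {last.loc['TSS', 'mean']:.3f} +/- {last.loc['TSS', 'sem']:.3f}"
          f" vs TES {last.loc['TES', 'mean']:.3f} +/- "
          f"{last.loc['TES', 'sem']:.3f} (p = "
          f"{last.loc['TES', 'tes_vs_tss_p']:.2e})")


if __name__ == "__main__":
    sys.exit(main())
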