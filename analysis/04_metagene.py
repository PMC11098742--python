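"""Scaled-region metagene profiles: promoter nucleosome-free dip.

Builds the 0 h and 4 h wild-type mean profiles for highly expressed
(TPM >= 30) and weakly expressed (0.1 <= TPM < 1) genes, in per-bp fragment
density so flank and body columns share units, and quantifies the promoter
dip near the TSS.  Profiles go to results/.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from dpcseq.annotation import geneset_from_bed6  # noqa: E402
from dpcseq.coverage import load_reads  # noqa: E402
from dpcseq.metagene import (ProfileConfig, average_profiles,  # noqa: E402
                             nfr_dip, scaled_region_matrix)


def main() -> None:
    bundle = ROOT / "scratch" / "sim_bundle"
    if not bundle.exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    genes = geneset_from_bed6(bundle / "genes.bed",
                              tpm=pd.read_csv(bundle / "tpm.tsv", sep="\t")
                              .set_index("gene_id")["tpm"].to_dict())
    sizes = dict(line.split("\t") for line in
                 (bundle / "chrom.sizes").read_text().splitlines())
    sizes = {k: int(v) for k, v in sizes.items()}
    out = ROOT / "results"
    for t in (0.0, 4.0):
        reads = [load_reads(bundle / "reads" / f"WT_t{t:g}h_rep{r}.bed")
                 for r in (1, 2, 3)]
        for lo, hi, tag in [(30.0, None, "tpm_ge30"),
                            (0.1, 1.0, "tpm_0.1_1")]:
            cfg = ProfileConfig(tpm_min=lo, tpm_max=hi, midpoint_mode=True,
                                per_bp=True)
            prof = average_profiles([
                scaled_region_matrix(rs, genes, cfg, chrom_sizes=sizes)
                for rs in reads])
            prof.to_csv(out / f"04_metagene_WT_t{t:g}h_{tag}.tsv", sep="\t",
                        index=False, float_format="%.5g")
            dip = nfr_dip(prof, cfg)
            print(f"WT t={t:g}h {tag}: min at TSS{dip['argmin_offset']:+d} "
                  f"bins, dip depth {dip['dip_depth']:.2f} "
                  f"(body mean {dip['body_mean']:.4g} per bp)")


if __name__ == "__main__":
    sys.exit(main())
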