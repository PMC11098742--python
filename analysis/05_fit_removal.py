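"""Invert the removal model: recover kinetic parameters from coverage.

Fits (k_max, lambda_w, k_b) to the wild-type and CSB-deficient residual
ratios by weighted least squares on log residuals against the closed-form
expected residual, after rescaling the observed library-share ratios by the
known genome-wide surviving fraction.  Compares fits to the generative truth
and writes the comparison to results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from dpcseq.annotation import geneset_from_bed6  # noqa: E402
from dpcseq.coverage import count_overlaps, load_reads  # noqa: E402
from dpcseq.metrics import estimate_removal_parameters, residual_ratio  # noqa: E402
from dpcseq.simulate import SimParams, load_truth  # noqa: E402


def main() -> None:
    bundle = ROOT / "scratch" / "sim_bundle"
    if not bundle.exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    truth = load_truth(bundle / "truth.json")
    params = SimParams(**{k: v for k, v in truth["params"].items()})
    genes = geneset_from_bed6(bundle / "genes.bed",
                              tpm=pd.read_csv(bundle / "tpm.tsv", sep="\t")
                              .set_index("gene_id")["tpm"].to_dict())
    result = {}
    fits = {}
    for cond in ("WT", "dCSB"):
        rts = []
        for r in (1, 2, 3):
            c4 = count_overlaps(
                load_reads(bundle / "reads" / f"{cond}_t4h_rep{r}.bed"),
                genes)
            c0 = count_overlaps(
                load_reads(bundle / "reads" / f"{cond}_t0h_rep{r}.bed"),
                genes)
            rts.append(residual_ratio(c4, c0))
        fit = estimate_removal_parameters(
            rts, genes, params, t=4.0,
            global_factor=truth["global_survival"][f"{cond}_t4h"])
        fits[cond] = fit
        result[cond] = {"k_max": fit.k_max, "lam_w": fit.lam_w,
                        "k_b": fit.k_b, "n_genes": fit.n_genes,
                        "converged": fit.converged}
        print(f"{cond}: k_max = {fit.k_max:.3f}/h, lambda_w = "
              f"{fit.lam_w/1e3:.1f} kb, k_b = {fit.k_b:.4f}/h "
              f"({fit.n_genes} genes)")
    gamma = params.genotype_factors["dCSB"]
    result["truth"] = {"k_max": params.k_max, "lam_w": params.lam_w,
                       "k_b": params.k_b, "gamma_dCSB": gamma}
    print(f"truth: k_max = {params.k_max:.3f}/h, lambda_w = "
          f"{params.lam_w/1e3:.1f} kb, k_b = {params.k_b:.4f}/h; "
          f"dCSB genotype factor {gamma}")
    print(f"fitted dCSB/WT k_max ratio: "
          f"{fits['dCSB'].k_max / fits['WT'].k_max:.3f} "
          f"(truth {gamma})")
    with open(ROOT / "results" / "05_removal_fit.json", "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    sys.exit(main())
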