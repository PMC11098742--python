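"""Count and normalize every simulated library.

Loads the bundle written by 01_simulate.py, counts reads per gene, and
applies both normalizations (CPM and reads-per-gene-length-per-million whose
per-sample total is 1e6).  The per-sample QC tallies go to results/; the full
per-gene count table stays under scratch/ (it is ~0.5 MB).
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from dpcseq.pipeline import RunConfig, SampleSpec, quantify  # noqa: E402


def bundle_samples(bundle: Path):
    out = []
    for bed in sorted((bundle / "reads").glob("*.bed")):
        cond, t_part, rep_part = bed.stem.rsplit("_", 2)
        out.append(SampleSpec(str(bed), cond, float(t_part[1:-1]),
                              int(rep_part.replace("rep", ""))))
    return out


def main() -> None:
    bundle = ROOT / "scratch" / "sim_bundle"
    if not bundle.exists():
        print("run analysis/01_simulate.py first", file=sys.stderr)
        return 1
    cfg = RunConfig(genes_bed=str(bundle / "genes.bed"),
                    expression=str(bundle / "tpm.tsv"),
                    samples=bundle_samples(bundle),
                    out_dir=str(ROOT / "scratch" / "quant"))
    genes, counts, qc = quantify(cfg)
    print(f"{qc['n_genes']} genes quantified in {len(counts)} libraries")
    for sid, s in sorted(qc["samples"].items()):
        print(f"  {sid}: {s['n_mapped']:,} mapped, {s['genic_reads']:,} genic, "
              f"score total {s['score_total']:.6g}")
    with open(ROOT / "results" / "02_quantify_qc.json", "w") as fh:
        json.dump(qc, fh, indent=1, sort_keys=True)


if __name__ == "__main__":
    sys.exit(main())
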