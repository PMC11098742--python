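import numpy as np
import pandas as pd
import pytest

from dpcseq.annotation import GeneSet
from dpcseq.coverage import ReadSet


def make_geneset(rows, species_mode="human"):
    """rows: (gene_id, chrom, start, end, strand[, tpm])"""
    recs = []
    for r in rows:
        tpm = r[5] if len(r) > 5 else np.nan
        recs.append(dict(gene_id=r[0], chrom=r[1], start=r[2], end=r[3],
                         strand=r[4], tpm=tpm))
    cols = ["gene_id", "chrom", "start", "end", "strand", "tpm"]
    df = pd.DataFrame(recs, columns=cols)
    return GeneSet(df, species_mode=species_mode)


def make_reads(rows, sample_id="s", **labels):
    """rows: (chrom, start, end[, strand])"""
    recs = [dict(chrom=r[0], start=r[1], end=r[2],
                 strand=r[3] if len(r) > 3 else ".") for r in rows]
    return ReadSet(sample_id, pd.DataFrame(recs), **labels)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n, genome=100_000, max_len=500, chrom="chr1"):
    start = rng.integers(0, genome - max_len, n)
    length = rng.integers(1, max_len, n)
    return pd.DataFrame({"chrom": chrom, "start": start,
                         "end": start + length, "strand": "."})


def brute_force_overlap_counts(reads: pd.DataFrame,
                               regions: pd.DataFrame) -> np.ndarray:
    """Quadratic all-pairs >=1 bp overlap oracle (half-open intervals)."""
    out = np.zeros(len(regions), dtype=int)
    for i, reg in enumerate(regions.itertuples(index=False)):
        for rd in reads.itertuples(index=False):
            if rd.chrom == reg.chrom and rd.start < reg.end and rd.end > reg.start:
                out[i] += 1
    return out
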