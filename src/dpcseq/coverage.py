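"""Read-interval ingestion, per-gene/window counting, and normalization.

A DPC-seq library is represented as a set of deduplicated genomic intervals
(one per sequenced fragment).  Counting is strand-blind with a >=1 bp overlap
rule (half-open intervals), matching bedtools semantics.  Two depth
normalizations are provided:

* CPM: counts per million mapped reads, ``C_g / N_mapped * 1e6``;
* RPGLPM ("reads per gene length per million"): counts divided by gene length
  and rescaled so every sample's total is exactly 1e6.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneSet

logger = logging.getLogger(__name__)

READ_COLUMNS = ["chrom", "start", "end", "strand"]


@dataclass
class ReadSet:
    """Deduplicated intervals from one sequenced sample
    (condition x recovery time x replicate)."""

    sample_id: str
    intervals: pd.DataFrame            # chrom, start, end, strand[, mapq]
    condition: str = ""
    time_h: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        df = self.intervals
        missing = [c for c in READ_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"ReadSet missing columns {missing}")
        if self.time_h < 0:
            raise ValueError("time_h must be >= 0")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if len(df) and (df["start"] >= df["end"]).any():
            raise ValueError("read intervals must satisfy start < end")
        self.intervals = df.reset_index(drop=True)

    @property
    def n_mapped(self) -> int:
        return len(self.intervals)

    def to_bed6(self, path: str | Path) -> None:
        df = self.intervals
        name = df["name"] if "name" in df.columns else [
            f"read{i}" for i in range(len(df))]
        score = df["mapq"].fillna(0).astype(int) if "mapq" in df.columns else 0
        bed = pd.DataFrame({"chrom": df["chrom"], "start": df["start"],
                            "end": df["end"], "name": name, "score": score,
                            "strand": df["strand"]})
        bed.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CountTable:
    """Per-region raw read counts for one sample.  ``counts`` is indexed by
    gene_id (or by (gene_id, window kind) for window counts)."""

    sample_id: str
    counts: pd.Series
    n_mapped: int
    condition: str = ""
    time_h: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative counts")


@dataclass
class NormalizedTable:
    """Per-gene scores on the reads-per-gene-length-per-million scale: the
    per-sample score total is exactly 1e6 whenever any count is positive."""

    sample_id: str
    scores: pd.Series
    n_mapped: int
    condition: str = ""
    time_h: float = 0.0
    replicate: int = 1


# ---------------------------------------------------------------------------
# loading

def load_reads(path: str | Path, mapq_min: int = 20, dedup: bool = True,
               sample_id: str | None = None, **labels) -> ReadSet:
    """Load aligned-read intervals from BED6 or SAM/BAM.

    BED input carries no mapping quality, so ``mapq_min`` does not apply to
    it; SAM/BAM records with mapq < mapq_min are dropped (threshold
    inclusive).  ``dedup`` collapses identical (chrom, start, end, strand)
    tuples, a minimal interval-level duplicate removal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".bam", ".sam", ".cram"}:
        df = _load_alignments(path, mapq_min)
    else:
        if path.stat().st_size == 0:
            logger.warning("%s: empty read file", path)
            df = pd.DataFrame(columns=READ_COLUMNS)
        else:
            bed = pd.read_csv(path, sep="\t", header=None,
                              names=["chrom", "start", "end", "name",
                                     "score", "strand"],
                              dtype={"chrom": str})
            df = bed[["chrom", "start", "end", "strand"]].copy()
            df["strand"] = df["strand"].fillna(".")
    n_before = len(df)
    if dedup and n_before:
        df = df.drop_duplicates(["chrom", "start", "end", "strand"])
    if n_before and len(df) < n_before:
        logger.info("%s: removed %d duplicate intervals", path,
                    n_before - len(df))
    return ReadSet(sample_id or path.stem, df.reset_index(drop=True), **labels)


def _load_alignments(path: Path, mapq_min: int) -> pd.DataFrame:
    import pysam

    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    rows = []
    with pysam.AlignmentFile(str(path), mode) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.mapping_quality < mapq_min:
                continue
            rows.append((rec.reference_name, rec.reference_start,
                         rec.reference_end, "-" if rec.is_reverse else "+",
                         rec.mapping_quality))
    return pd.DataFrame(rows, columns=READ_COLUMNS + ["mapq"])


# ---------------------------------------------------------------------------
# counting

def _interval_counts(reads: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Number of read intervals overlapping each region by >=1 bp.

    Half-open intervals: read [s,e) overlaps region [a,b) iff s < b and e > a.
    Per chromosome, with sorted read starts S and ends E, that count is
    ``#{S < b} - #{E <= a}`` (every read with end <= a also starts before b).
    Regions may overlap each other freely.
    """
    out = np.zeros(len(regions), dtype=np.int64)
    by_chrom = {c: sub for c, sub in reads.groupby("chrom", sort=False)}
    for chrom, sub in regions.groupby("chrom", sort=False):
        r = by_chrom.get(chrom)
        if r is None:
            continue
        starts = np.sort(r["start"].to_numpy())
        ends = np.sort(r["end"].to_numpy())
        a = sub["start"].to_numpy()
        b = sub["end"].to_numpy()
        cnt = (np.searchsorted(starts, b, side="left")
               - np.searchsorted(ends, a, side="right"))
        out[regions.index.get_indexer(sub.index)] = cnt
    return out


def count_overlaps(reads: ReadSet, genes: GeneSet) -> CountTable:
    """Per-gene read counts (>=1 bp overlap, strand-blind).  Reads on
    chromosomes absent from the gene set count only toward ``n_mapped``."""
    g = genes.genes
    regions = g[["chrom", "start", "end"]].reset_index(drop=True)
    gene_chroms = set(g["chrom"])
    extra = set(reads.intervals["chrom"]) - gene_chroms
    if extra:
        logger.info("%s: chromosomes %s present in reads but not in genes "
                    "(counted as intergenic)", reads.sample_id, sorted(extra))
    cnt = _interval_counts(reads.intervals, regions)
    return CountTable(reads.sample_id,
                      pd.Series(cnt, index=pd.Index(g["gene_id"], name="gene_id")),
                      reads.n_mapped, condition=reads.condition,
                      time_h=reads.time_h, replicate=reads.replicate)


def tss_tes_windows(genes: GeneSet, window_bp: int = 1000) -> pd.DataFrame:
    """1-kb (by default) windows at both gene ends, in transcription
    orientation: the TSS window is the first ``window_bp`` of the gene body,
    the TES window the last.  Genes shorter than ``2 * window_bp`` (colliding
    windows) are excluded."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    g = genes.genes
    ok = g["length"] >= 2 * window_bp
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("tss_tes_windows: excluded %d genes shorter than %d bp",
                    n_skip, 2 * window_bp)
    g = g.loc[ok]
    plus = g["strand"] == "+"
    tss_start = np.where(plus, g["start"], g["end"] - window_bp)
    tes_start = np.where(plus, g["end"] - window_bp, g["start"])
    rows = []
    for kind, starts in (("TSS", tss_start), ("TES", tes_start)):
        rows.append(pd.DataFrame({
            "gene_id": g["gene_id"].to_numpy(), "kind": kind,
            "chrom": g["chrom"].to_numpy(),
            "start": starts.astype(np.int64),
            "end": (starts + window_bp).astype(np.int64)}))
    return pd.concat(rows, ignore_index=True)


def window_counts(reads: ReadSet, windows: pd.DataFrame) -> CountTable:
    """Counts over arbitrary (gene_id, kind, chrom, start, end) windows,
    same overlap rule as :func:`count_overlaps`; keyed by (gene_id, kind)."""
    w = windows.reset_index(drop=True)
    if ((w["end"] - w["start"]) <= 0).any():
        raise ValueError("zero-width window")
    cnt = _interval_counts(reads.intervals, w[["chrom", "start", "end"]])
    kind = w["kind"] if "kind" in w.columns else "window"
    index = pd.MultiIndex.from_arrays([w["gene_id"], kind],
                                      names=["gene_id", "kind"])
    return CountTable(reads.sample_id, pd.Series(cnt, index=index),
                      reads.n_mapped, condition=reads.condition,
                      time_h=reads.time_h, replicate=reads.replicate)


# ---------------------------------------------------------------------------
# normalization

def rpglpm(counts: CountTable, genes: GeneSet) -> NormalizedTable:
    """Reads per gene length per million: counts are divided by gene length
    and the per-sample sum is rescaled to exactly 1e6 (all-zero counts stay
    all-zero)."""
    lengths = genes.genes.set_index("gene_id")["length"]
    missing = counts.counts.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"counts contain gene_ids absent from GeneSet: "
                       f"{list(missing[:5])}")
    L = lengths.reindex(counts.counts.index)
    rate = counts.counts / L
    total = rate.sum()
    scores = rate * (1e6 / total) if total > 0 else rate * 0.0
    return NormalizedTable(counts.sample_id, scores, counts.n_mapped,
                           condition=counts.condition, time_h=counts.time_h,
                           replicate=counts.replicate)


def cpm_gene(counts: CountTable) -> pd.Series:
    """Counts per million mapped reads; uses the genome-wide library size."""
    if counts.n_mapped <= 0:
        raise ValueError("n_mapped must be positive for CPM")
    return counts.counts / counts.n_mapped * 1e6


def dpc_fraction(precipitated_ng: float, soluble_ng: float) -> float:
    """Bulk DPC level: precipitated DNA over total (precipitated + soluble)."""
    if precipitated_ng < 0 or soluble_ng < 0:
        raise ValueError("DNA masses must be >= 0")
    total = precipitated_ng + soluble_ng
    if total == 0:
        raise ValueError("precipitated and soluble DNA are both zero")
    return precipitated_ng / total
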