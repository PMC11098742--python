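"""Scaled-region metagene matrices and averaged profiles.

Each gene body is scaled to a fixed number of bins and flanked by fixed-width
upstream/downstream windows (the deepTools scale-regions idiom), all rows
oriented 5' -> 3' so the TSS is always the first body column.  Bin values are
CPM (counts per million mapped reads); a read overlapping several bins
increments each of them (coverage semantics) unless midpoint mode is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneSet
from .coverage import ReadSet

logger = logging.getLogger(__name__)


@dataclass
class ProfileConfig:
    """Geometry and gene filter of a scaled-region profile."""

    body_bins: int = 100
    flank_bp: int = 2000
    flank_bin_bp: int = 50
    tpm_min: float | None = None
    tpm_max: float | None = None
    midpoint_mode: bool = False
    #: divide each bin by its genomic width, giving a per-bp density that is
    #: comparable between the fixed-width flank bins and the scaled body bins
    per_bp: bool = False

    def __post_init__(self) -> None:
        if self.body_bins < 10:
            raise ValueError("body_bins must be >= 10")
        if self.flank_bp % self.flank_bin_bp:
            raise ValueError("flank_bp must be divisible by flank_bin_bp")

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.flank_bin_bp

    @property
    def n_columns(self) -> int:
        return 2 * self.n_flank_bins + self.body_bins

    @property
    def tss_col(self) -> int:
        """Index of the first gene-body column."""
        return self.n_flank_bins

    @property
    def tes_col(self) -> int:
        """Index of the last gene-body column."""
        return self.n_flank_bins + self.body_bins - 1


@dataclass
class MetageneMatrix:
    """Genes x bins CPM matrix, rows oriented 5'->3'."""

    values: pd.DataFrame           # index gene_id, columns 0..n_columns-1
    config: ProfileConfig
    n_mapped: int
    sample_id: str = ""

    def column_annotation(self) -> pd.DataFrame:
        c = self.config
        kind = (["upstream"] * c.n_flank_bins + ["body"] * c.body_bins
                + ["downstream"] * c.n_flank_bins)
        return pd.DataFrame({
            "column": np.arange(c.n_columns), "kind": kind,
            "is_tss": np.arange(c.n_columns) == c.tss_col,
            "is_tes": np.arange(c.n_columns) == c.tes_col})


def _gene_bin_edges(start: int, end: int, cfg: ProfileConfig) -> np.ndarray:
    """Genomic bin edges in genomic order: upstream flank, body (equal-width,
    last bin absorbs the remainder), downstream flank."""
    L = end - start
    up = start - cfg.flank_bp + np.arange(cfg.n_flank_bins + 1) * cfg.flank_bin_bp
    w = L // cfg.body_bins
    body = start + np.arange(1, cfg.body_bins) * w
    down = end + np.arange(cfg.n_flank_bins + 1) * cfg.flank_bin_bp
    return np.concatenate([up, body, down]).astype(np.int64)


def scaled_region_matrix(reads: ReadSet, genes: GeneSet, config: ProfileConfig,
                         chrom_sizes: Mapping[str, int] | None = None
                         ) -> MetageneMatrix:
    """Build the scaled-region CPM matrix for one sample.

    Genes outside the configured TPM range and genes shorter than
    ``body_bins`` bp (sub-bp bins) are excluded; flank bins running past a
    chromosome end are set to NaN.
    """
    g = genes.genes
    sel = np.ones(len(g), dtype=bool)
    if config.tpm_min is not None:
        sel &= (g["tpm"] >= config.tpm_min).fillna(False).to_numpy()
    if config.tpm_max is not None:
        sel &= (g["tpm"] < config.tpm_max).fillna(False).to_numpy()
    short = (g["length"] < config.body_bins).to_numpy()
    if (sel & short).any():
        logger.info("metagene: excluded %d genes shorter than %d bp",
                    int((sel & short).sum()), config.body_bins)
    sel &= ~short
    g = g.loc[sel]

    by_chrom = {}
    for chrom, sub in reads.intervals.groupby("chrom", sort=False):
        by_chrom[chrom] = (np.sort(sub["start"].to_numpy()),
                           np.sort(sub["end"].to_numpy()),
                           np.sort(((sub["start"] + sub["end"]) // 2).to_numpy()))
    rows = np.zeros((len(g), config.n_columns))
    for i, row in enumerate(g.itertuples(index=False)):
        edges = _gene_bin_edges(int(row.start), int(row.end), config)
        data = by_chrom.get(row.chrom)
        if data is None:
            cnt = np.zeros(config.n_columns)
        else:
            starts, ends, mids = data
            if config.midpoint_mode:
                cnt = np.diff(np.searchsorted(mids, edges, side="left")) \
                    .astype(float)
            else:
                cnt = (np.searchsorted(starts, edges[1:], side="left")
                       - np.searchsorted(ends, edges[:-1], side="right")) \
                    .astype(float)
        # flank bins beyond the chromosome are missing, not zero
        size = None if chrom_sizes is None else chrom_sizes.get(row.chrom)
        clipped = edges[:-1] < 0
        if size is not None:
            clipped |= edges[1:] > size
        cnt[clipped] = np.nan
        if config.per_bp:
            cnt = cnt / np.diff(edges)
        if row.strand == "-":
            cnt = cnt[::-1]
        rows[i] = cnt
    values = pd.DataFrame(rows / max(reads.n_mapped, 1) * 1e6,
                          index=pd.Index(g["gene_id"], name="gene_id"))
    return MetageneMatrix(values, config, reads.n_mapped, reads.sample_id)


def average_profiles(matrices: Sequence[MetageneMatrix]) -> pd.DataFrame:
    """Mean profile curve +/- s.e.m. across replicates.

    Genes are weighted equally: per replicate each column is averaged over
    genes, then the mean and s.e.m. are taken across the replicate curves.
    """
    if not matrices:
        raise ValueError("no matrices")
    cfg = matrices[0].config
    if any(m.config != cfg for m in matrices):
        raise ValueError("profile configs differ across replicates")
    per_rep = np.vstack([m.values.mean(axis=0, skipna=True).to_numpy()
                         for m in matrices])
    mean = per_rep.mean(axis=0)
    sem = (per_rep.std(axis=0, ddof=1) / np.sqrt(len(matrices))
           if len(matrices) > 1 else np.full(cfg.n_columns, np.nan))
    ann = matrices[0].column_annotation()
    return pd.DataFrame({"column": ann["column"], "kind": ann["kind"],
                         "is_tss": ann["is_tss"], "is_tes": ann["is_tes"],
                         "mean": mean, "sem": sem})


def heatmap_order(matrix: MetageneMatrix, sort_key: str,
                  genes: GeneSet | None = None) -> list[str]:
    """Stable descending row ordering by tpm, length, or row_mean; ties break
    by gene_id."""
    ids = matrix.values.index.to_numpy()
    if sort_key == "row_mean":
        key = np.nanmean(matrix.values.to_numpy(), axis=1)
    elif sort_key in {"tpm", "length"}:
        if genes is None:
            raise ValueError(f"sort key {sort_key!r} needs the GeneSet")
        key = genes.genes.set_index("gene_id")[sort_key] \
            .reindex(ids).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown sort key {sort_key!r}")
    order = np.lexsort((ids, -key))
    return [str(ids[i]) for i in order]


def nfr_dip(profile: pd.DataFrame, config: ProfileConfig,
            window_bins: int = 2, smooth_bins: int = 3) -> dict:
    """Quantify the promoter nucleosome-free dip near the TSS column.

    The profile is first smoothed with a centered ``smooth_bins`` rolling
    mean: the NFR is a ~200-bp feature spanning several profile columns, so a
    single-column minimum would measure counting noise rather than the
    feature.  Returns the offset of the smoothed global minimum from the TSS
    column and the dip depth ``(body_mean - min_near_tss) / body_mean``,
    where the near-TSS window spans ``tss_col +/- window_bins`` and the body
    mean excludes it.  Use a per-bp profile so flank and body columns share
    units.
    """
    mean = pd.Series(profile["mean"].to_numpy()) \
        .rolling(smooth_bins, center=True, min_periods=1).mean().to_numpy()
    tss = config.tss_col
    argmin = int(np.nanargmin(mean))
    lo, hi = tss - window_bins, tss + window_bins + 1
    near = mean[max(lo, 0):hi]
    body_mask = np.arange(config.tss_col, config.tes_col + 1)
    body = mean[config.tss_col:config.tes_col + 1]
    body = body[(body_mask < lo) | (body_mask >= hi)]
    body_mean = float(np.nanmean(body))
    return {"argmin_offset": argmin - tss,
            "min_near_tss": float(np.nanmin(near)),
            "body_mean": body_mean,
            "dip_depth": (body_mean - float(np.nanmin(near))) / body_mean}
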