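"""Gene-universe construction for DPC-seq quantification.

All downstream statistics (residual ratios, expression/length binning, metagene
profiles) are computed over a filtered set of single-transcript gene models:
for every gene the longest transcript is kept, genes whose genomic extents
overlap any other gene are discarded, mitochondrial genes are removed (and sex
chromosomes in mouse), and a per-gene expression level (TPM) is attached from
an external table.

Coordinates are 0-based half-open (BED convention) throughout; GTF's 1-based
closed coordinates are converted on read.  Gene "length" is the unspliced
transcript span ``end - start``, since coverage statistics are computed over
genomic gene bodies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "tpm"]

#: Default binning edges.  The source figures never print their edges; these
#: seven length bins are consistent with the printed "3-10 kb" and ">=20 kb"
#: contrasts, and the TPM schemes with the printed "TPM >= 30",
#: "0.1 <= TPM < 1" and "0.01 <= TPM < 0.1" categories.
LENGTH_EDGES_BP = [0, 3_000, 10_000, 20_000, 50_000, 100_000, 200_000]
TPM_EDGES_4 = [0.1, 1.0, 10.0, 100.0]
TPM_EDGES_6_MOUSE = [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0]


class AnnotationError(ValueError):
    """Malformed annotation input."""


@dataclass
class GeneModel:
    """One gene: coordinates, strand, and expression level.

    ``tss``/``tes`` are strand-aware: the TSS is ``start`` on the plus strand
    and ``end`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tpm: float = np.nan

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"{self.gene_id}: start must be < end ({self.start} >= {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise AnnotationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not np.isnan(self.tpm) and self.tpm < 0:
            raise AnnotationError(f"{self.gene_id}: negative TPM {self.tpm}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class GeneSet:
    """An ordered collection of single-transcript gene models.

    Wraps a DataFrame with columns gene_id, chrom, start, end, strand, tpm
    (tpm NaN where unknown) plus a derived ``length`` column.
    """

    genes: pd.DataFrame
    species_mode: str = "human"
    provenance: str = ""

    def __post_init__(self) -> None:
        df = self.genes
        missing = [c for c in GENE_COLUMNS if c not in df.columns]
        if missing:
            raise AnnotationError(f"GeneSet missing columns {missing}")
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise AnnotationError(f"duplicate gene_id {dup!r}")
        df = df.copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["tpm"] = df["tpm"].astype(float)
        if (df["start"] >= df["end"]).any():
            raise AnnotationError("start >= end in gene records")
        if (df["tpm"].dropna() < 0).any():
            raise AnnotationError("negative TPM in gene records")
        df["length"] = df["end"] - df["start"]
        self.genes = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        for row in self.genes.itertuples(index=False):
            yield GeneModel(row.gene_id, row.chrom, int(row.start), int(row.end),
                            row.strand, float(row.tpm))

    @property
    def tss(self) -> pd.Series:
        g = self.genes
        return g["start"].where(g["strand"] == "+", g["end"])

    @property
    def tes(self) -> pd.Series:
        g = self.genes
        return g["end"].where(g["strand"] == "+", g["start"])

    def to_bed6(self, path: str | Path) -> None:
        g = self.genes
        bed = pd.DataFrame({
            "chrom": g["chrom"], "start": g["start"], "end": g["end"],
            "name": g["gene_id"], "score": 0, "strand": g["strand"],
        })
        bed.to_csv(path, sep="\t", header=False, index=False)

    def to_tsv(self, path: str | Path) -> None:
        """Sidecar table: gene_id, length, tpm."""
        self.genes[["gene_id", "chrom", "start", "end", "strand", "length", "tpm"]] \
            .to_csv(path, sep="\t", index=False)


def geneset_from_bed6(path: str | Path, tpm: Mapping[str, float] | None = None,
                      species_mode: str = "human") -> GeneSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    genes = pd.DataFrame({
        "gene_id": df["name"].astype(str), "chrom": df["chrom"],
        "start": df["start"], "end": df["end"], "strand": df["strand"],
        "tpm": np.nan,
    })
    gs = GeneSet(genes, species_mode=species_mode, provenance=str(path))
    if tpm is not None:
        gs = attach_expression(gs, tpm)
    return gs


# ---------------------------------------------------------------------------
# annotation parsing

def _gtf_prevalidate(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(
                    f"{path}: malformed GTF record at line {lineno} "
                    f"({len(fields)} fields, expected 9)")
            try:
                int(fields[3]); int(fields[4])
            except ValueError:
                raise AnnotationError(
                    f"{path}: non-integer coordinates at line {lineno}") from None


def _parse_gtf(path: Path) -> pd.DataFrame:
    """Return one row per transcript: gene_id, transcript_id, chrom, start,
    end, strand (0-based half-open)."""
    import gffutils

    _gtf_prevalidate(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=False)
    rows = []
    seen = set()
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None or gid is None:
            continue
        key = (gid, tid, feat.seqid)
        rows.append((gid, tid, feat.seqid, feat.start - 1, feat.end, feat.strand))
        seen.add(key)
    if not rows:
        return pd.DataFrame(columns=["gene_id", "transcript_id", "chrom",
                                     "start", "end", "strand"])
    df = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "chrom",
                                     "start", "end", "strand"])
    # transcript extent = union span of all records carrying its transcript_id
    agg = df.groupby(["gene_id", "transcript_id", "chrom", "strand"],
                     sort=False).agg(start=("start", "min"), end=("end", "max"))
    return agg.reset_index()[["gene_id", "transcript_id", "chrom",
                              "start", "end", "strand"]]


def _parse_bed12(path: Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand",
             "thickStart", "thickEnd", "itemRgb", "blockCount",
             "blockSizes", "blockStarts"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names,
                         dtype={"chrom": str, "name": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise AnnotationError(f"{path}: malformed BED12 ({exc})") from exc
    if df["start"].isna().any() or df["end"].isna().any():
        raise AnnotationError(f"{path}: malformed BED12 (missing coordinates)")
    split = df["name"].str.split("|", n=1, expand=True)
    gene_id = split[0]
    transcript_id = split[1].fillna(split[0]) if split.shape[1] > 1 else split[0]
    return pd.DataFrame({
        "gene_id": gene_id, "transcript_id": transcript_id,
        "chrom": df["chrom"], "start": df["start"].astype(np.int64),
        "end": df["end"].astype(np.int64), "strand": df["strand"],
    })


def parse_gene_annotation(path: str | Path, fmt: str | None = None,
                          species_mode: str = "human") -> GeneSet:
    """Build a single-transcript GeneSet from a GTF or BED12 annotation.

    For each gene the transcript with the maximal genomic span (end - start)
    is kept; ties are broken by the lexicographically smallest transcript_id.
    Genes contributing no transcript record are skipped (counted in the log).
    """
    path = Path(path)
    if fmt is None:
        fmt = "bed12" if path.suffix.lower() in {".bed", ".bed12"} else "gtf"
    tx = _parse_gtf(path) if fmt == "gtf" else _parse_bed12(path)
    if tx.empty:
        logger.warning("%s: no transcripts parsed", path)
        return GeneSet(pd.DataFrame(columns=GENE_COLUMNS),
                       species_mode=species_mode, provenance=str(path))
    tx = tx.assign(span=tx["end"] - tx["start"])
    # longest span, ties -> smallest transcript_id
    tx = tx.sort_values(["gene_id", "span", "transcript_id"],
                        ascending=[True, False, True], kind="mergesort")
    best = tx.drop_duplicates("gene_id", keep="first")
    genes = pd.DataFrame({
        "gene_id": best["gene_id"], "chrom": best["chrom"],
        "start": best["start"], "end": best["end"], "strand": best["strand"],
        "tpm": np.nan,
    })
    return GeneSet(genes, species_mode=species_mode, provenance=str(path))


# ---------------------------------------------------------------------------
# filters

def exclude_overlapping_genes(genes: GeneSet) -> GeneSet:
    """Drop every gene whose interval intersects any other gene (>=1 bp,
    strand-blind, same chromosome).  Both members of an overlapping pair are
    removed; containment counts as overlap."""
    df = genes.genes
    if len(df) <= 1:
        return replace(genes, genes=df.copy())
    flagged = np.zeros(len(df), dtype=bool)
    order = df.sort_values(["chrom", "start", "end"], kind="mergesort")
    for _, sub in order.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        start = sub["start"].to_numpy()
        end = sub["end"].to_numpy()
        if len(idx) < 2:
            continue
        # a gene overlaps a predecessor iff running max end of earlier genes
        # exceeds its start; it overlaps a successor iff the next start
        # (smallest later start) is below its own end
        prev_max_end = np.concatenate(([np.iinfo(np.int64).min],
                                       np.maximum.accumulate(end)[:-1]))
        next_start = np.concatenate((start[1:], [np.iinfo(np.int64).max]))
        bad = (prev_max_end > start) | (next_start < end)
        flagged[idx] |= bad  # df index is a RangeIndex, idx are positions
    kept = df.loc[~flagged].reset_index(drop=True)
    logger.info("overlap exclusion: removed %d of %d genes",
                int(flagged.sum()), len(df))
    out = replace(genes, genes=kept)
    out.n_overlap_removed = int(flagged.sum())
    return out


_MITO = {"chrm", "mt", "chrmt", "m"}
_SEX = {"chrx", "x", "chry", "y"}


def filter_chromosomes(genes: GeneSet, species_mode: str | None = None) -> GeneSet:
    """Remove mitochondrial genes (human and mouse) and sex-chromosome genes
    (mouse only).  Recognizes both "chrM"/"MT" and "chrX"/"X" dialects."""
    mode = species_mode or genes.species_mode
    if mode not in {"human", "mouse"}:
        raise ValueError(f"unknown species_mode {mode!r} (expected human|mouse)")
    low = genes.genes["chrom"].str.lower()
    drop = low.isin(_MITO)
    if mode == "mouse":
        drop |= low.isin(_SEX)
    kept = genes.genes.loc[~drop].reset_index(drop=True)
    logger.info("chromosome filter (%s): removed %d of %d genes",
                mode, int(drop.sum()), len(genes.genes))
    out = replace(genes, genes=kept, species_mode=mode)
    out.n_chrom_removed = int(drop.sum())
    return out


def attach_expression(genes: GeneSet,
                      expression: Mapping[str, float] | pd.DataFrame | str | Path
                      ) -> GeneSet:
    """Populate per-gene TPM from a gene_id -> TPM mapping or a TSV with
    columns gene_id, tpm.  Genes absent from the table keep tpm = NaN and are
    excluded from any TPM-filtered statistic downstream."""
    if isinstance(expression, (str, Path)):
        expression = pd.read_csv(expression, sep="\t")
    if isinstance(expression, pd.DataFrame):
        if not {"gene_id", "tpm"} <= set(expression.columns):
            raise AnnotationError("expression table needs gene_id, tpm columns")
        mapping = dict(zip(expression["gene_id"].astype(str),
                           expression["tpm"].astype(float)))
    else:
        mapping = {str(k): float(v) for k, v in expression.items()}
    if any(v < 0 for v in mapping.values()):
        raise AnnotationError("negative TPM in expression table")
    df = genes.genes.copy()
    df["tpm"] = df["gene_id"].map(mapping)
    n_matched = int(df["tpm"].notna().sum())
    n_extra = len(set(mapping) - set(df["gene_id"]))
    logger.info("expression: matched %d/%d genes (%d table ids unused)",
                n_matched, len(df), n_extra)
    out = replace(genes, genes=df)
    out.n_expression_matched = n_matched
    out.n_expression_extra = n_extra
    return out


# ---------------------------------------------------------------------------
# binning

@dataclass
class BinningScheme:
    """Left-closed, right-open bins over TPM or gene length; the last edge
    opens an unbounded bin, so there are ``len(edges)`` bins in total.
    Values below ``edges[0]`` fall in no bin."""

    variable: str                     # "tpm" | "length"
    edges: list[float]
    labels: list[str] = field(default_factory=list)
    min_tpm_filter: float | None = None

    def __post_init__(self) -> None:
        if self.variable not in {"tpm", "length"}:
            raise ValueError(f"unknown binning variable {self.variable!r}")
        edges = [float(e) for e in self.edges]
        if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly ascending")
        self.edges = edges
        if not self.labels:
            self.labels = self._default_labels()
        if len(self.labels) != len(self.edges):
            raise ValueError("need one label per bin (len(labels) == len(edges))")

    def _default_labels(self) -> list[str]:
        def fmt(v: float) -> str:
            if self.variable == "length":
                return f"{v / 1000:g}"
            return f"{v:g}"
        unit = " kb" if self.variable == "length" else ""
        labels = [f"{fmt(a)}-{fmt(b)}{unit}"
                  for a, b in zip(self.edges, self.edges[1:])]
        labels.append(f">={fmt(self.edges[-1])}{unit}")
        return labels


def length_bins_default() -> BinningScheme:
    return BinningScheme("length", list(LENGTH_EDGES_BP))


def tpm_bins_default(n: int = 4) -> BinningScheme:
    if n == 4:
        return BinningScheme("tpm", list(TPM_EDGES_4))
    if n == 6:
        return BinningScheme("tpm", list(TPM_EDGES_6_MOUSE))
    raise ValueError("default TPM schemes exist for n=4 (human) and n=6 (mouse)")


def assign_bins(genes: GeneSet, scheme: BinningScheme) -> pd.Series:
    """Map each eligible gene_id to its bin label.

    A gene is eligible if it carries the binned variable, lies at or above the
    first edge, and passes ``min_tpm_filter`` when set.  Boundary values go to
    the bin whose left edge they equal (left-closed convention).  Ineligible
    genes are absent from the result (their count is logged).
    """
    df = genes.genes
    values = df[scheme.variable].astype(float)
    eligible = values.notna() & (values >= scheme.edges[0])
    if scheme.min_tpm_filter is not None:
        eligible &= df["tpm"].notna() & (df["tpm"] >= scheme.min_tpm_filter)
    idx = np.searchsorted(scheme.edges, values[eligible].to_numpy(),
                          side="right") - 1
    labels = pd.Series(np.asarray(scheme.labels, dtype=object)[idx],
                       index=df.loc[eligible, "gene_id"], name="bin")
    n_excluded = int((~eligible).sum())
    if n_excluded:
        logger.info("binning (%s): excluded %d of %d genes",
                    scheme.variable, n_excluded, len(df))
    return labels


def build_gene_universe(annotation: str | Path,
                        expression: Mapping[str, float] | pd.DataFrame | str | Path | None = None,
                        species_mode: str = "human",
                        overlap_first: bool = True) -> GeneSet:
    """Full filtering chain: longest transcript -> overlap exclusion ->
    chromosome filter -> expression attachment.  ``overlap_first=False``
    attaches expression before the overlap exclusion (the order the filters
    run in does not change membership, only the logged tallies)."""
    gs = parse_gene_annotation(annotation, species_mode=species_mode)
    if overlap_first:
        gs = exclude_overlapping_genes(gs)
        gs = filter_chromosomes(gs)
        if expression is not None:
            gs = attach_expression(gs, expression)
    else:
        if expression is not None:
            gs = attach_expression(gs, expression)
        gs = exclude_overlapping_genes(gs)
        gs = filter_chromosomes(gs)
    return gs
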