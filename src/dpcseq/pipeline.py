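"""End-to-end orchestration used by the CLI and the analysis scripts.

A run is described by a declarative config (YAML on disk, a plain dict in
memory): paths to annotation/expression/read files with condition, time and
replicate labels, the binning schemes, profile geometry and thresholds.  All
tabular outputs are sorted deterministically so reruns from the same config
and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (BinningScheme, GeneSet, build_gene_universe,
                         geneset_from_bed6, length_bins_default,
                         tpm_bins_default)
from .coverage import CountTable, count_overlaps, cpm_gene, load_reads, rpglpm
from .metrics import (ResidualTable, residual_ratio, summarize_by_bin,
                      unpaired_t_test)
from .annotation import assign_bins

logger = logging.getLogger(__name__)


@dataclass
class SampleSpec:
    path: str
    condition: str
    time_h: float
    replicate: int

    @property
    def sample_id(self) -> str:
        return f"{self.condition}_t{self.time_h:g}h_rep{self.replicate}"


@dataclass
class RunConfig:
    annotation: str | None = None
    genes_bed: str | None = None          # pre-filtered BED6 alternative
    expression: str | None = None
    samples: list[SampleSpec] = field(default_factory=list)
    species_mode: str = "human"
    mapq_min: int = 20
    min_baseline_count: int = 10
    baseline_time_h: float = 0.0
    window_bp: int = 1000
    tpm_min_profile: float = 30.0
    seed: int = 0
    out_dir: str = "dpcseq_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        cfg = cls(samples=samples, **raw)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)

    def validate(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample labels are not unique")
        for s in self.samples:
            if not Path(s.path).exists():
                raise FileNotFoundError(f"sample file missing: {s.path}")
        if self.expression is not None and not Path(self.expression).exists():
            raise FileNotFoundError(f"expression file missing: {self.expression}")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: Path, files: Sequence[Path]) -> Path:
    manifest = {str(p.relative_to(out_dir)): _checksum(p)
                for p in sorted(files)}
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump({"version": __version__, "files": manifest}, fh,
                  indent=1, sort_keys=True)
    return path


def load_gene_universe(cfg: RunConfig) -> GeneSet:
    if cfg.genes_bed:
        gs = geneset_from_bed6(cfg.genes_bed, species_mode=cfg.species_mode)
        if cfg.expression:
            from .annotation import attach_expression
            gs = attach_expression(gs, cfg.expression)
        return gs
    if not cfg.annotation:
        raise ValueError("config needs either annotation or genes_bed")
    return build_gene_universe(cfg.annotation, expression=cfg.expression,
                               species_mode=cfg.species_mode)


def quantify(cfg: RunConfig, genes: GeneSet | None = None):
    """Counting + normalization for every sample; returns
    (genes, {sample_id: CountTable}, qc dict) and writes TSVs + QC report."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if genes is None:
        genes = load_gene_universe(cfg)
    qc = {"n_genes": len(genes),
          "n_overlap_removed": getattr(genes, "n_overlap_removed", None),
          "n_chrom_removed": getattr(genes, "n_chrom_removed", None),
          "samples": {}}
    counts: dict[str, CountTable] = {}
    score_rows, count_rows = [], []
    for s in cfg.samples:
        rs = load_reads(s.path, mapq_min=cfg.mapq_min, sample_id=s.sample_id,
                        condition=s.condition, time_h=s.time_h,
                        replicate=s.replicate)
        ct = count_overlaps(rs, genes)
        counts[s.sample_id] = ct
        norm = rpglpm(ct, genes)
        cpm = cpm_gene(ct)
        qc["samples"][s.sample_id] = {
            "n_mapped": rs.n_mapped,
            "genic_reads": int(ct.counts.sum()),
            "score_total": float(norm.scores.sum()),
        }
        count_rows.append(pd.DataFrame({
            "sample_id": s.sample_id, "gene_id": ct.counts.index,
            "count": ct.counts.to_numpy(), "cpm": cpm.to_numpy(),
            "rpglpm": norm.scores.to_numpy()}))
    table = pd.concat(count_rows, ignore_index=True) \
        .sort_values(["sample_id", "gene_id"], kind="mergesort")
    table.to_csv(out / "counts.tsv", sep="\t", index=False,
                 float_format="%.6g")
    genes.to_tsv(out / "genes.filtered.tsv")
    with open(out / "qc.json", "w") as fh:
        json.dump(qc, fh, indent=1, sort_keys=True)
    return genes, counts, qc


def residual_tables(cfg: RunConfig, counts: dict[str, CountTable]
                    ) -> dict[str, list[ResidualTable]]:
    """Pair each recovery-time sample with its same-replicate baseline
    (replicate i at t over replicate i at 0 h), per condition."""
    by_key = {}
    for ct in counts.values():
        by_key[(ct.condition, ct.time_h, ct.replicate)] = ct
    out: dict[str, list[ResidualTable]] = {}
    for (cond, t, rep), ct in sorted(by_key.items()):
        if t == cfg.baseline_time_h:
            continue
        base = by_key.get((cond, cfg.baseline_time_h, rep))
        if base is None:
            logger.warning("no baseline for %s t=%g rep=%d", cond, t, rep)
            continue
        out.setdefault(cond, []).append(
            residual_ratio(ct, base,
                           min_baseline_count=cfg.min_baseline_count))
    return out


def report(cfg: RunConfig, genes: GeneSet, counts: dict[str, CountTable],
           truth: dict | None = None) -> dict:
    """Figure-style outputs: residual bin summaries per condition (TPM and
    gene-length bins), pairwise condition tests, and (when simulation truth is
    supplied) a parameter-recovery section.  Everything is written as sorted
    TSV/JSON under the output directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    residuals = residual_tables(cfg, counts)
    tpm_scheme = tpm_bins_default(4)
    len_scheme = BinningScheme("length", length_bins_default().edges,
                               min_tpm_filter=100.0)
    tpm_bins = assign_bins(genes, tpm_scheme)
    len_bins = assign_bins(genes, len_scheme)
    summary_rows = []
    top_bin_means: dict[str, list[float]] = {}
    for cond, rts in sorted(residuals.items()):
        for scheme, bins, kind in ((tpm_scheme, tpm_bins, "tpm"),
                                   (len_scheme, len_bins, "length")):
            summ = summarize_by_bin(rts, bins, bin_order=scheme.labels)
            summ.insert(0, "condition", cond)
            summ.insert(1, "binning", kind)
            summary_rows.append(summ)
            if kind == "tpm":
                top = summ.iloc[-1]
                top_bin_means[cond] = [m for m in top["replicate_means"]
                                       if not np.isnan(m)]
    summary = pd.concat(summary_rows, ignore_index=True)
    summary.drop(columns="replicate_means").to_csv(
        out / "residual_bin_summary.tsv", sep="\t", index=False,
        float_format="%.6g")

    tests = []
    conds = sorted(top_bin_means)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            if len(top_bin_means[a]) >= 2 and len(top_bin_means[b]) >= 2:
                t = unpaired_t_test(top_bin_means[a], top_bin_means[b])
                tests.append({"comparison": f"{a}_vs_{b}",
                              "bin": tpm_scheme.labels[-1],
                              "t": t.statistic, "df": t.df, "p": t.pvalue})
    result = {"summary": summary, "tests": pd.DataFrame(tests)}
    if tests:
        result["tests"].to_csv(out / "condition_tests.tsv", sep="\t",
                               index=False, float_format="%.6g")
    if truth is not None:
        rec = {}
        for key, expected in sorted(truth.get("expected_residual", {}).items()):
            cond = key.rsplit("_t", 1)[0]
            if cond not in residuals:
                continue
            exp = pd.Series(expected)
            gf = truth.get("global_survival", {}).get(key, 1.0)
            obs = pd.concat([rt.usable for rt in residuals[cond]],
                            axis=1).mean(axis=1) * gf
            joint = pd.DataFrame({"obs": obs, "exp": exp}).dropna()
            rec[key] = {
                "n": len(joint),
                "global_survival": gf,
                "median_abs_dev": float((joint["obs"] - joint["exp"]).abs()
                                        .median()),
            }
        with open(out / "truth_comparison.json", "w") as fh:
            json.dump(rec, fh, indent=1, sort_keys=True)
        result["truth_comparison"] = rec
    cfg.to_yaml(out / "config.resolved.yaml")
    return result
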