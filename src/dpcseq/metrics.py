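"""Residual-ratio statistics: the headline DPC-seq quantities.

The per-gene residual ratio R_g is the depth-normalized coverage of gene g at
a recovery time divided by that at 0 h (1 = no removal, -> 0 = complete
removal).  Ratios are summarized per expression or gene-length bin with the
replicate as the unit of error (mean +/- s.e.m. across independent
replicates), compared between TSS- and TES-proximal 1-kb windows, tested with
the classical two-sided unpaired t-test, and inverted against the simulator's
closed-form expected residual to recover removal parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .annotation import BinningScheme, GeneSet, assign_bins
from .coverage import (CountTable, NormalizedTable, ReadSet, count_overlaps,
                       tss_tes_windows, window_counts)

logger = logging.getLogger(__name__)


@dataclass
class ResidualTable:
    """Per-gene residual ratios for one condition x replicate.

    ``values`` has columns R (NaN where QC failed) and qc ("ok" or
    "low_count"); flagged genes are reported, never dropped.
    """

    condition: str
    replicate: int
    values: pd.DataFrame          # index gene_id (or (gene_id, kind))
    time_h: float = np.nan

    @property
    def usable(self) -> pd.Series:
        ok = self.values["qc"] == "ok"
        return self.values.loc[ok, "R"]


def _depth_norm(table: CountTable | NormalizedTable) -> pd.Series:
    if isinstance(table, NormalizedTable):
        return table.scores
    if table.n_mapped <= 0:
        raise ValueError(f"{table.sample_id}: n_mapped must be positive")
    return table.counts / table.n_mapped * 1e6


def residual_ratio(recovered: CountTable | NormalizedTable,
                   baseline: CountTable | NormalizedTable,
                   min_baseline_count: int = 10,
                   depth_normalize: bool = True,
                   global_factor: float | None = None) -> ResidualTable:
    """R_g = depth-normalized signal(recovered) / signal(baseline).

    Depth normalization is CPM over the genome-wide library size (libraries
    differ in depth; disable with ``depth_normalize=False`` only for matched
    depths).  Genes whose baseline raw count falls below
    ``min_baseline_count`` are flagged "low_count" and excluded from
    summaries.

    Because CPM measures library *shares*, the ratio estimates the absolute
    surviving fraction divided by the genome-wide surviving fraction; the
    offset is identical for all genes, so orderings, correlations and
    between-condition contrasts are unaffected.  When the genome-wide factor
    is known -- from a bulk precipitated-DNA fraction measurement or from
    simulation truth -- pass it as ``global_factor`` to rescale R onto the
    absolute scale.
    """
    rec_idx = recovered.counts.index if isinstance(recovered, CountTable) \
        else recovered.scores.index
    base_idx = baseline.counts.index if isinstance(baseline, CountTable) \
        else baseline.scores.index
    if not rec_idx.equals(base_idx):
        raise ValueError("recovered and baseline gene universes differ")
    num = _depth_norm(recovered) if depth_normalize else (
        recovered.counts if isinstance(recovered, CountTable) else recovered.scores)
    den = _depth_norm(baseline) if depth_normalize else (
        baseline.counts if isinstance(baseline, CountTable) else baseline.scores)
    base_counts = baseline.counts if isinstance(baseline, CountTable) else \
        baseline.scores
    low = base_counts < min_baseline_count
    with np.errstate(divide="ignore", invalid="ignore"):
        R = num / den
    if global_factor is not None:
        R = R * global_factor
    R[low | (den <= 0)] = np.nan
    values = pd.DataFrame({
        "R": R, "qc": np.where(low | (den <= 0), "low_count", "ok")})
    if isinstance(recovered, CountTable) and isinstance(baseline, CountTable):
        values["recovered_count"] = recovered.counts
        values["baseline_count"] = baseline.counts
    return ResidualTable(recovered.condition or baseline.condition,
                         recovered.replicate, values, time_h=recovered.time_h)


@dataclass
class BinSummary:
    bin_label: str
    n_genes: int
    replicate_means: list[float]
    mean: float
    sem: float
    n_replicates: int


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if len(x) < 2:
        return np.nan
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def summarize_by_bin(residuals: Sequence[ResidualTable],
                     bins: pd.Series,
                     bin_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-bin residual summary across replicates.

    Per replicate the bin mean is the mean of R over QC-passing genes in the
    bin; the grand mean and s.e.m. are taken across replicate means, making
    the replicate the unit of error ("means +/- s.e.m. from n independent
    experiments").  Empty bins are reported with n_genes = 0 and NaN mean.
    """
    if not residuals:
        raise ValueError("need at least one replicate")
    if bin_order is None:
        bin_order = list(pd.unique(bins))
    rows = []
    for label in bin_order:
        gene_ids = bins.index[bins == label]
        rep_means, gene_pool = [], set()
        for rt in residuals:
            r = rt.usable
            idx = r.index.intersection(gene_ids)
            gene_pool |= set(idx)
            rep_means.append(float(r.loc[idx].mean()) if len(idx) else np.nan)
        valid = [m for m in rep_means if not np.isnan(m)]
        rows.append({
            "bin": label, "n_genes": len(gene_pool),
            "mean": float(np.mean(valid)) if valid else np.nan,
            "sem": _sem(valid), "n_replicates": len(valid),
            "replicate_means": rep_means,
        })
    return pd.DataFrame(rows)


@dataclass
class TestResult:
    statistic: float
    df: float
    pvalue: float
    n_a: int
    n_b: int
    degenerate: bool = False


def unpaired_t_test(group_a: Sequence[float], group_b: Sequence[float]
                    ) -> TestResult:
    """Classical Student two-sided unpaired t-test (pooled variance).

    Zero pooled variance: equal means give t = 0, p = 1; unequal means give
    p -> 0, flagged degenerate.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 observations")
    dof = len(a) + len(b) - 2
    pooled = ((len(a) - 1) * np.var(a, ddof=1)
              + (len(b) - 1) * np.var(b, ddof=1)) / dof
    if pooled == 0:
        if np.mean(a) == np.mean(b):
            return TestResult(0.0, dof, 1.0, len(a), len(b))
        return TestResult(np.inf if np.mean(a) > np.mean(b) else -np.inf,
                          dof, 0.0, len(a), len(b), degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), dof, float(res.pvalue),
                      len(a), len(b))


def pairwise_bonferroni(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """All pairwise t-tests with Bonferroni-adjusted p values -- a
    conservative stand-in for the multiple-comparison procedures used in the
    source figures (Dunnett / Tukey-Kramer), labelled as such in output."""
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            t = unpaired_t_test(groups[x], groups[y])
            rows.append({"group_a": x, "group_b": y, "t": t.statistic,
                         "df": t.df, "p": t.pvalue,
                         "p_bonferroni": min(1.0, t.pvalue * m),
                         "method": "t-test+Bonferroni"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TSS/TES window residuals

def tss_tes_residual(recovered_reads: Sequence[ReadSet],
                     baseline_reads: Sequence[ReadSet],
                     genes: GeneSet,
                     length_scheme: BinningScheme,
                     window_bp: int = 1000,
                     min_baseline_count: int = 10,
                     tpm_min: float | None = None) -> pd.DataFrame:
    """Residual ratios on 1-kb TSS- and TES-proximal windows, summarized per
    gene-length bin with a per-bin TES-vs-TSS t-test across replicates.

    Replicates are paired by list position (replicate i recovered over
    replicate i baseline).  Genes shorter than ``2 * window_bp`` are excluded
    (their windows would collide).
    """
    if len(recovered_reads) != len(baseline_reads):
        raise ValueError("need matched recovered/baseline replicates")
    g = genes
    if tpm_min is not None:
        g = replace(genes, genes=genes.genes[genes.genes["tpm"] >= tpm_min]
                    .reset_index(drop=True))
    windows = tss_tes_windows(g, window_bp)
    residuals = []
    for rec, base in zip(recovered_reads, baseline_reads):
        rt = residual_ratio(window_counts(rec, windows),
                            window_counts(base, windows),
                            min_baseline_count=min_baseline_count)
        residuals.append(rt)
    bins = assign_bins(g, length_scheme)
    rows = []
    for label in length_scheme.labels:
        gene_ids = set(bins.index[bins == label])
        per_kind = {}
        for kind in ("TSS", "TES"):
            rep_means = []
            n_genes = set()
            for rt in residuals:
                r = rt.usable
                sel = r[[gid in gene_ids and k == kind
                         for gid, k in r.index]]
                n_genes |= set(sel.index)
                rep_means.append(float(sel.mean()) if len(sel) else np.nan)
            per_kind[kind] = rep_means
            valid = [m for m in rep_means if not np.isnan(m)]
            rows.append({"bin": label, "kind": kind, "n_genes": len(n_genes),
                         "mean": float(np.mean(valid)) if valid else np.nan,
                         "sem": _sem(valid), "n_replicates": len(valid),
                         "replicate_means": rep_means})
        a = [m for m in per_kind["TES"] if not np.isnan(m)]
        b = [m for m in per_kind["TSS"] if not np.isnan(m)]
        if len(a) >= 2 and len(b) >= 2:
            t = unpaired_t_test(a, b)
            for row in rows[-2:]:
                row["tes_vs_tss_t"] = t.statistic
                row["tes_vs_tss_p"] = t.pvalue
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# removal-parameter estimation

@dataclass
class RemovalFit:
    k_max: float
    lam_w: float
    k_b: float
    rss: float
    n_genes: int
    converged: bool


def estimate_removal_parameters(residuals: Sequence[ResidualTable],
                                genes: GeneSet,
                                params,                 # simulate.SimParams
                                t: float,
                                min_genes: int = 30,
                                global_factor: float | None = None
                                ) -> RemovalFit:
    """Fit (k_max, lambda_w, k_b) by least squares on log residuals.

    Minimizes sum_g (log R_g - log E[R_g | k_max, lambda_w, k_b])^2 over
    QC-passing genes, where E[R_g] is the closed-form expected residual of
    the deposition/removal model at genotype factor 1 (a reduced-activity
    genotype therefore fits a proportionally reduced k_max).  A coarse grid
    over (k_max, lambda_w, k_b) seeds a bounded least-squares refinement in
    log-parameter space to avoid local minima.

    Depth-normalized residuals are library shares inflated by the inverse
    genome-wide survival, which the non-negative rates cannot absorb; pass
    ``global_factor`` (simulation truth, or a bulk precipitated-DNA fraction
    ratio) to rescale them onto the absolute survival scale first.
    """
    from .simulate import _survival_mass, deposition_field

    # Per-replicate log ratios with the delta-method bias correction for logs
    # of Poisson count ratios (E[ln(X/Y)] ~ ln(lx/ly) - 1/(2lx) + 1/(2ly)),
    # combined across replicates by inverse variance; genes without counts
    # (pre-normalized input) fall back to unweighted uncorrected logs.
    log_parts, w_parts = [], []
    for rt in residuals:
        r = rt.usable
        r = r[r > 0]
        logr = np.log(r)
        if global_factor is not None:
            logr = logr + np.log(global_factor)
        if {"recovered_count", "baseline_count"} <= set(rt.values.columns):
            c4 = rt.values.loc[logr.index, "recovered_count"].clip(lower=1)
            c0 = rt.values.loc[logr.index, "baseline_count"].clip(lower=1)
            logr = logr + 1 / (2 * c4) - 1 / (2 * c0)
            w = 1.0 / (1 / c4 + 1 / c0)
        else:
            w = pd.Series(1.0, index=logr.index)
        log_parts.append(logr)
        w_parts.append(w)
    keys = range(len(w_parts))
    W = pd.concat(w_parts, axis=1, keys=keys)
    logR_all = (pd.concat(log_parts, axis=1, keys=keys) * W) \
        .sum(axis=1, skipna=True) / W.sum(axis=1, skipna=True)
    w_gene = W.sum(axis=1, skipna=True)
    logR_all = logR_all.dropna()
    if len(logR_all) < min_genes:
        raise ValueError(f"only {len(logR_all)} usable genes (< {min_genes}); "
                         "refusing to fit")
    field = deposition_field(genes, params)
    gene_ids = genes.genes["gene_id"]
    mask = gene_ids.isin(logR_all.index).to_numpy()
    logR = logR_all.reindex(gene_ids[mask]).to_numpy()
    sqrt_w = np.sqrt(w_gene.reindex(gene_ids[mask]).to_numpy())

    # Coarsened gene-body integrand: merge runs of occupancy segments into
    # ~3-period spans carrying their length-weighted mean rate.  The E1
    # integral stays exact per span; only the sub-span correlation between
    # the occupancy pattern and the survival curvature is dropped, a
    # second-order effect well below the fit tolerances.
    genic = field.gene_idx >= 0
    gidx = field.gene_idx[genic]
    d1 = field.d_start[genic]
    d2 = field.d_end[genic]
    w = field.rate[genic]
    merge = 6   # core+linker pairs per merged span
    within = np.arange(len(gidx))
    first = np.concatenate(([0], np.nonzero(np.diff(gidx))[0] + 1))
    offset = within - np.repeat(first, np.diff(np.append(first, len(gidx))))
    group = gidx * 100_000 + offset // merge   # < 1e5 merged spans per gene
    _, inv = np.unique(group, return_inverse=True)
    n_grp = inv.max() + 1
    seg_len = d2 - d1
    m_d1 = np.full(n_grp, np.inf)
    np.minimum.at(m_d1, inv, d1)
    m_d2 = np.zeros(n_grp)
    np.maximum.at(m_d2, inv, d2)
    m_wlen = np.bincount(inv, weights=w * seg_len, minlength=n_grp)
    m_gidx = np.zeros(n_grp, dtype=np.int64)
    m_gidx[inv] = gidx
    m_w = m_wlen / (m_d2 - m_d1)
    tpm = genes.genes["tpm"].to_numpy()
    f_g = params.f_tpm(tpm)
    n_genes_all = len(genes.genes)
    mass0 = np.bincount(m_gidx, weights=m_w * (m_d2 - m_d1),
                        minlength=n_genes_all)

    def expected(k_max: float, lam_w: float, k_b: float) -> np.ndarray:
        a = k_max * f_g[m_gidx] * t
        m_t = m_w * _survival_mass(m_d1, m_d2, a, lam_w) * np.exp(-k_b * t)
        num = np.bincount(m_gidx, weights=m_t, minlength=n_genes_all)
        with np.errstate(invalid="ignore"):
            return num / mass0

    def resid(logp: np.ndarray) -> np.ndarray:
        e = expected(*np.exp(logp))[mask]
        return (np.log(np.clip(e, 1e-300, None)) - logR) * sqrt_w

    grid = [(km, lw, kb)
            for km in np.geomspace(0.05, 5.0, 7)
            for lw in np.geomspace(1e3, 1e5, 7)
            for kb in (1e-3, 1e-2, 1e-1)]
    best = min(grid, key=lambda g: float(np.sum(resid(np.log(g)) ** 2)))
    sol = optimize.least_squares(
        resid, np.log(best),
        bounds=(np.log([1e-4, 1e2, 1e-6]), np.log([50.0, 1e7, 10.0])))
    k_max, lam_w, k_b = np.exp(sol.x)
    return RemovalFit(float(k_max), float(lam_w), float(k_b),
                      float(np.sum(sol.fun ** 2)), int(mask.sum()),
                      bool(sol.success))


def spearman_residual_tpm(residual: ResidualTable, genes: GeneSet,
                          tpm_min: float = 0.1) -> tuple[float, int]:
    """Spearman correlation between per-gene residual ratios and expression,
    over genes with TPM >= ``tpm_min``: negative under transcription-coupled
    removal."""
    tpm = genes.genes.set_index("gene_id")["tpm"]
    r = residual.usable
    joint = pd.DataFrame({"R": r, "tpm": tpm.reindex(r.index)}).dropna()
    joint = joint[joint["tpm"] >= tpm_min]
    rho = stats.spearmanr(joint["R"], joint["tpm"]).statistic
    return float(rho), len(joint)
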