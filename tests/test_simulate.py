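"""Simulator: determinism, deposition geometry, removal model, sampling."""

import numpy as np
import pandas as pd
import pytest

from dpcseq.simulate import (SimParams, apply_removal, deposition_field,
                             expected_residual, global_survival,
                             removal_masses, sample_reads,
                             simulate_experiment, simulate_gene_universe,
                             survival)


def small_params(**kw):
    kw.setdefault("n_genes", 100)
    kw.setdefault("chrom_sizes", {"chr1": 12_000_000})
    kw.setdefault("depth", 50_000)
    kw.setdefault("seed", 3)
    return SimParams(**kw)


class TestGeneUniverse:
    def test_deterministic_and_non_overlapping(self):
        p = small_params()
        a = simulate_gene_universe(p, 3)
        b = simulate_gene_universe(p, 3)
        pd.testing.assert_frame_equal(a.genes, b.genes)
        g = a.genes.sort_values(["chrom", "start"])
        gaps = g["start"].to_numpy()[1:] - g["end"].to_numpy()[:-1]
        assert (gaps >= p.gap_min_bp).all()

    def test_lengths_within_configured_bounds(self):
        g = simulate_gene_universe(small_params(), 3).genes
        assert g["length"].between(1_000, 300_000).all()

    def test_zero_inflation_rate(self):
        p = small_params(n_genes=2000, chrom_sizes={"chr1": 140_000_000})
        g = simulate_gene_universe(p, 1).genes
        # binomial 95% CI around 0.3 at n=2000 is about +/-0.02
        assert abs((g["tpm"] == 0).mean() - 0.3) < 0.03

    def test_impossible_placement_raises(self):
        p = small_params(chrom_sizes={"chr1": 100_000})
        with pytest.raises(ValueError, match="chrom_sizes"):
            simulate_gene_universe(p, 3)


class TestDeposition:
    def test_mean_occupancy_over_one_period(self):
        # (147*1 + 50*0.3)/197
        p = small_params()
        f = deposition_field(simulate_gene_universe(p, 3), p)
        genic = f.gene_idx >= 0
        # take one long gene and average occupancy over whole periods
        gi = int(f.gene_idx[genic][np.argmax(f.d_end[genic])])
        sel = genic & (f.gene_idx == gi)
        period = 197
        n_period = int(f.d_end[sel].max() // period)
        inside = sel & (f.d_end <= n_period * period) & (f.d_start >= 50)
        w = ((f.end - f.start)[inside] * f.rate[inside]).sum()
        span = (f.end - f.start)[inside].sum()
        assert w / span == pytest.approx((147 + 50 * 0.3) / 197, rel=0.02)

    def test_inactive_gene_has_no_nfr_dip(self):
        p = small_params()
        gs = simulate_gene_universe(p, 3)
        f = deposition_field(gs, p)
        zero = gs.genes.index[gs.genes["tpm"] == 0][0]
        sel = (f.gene_idx == zero) & (f.d_start < 50)
        # promoter-proximal core occupancy equals the plain core rate
        assert f.rate[sel].max() == pytest.approx(p.d0)

    def test_saturated_nfr_depth(self):
        p = small_params()
        gs = simulate_gene_universe(p, 3)
        gs.genes.loc[0, "tpm"] = 1e9  # TPM >> K
        f = deposition_field(gs, p)
        sel = (f.gene_idx == 0) & (f.d_end <= 50)
        assert f.rate[sel].max() == pytest.approx(0.2 * p.d0, rel=1e-4)

    def test_histone_only_mode_zeroes_background(self):
        p = small_params(histone_only=True)
        gs = simulate_gene_universe(p, 3)
        f = deposition_field(gs, p)
        assert f.rate[f.gene_idx < 0].max() == 0.0
        rs = sample_reads(f, 0.0, "WT", depth=5000, seed_entropy=[1])
        mids = ((rs.intervals["start"] + rs.intervals["end"]) // 2).to_numpy()
        g = gs.genes
        genic = np.zeros(len(mids), dtype=bool)
        for row in g.itertuples(index=False):
            genic |= (mids >= row.start - 200) & (mids < row.end + 200)
        assert genic.all()


class TestRemoval:
    def test_time_zero_is_identity(self):
        p = small_params()
        f = deposition_field(simulate_gene_universe(p, 3), p)
        np.testing.assert_allclose(removal_masses(f, 0.0, "WT"), f.mass0)

    def test_gamma_zero_and_no_background_leaves_field_unchanged(self):
        p = small_params(k_b=0.0, genotype_factors={"none": 0.0})
        f = deposition_field(simulate_gene_universe(p, 3), p)
        np.testing.assert_allclose(removal_masses(f, 4.0, "none"), f.mass0)

    def test_survival_limit_at_tss_high_expression(self):
        p = small_params()
        s = survival(0.0, 1e12, 4.0, "WT", p)
        assert s == pytest.approx(np.exp(-(p.k_b + p.k_max) * 4.0), rel=1e-6)

    def test_negative_time_rejected(self):
        p = small_params()
        f = deposition_field(simulate_gene_universe(p, 3), p)
        with pytest.raises(ValueError):
            removal_masses(f, -1.0, "WT")

    def test_unknown_genotype_rejected(self):
        p = small_params()
        with pytest.raises(KeyError, match="genotype"):
            p.gamma("XYZ")


class TestExpectedResidual:
    def test_position_independent_limit_is_exponential(self):
        p = small_params(lam_w=np.inf)
        gs = simulate_gene_universe(p, 3)
        f = deposition_field(gs, p)
        er = expected_residual(f, 4.0, "WT")
        tpm = gs.genes.set_index("gene_id")["tpm"]
        expected = np.exp(-(p.k_b + p.k_max * tpm / (tpm + p.K)) * 4.0)
        np.testing.assert_allclose(er.to_numpy(), expected.to_numpy(),
                                   rtol=1e-9)

    def test_inactive_gene_without_background_has_unit_residual(self):
        p = small_params(k_b=0.0)
        gs = simulate_gene_universe(p, 3)
        f = deposition_field(gs, p)
        er = expected_residual(f, 4.0, "WT")
        zero = gs.genes["tpm"] == 0
        assert np.allclose(er.to_numpy()[zero], 1.0)

    def test_monotone_in_time_tpm_gamma_and_length(self):
        p = SimParams(n_genes=60, chrom_sizes={"chr1": 20_000_000}, seed=5)
        gs = simulate_gene_universe(p, 5)
        f = deposition_field(gs, p)
        e2 = expected_residual(f, 2.0, "WT").to_numpy()
        e4 = expected_residual(f, 4.0, "WT").to_numpy()
        assert (e4 <= e2 + 1e-12).all()                      # time
        edc = expected_residual(f, 4.0, "dCSB").to_numpy()
        assert (e4 <= edc + 1e-12).all()                     # genotype factor
        g = gs.genes
        active = g["tpm"].to_numpy() > 0
        order = np.argsort(g["tpm"].to_numpy())
        # TPM monotonicity at matched geometry: survival at fixed distance
        d = np.linspace(0, 50_000, 64)
        s_lo = survival(d, np.full_like(d, 1.0), 4.0, "WT", p)
        s_hi = survival(d, np.full_like(d, 100.0), 4.0, "WT", p)
        assert (s_hi <= s_lo).all()
        # length monotonicity at fixed TPM: longer genes retain more
        lengths = np.array([3_000, 10_000, 30_000, 100_000, 300_000])
        vals = []
        for L in lengths:
            gs1 = gs.genes.iloc[:1].copy()
            gs1.loc[:, ["start", "end", "tpm"]] = [10_000, 10_000 + L, 100.0]
            from dpcseq.annotation import GeneSet
            f1 = deposition_field(
                GeneSet(gs1), small_params(chrom_sizes={"chr1": 1_000_000}))
            vals.append(expected_residual(f1, 4.0, "WT").iloc[0])
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_matches_monte_carlo_integration(self):
        p = small_params()
        gs = simulate_gene_universe(p, 3)
        f = deposition_field(gs, p)
        rng = np.random.default_rng(0)
        active = gs.genes.index[gs.genes["tpm"] > 1][:3]
        for gi in active:
            sel = f.gene_idx == gi
            m0 = f.mass0[sel]
            cdf = np.cumsum(m0)
            n = 200_000
            seg = np.searchsorted(cdf, rng.random(n) * m0.sum(), "right")
            d = (f.d_start[sel][seg]
                 + rng.random(n) * (f.d_end - f.d_start)[sel][seg])
            tpm = gs.genes.loc[gi, "tpm"]
            s = survival(d, np.full(n, tpm), 4.0, "WT", p)
            mc, se = s.mean(), s.std(ddof=1) / np.sqrt(n)
            analytic = expected_residual(f, 4.0, "WT").iloc[gi]
            assert abs(mc - analytic) < 3 * max(se, 1e-12)


class TestSampling:
    def test_exact_depth_and_determinism(self, tmp_path):
        p = small_params()
        f = deposition_field(simulate_gene_universe(p, 3), p)
        a = sample_reads(f, 4.0, "WT", depth=20_000, seed_entropy=[9, 1])
        b = sample_reads(f, 4.0, "WT", depth=20_000, seed_entropy=[9, 1])
        assert a.n_mapped == 20_000
        pd.testing.assert_frame_equal(a.intervals, b.intervals)
        a.to_bed6(tmp_path / "a.bed")
        b.to_bed6(tmp_path / "b.bed")
        assert (tmp_path / "a.bed").read_bytes() == \
            (tmp_path / "b.bed").read_bytes()

    def test_uniform_intensity_gives_uniform_midpoints(self):
        from dpcseq.annotation import GeneSet
        # single inactive "gene" covering everything, no nucleosome contrast
        p = SimParams(n_genes=1, chrom_sizes={"chr1": 1_000_000},
                      linker_occupancy=1.0, nfr_alpha=0.0, b0=1.0, seed=1)
        gs = GeneSet(pd.DataFrame([dict(
            gene_id="G0", chrom="chr1", start=0, end=1_000_000, strand="+",
            tpm=0.0)]))
        f = deposition_field(gs, p)
        depth = 100_000
        rs = sample_reads(f, 0.0, "WT", depth=depth, seed_entropy=[4])
        mids = ((rs.intervals["start"] + rs.intervals["end"]) / 2).to_numpy()
        u = np.sort(mids) / 1_000_000
        ks = np.max(np.abs(u - np.arange(1, depth + 1) / depth))
        assert ks < 1.63 / np.sqrt(depth)   # 99% KS bound

    def test_per_gene_read_share_tracks_intensity(self):
        p = small_params(depth=200_000)
        gs = simulate_gene_universe(p, 3)
        f = deposition_field(gs, p)
        rs = sample_reads(f, 0.0, "WT", depth=p.depth, seed_entropy=[8])
        from dpcseq.coverage import count_overlaps
        counts = count_overlaps(rs, gs).counts.to_numpy()
        genic = f.gene_idx >= 0
        mass = np.bincount(f.gene_idx[genic], weights=f.mass0[genic],
                           minlength=len(gs.genes))
        expected = p.depth * mass / f.mass0.sum()
        # fragment-overlap smear adds ~frag_mean of flanking mass per gene
        slack = 3 * np.sqrt(np.maximum(expected, 1)) \
            + p.depth * p.frag_mean * 1.2 * f.rate.max() / f.mass0.sum()
        assert (np.abs(counts - expected) < slack).all()

    def test_zero_intensity_rejected(self):
        p = small_params(d0=0.0, b0=0.0)
        f = deposition_field(simulate_gene_universe(p, 3), p)
        with pytest.raises(ValueError, match="zero"):
            sample_reads(f, 0.0, "WT", depth=10, seed_entropy=[1])


class TestExperiment:
    def test_bundle_determinism_and_subseed_isolation(self, tmp_path):
        p = small_params(depth=5000)
        conds = [("WT", 0.0, 2), ("WT", 4.0, 2)]
        b1 = simulate_experiment(p, conds, seed=7, out_dir=tmp_path / "r1")
        b2 = simulate_experiment(p, conds + [("dCSB", 4.0, 2)], seed=7,
                                 out_dir=tmp_path / "r2")
        for name in ["WT_t0h_rep1", "WT_t0h_rep2", "WT_t4h_rep1"]:
            a = (tmp_path / "r1" / "reads" / f"{name}.bed").read_bytes()
            c = (tmp_path / "r2" / "reads" / f"{name}.bed").read_bytes()
            assert a == c
        assert len(b2.samples) == len(b1.samples) + 2

    def test_duplicate_conditions_rejected(self):
        p = small_params()
        with pytest.raises(ValueError, match="duplicate"):
            simulate_experiment(p, [("WT", 0.0, 2), ("WT", 0.0, 3)], seed=1)

    def test_truth_carries_expected_residual_in_unit_interval(self):
        p = small_params(depth=2000)
        b = simulate_experiment(p, [("WT", 0.0, 1), ("WT", 4.0, 1)], seed=2)
        er = np.array(list(b.truth["expected_residual"]["WT_t4h"].values()))
        assert ((er > 0) & (er <= 1)).all()
        assert 0 < b.truth["global_survival"]["WT_t4h"] <= 1
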