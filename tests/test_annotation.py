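"""Gene-universe construction: longest-transcript selection, overlap
exclusion, chromosome filters, expression attachment, and binning."""

import numpy as np
import pandas as pd
import pytest

from dpcseq.annotation import (AnnotationError, BinningScheme, GeneSet,
                               assign_bins, attach_expression,
                               exclude_overlapping_genes, filter_chromosomes,
                               geneset_from_bed6, length_bins_default,
                               parse_gene_annotation, tpm_bins_default)
from conftest import make_geneset


def write_gtf(path, transcripts):
    """transcripts: (gene_id, transcript_id, chrom, start1, end1, strand)
    with 1-based closed coordinates, one transcript feature per entry."""
    lines = []
    for g, t, c, s, e, strand in transcripts:
        attrs = f'gene_id "{g}"; transcript_id "{t}";'
        lines.append(f"{c}\tsrc\ttranscript\t{s}\t{e}\t.\t{strand}\t.\t{attrs}")
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParseAnnotation:
    def test_longest_transcript_per_gene(self, tmp_path):
        # three genes; the middle one has 4000- and 2500-bp isoforms
        gtf = write_gtf(tmp_path / "a.gtf", [
            ("G1", "T1", "chr1", 1001, 2000, "+"),
            ("G2", "T2a", "chr1", 10001, 14000, "-"),
            ("G2", "T2b", "chr1", 10001, 12500, "-"),
            ("G3", "T3", "chr2", 501, 1300, "+"),
        ])
        gs = parse_gene_annotation(gtf)
        lengths = dict(zip(gs.genes["gene_id"], gs.genes["length"]))
        assert lengths == {"G1": 1000, "G2": 4000, "G3": 800}

    def test_gtf_coordinates_become_zero_based_half_open(self, tmp_path):
        gtf = write_gtf(tmp_path / "a.gtf", [("G1", "T1", "chr1", 101, 200, "+")])
        g = parse_gene_annotation(gtf).genes.iloc[0]
        assert (g.start, g.end) == (100, 200)

    def test_tie_breaks_by_smallest_transcript_id(self, tmp_path):
        gtf = write_gtf(tmp_path / "a.gtf", [
            ("G1", "Tb", "chr1", 1, 5000, "+"),
            ("G1", "Ta", "chr1", 9001, 14000, "+"),
        ])
        g = parse_gene_annotation(gtf).genes.iloc[0]
        assert (g.start, g.end) == (9000, 14000)  # Ta wins the tie

    def test_transcript_extent_inferred_from_exons(self, tmp_path):
        lines = []
        for s, e in [(1001, 1200), (1801, 2000)]:
            lines.append(f"chr1\tsrc\texon\t{s}\t{e}\t.\t+\t."
                         f"\tgene_id \"G1\"; transcript_id \"T1\";")
        p = tmp_path / "exons.gtf"
        p.write_text("\n".join(lines) + "\n")
        g = parse_gene_annotation(p).genes.iloc[0]
        assert (g.start, g.end) == (1000, 2000)

    def test_malformed_record_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text("chr1\tsrc\ttranscript\t1\t100\n")
        with pytest.raises(AnnotationError, match="line 1"):
            parse_gene_annotation(p)

    def test_bed12_single_transcript_identity(self, tmp_path):
        row = ("chr1\t100\t5100\tG9\t0\t-\t100\t5100\t0\t1\t5000\t0")
        p = tmp_path / "a.bed"
        p.write_text(row + "\n")
        g = parse_gene_annotation(p).genes.iloc[0]
        assert (g.gene_id, g.start, g.end, g.strand) == ("G9", 100, 5100, "-")

    def test_idempotent_on_single_transcript_output(self, tmp_path):
        gtf = write_gtf(tmp_path / "a.gtf", [
            ("G1", "T1", "chr1", 1001, 2000, "+"),
            ("G2", "T2a", "chr1", 10001, 14000, "-"),
            ("G2", "T2b", "chr1", 10001, 12500, "-"),
        ])
        gs = parse_gene_annotation(gtf)
        rewritten = write_gtf(tmp_path / "b.gtf", [
            (g.gene_id, g.gene_id, g.chrom, g.start + 1, g.end, g.strand)
            for g in gs])
        again = parse_gene_annotation(rewritten)
        pd.testing.assert_frame_equal(
            gs.genes[["chrom", "start", "end", "strand", "length"]],
            again.genes[["chrom", "start", "end", "strand", "length"]])


class TestOverlapExclusion:
    def test_overlapping_pair_removed_isolated_kept(self):
        gs = make_geneset([("A", "chr1", 0, 1000, "+"),
                           ("B", "chr1", 500, 1500, "-"),
                           ("C", "chr1", 2000, 3000, "+")])
        out = exclude_overlapping_genes(gs)
        assert list(out.genes["gene_id"]) == ["C"]

    def test_identical_coordinates_on_different_chromosomes_kept(self):
        gs = make_geneset([("A", "chr1", 0, 1000, "+"),
                           ("B", "chr2", 0, 1000, "+")])
        assert len(exclude_overlapping_genes(gs)) == 2

    def test_nested_genes_both_removed(self):
        gs = make_geneset([("A", "chr1", 0, 10000, "+"),
                           ("B", "chr1", 2000, 3000, "-")])
        assert len(exclude_overlapping_genes(gs)) == 0

    def test_half_open_adjacency_is_not_overlap(self):
        gs = make_geneset([("A", "chr1", 0, 1000, "+"),
                           ("B", "chr1", 1000, 2000, "+")])
        assert len(exclude_overlapping_genes(gs)) == 2

    def test_matches_brute_force_on_random_sets(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 200))
            start = rng.integers(0, 50_000, n)
            length = rng.integers(1, 3000, n)
            chrom = rng.choice(["chr1", "chr2"], n)
            gs = make_geneset([(f"g{i}", chrom[i], int(start[i]),
                                int(start[i] + length[i]), "+")
                               for i in range(n)])
            out = set(exclude_overlapping_genes(gs).genes["gene_id"])
            # quadratic oracle
            keep = set()
            rows = list(gs.genes.itertuples(index=False))
            for i, a in enumerate(rows):
                ok = all(a.chrom != b.chrom or a.start >= b.end
                         or a.end <= b.start
                         for j, b in enumerate(rows) if i != j)
                if ok:
                    keep.add(a.gene_id)
            assert out == keep


class TestChromosomeFilter:
    def test_human_drops_only_mitochondria(self):
        gs = make_geneset([("A", "chr1", 0, 100, "+"),
                           ("B", "chrM", 0, 100, "+"),
                           ("C", "chrX", 0, 100, "+")])
        out = filter_chromosomes(gs, "human")
        assert list(out.genes["gene_id"]) == ["A", "C"]

    def test_mouse_drops_mitochondria_and_sex_chromosomes(self):
        gs = make_geneset([("A", "chr1", 0, 100, "+"),
                           ("B", "chrX", 0, 100, "+"),
                           ("C", "chrY", 0, 100, "+"),
                           ("D", "chrM", 0, 100, "+")], species_mode="mouse")
        assert list(filter_chromosomes(gs).genes["gene_id"]) == ["A"]

    def test_name_dialects_recognized(self):
        gs = make_geneset([("A", "1", 0, 100, "+"), ("B", "MT", 0, 100, "+"),
                           ("C", "X", 0, 100, "+")], species_mode="mouse")
        assert list(filter_chromosomes(gs).genes["gene_id"]) == ["A"]

    def test_unknown_species_mode_rejected(self):
        gs = make_geneset([("A", "chr1", 0, 100, "+")])
        with pytest.raises(ValueError, match="species_mode"):
            filter_chromosomes(gs, "yeast")

    def test_empty_set_passes_through(self):
        gs = make_geneset([])
        assert len(filter_chromosomes(gs, "human")) == 0


class TestExpression:
    def test_tpm_attached_and_missing_left_nan(self):
        gs = make_geneset([("PKM", "chr1", 0, 1000, "+"),
                           ("GRAMD2A", "chr1", 2000, 3000, "-"),
                           ("G3", "chr1", 4000, 5000, "+")])
        out = attach_expression(gs, {"PKM": 1730.0, "GRAMD2A": 0.3})
        tpm = out.genes.set_index("gene_id")["tpm"]
        assert tpm["PKM"] == 1730.0 and tpm["GRAMD2A"] == 0.3
        assert np.isnan(tpm["G3"])

    def test_empty_table_leaves_all_missing(self):
        gs = make_geneset([("A", "chr1", 0, 100, "+")])
        assert attach_expression(gs, {}).genes["tpm"].isna().all()

    def test_extra_ids_ignored_and_counted(self):
        gs = make_geneset([("A", "chr1", 0, 100, "+")])
        out = attach_expression(gs, {"A": 1.0, "ZZZ": 5.0})
        assert out.n_expression_extra == 1
        assert out.genes["tpm"].iloc[0] == 1.0

    def test_negative_tpm_rejected(self):
        gs = make_geneset([("A", "chr1", 0, 100, "+")])
        with pytest.raises(AnnotationError, match="negative"):
            attach_expression(gs, {"A": -1.0})


class TestBinning:
    def test_length_bin_lookup(self):
        gs = make_geneset([("A", "chr1", 0, 15_000, "+")])
        bins = assign_bins(gs, length_bins_default())
        assert bins["A"] == "10-20 kb"

    def test_boundary_goes_to_left_closed_bin(self):
        gs = make_geneset([("A", "chr1", 0, 20_000, "+")])
        bins = assign_bins(gs, length_bins_default())
        assert bins["A"] == "20-50 kb"

    def test_min_tpm_filter_excludes(self):
        gs = make_geneset([("A", "chr1", 0, 15_000, "+", 50.0),
                           ("B", "chr1", 20_000, 40_000, "+", 150.0)])
        scheme = BinningScheme("length", length_bins_default().edges,
                               min_tpm_filter=100.0)
        bins = assign_bins(gs, scheme)
        assert "A" not in bins.index and bins["B"] == "20-50 kb"

    def test_bins_partition_eligible_genes(self, rng):
        rows = [(f"g{i}", "chr1", i * 10_000, i * 10_000 + int(l), "+",
                 float(t))
                for i, (l, t) in enumerate(zip(
                    rng.integers(500, 400_000, 300),
                    rng.uniform(0, 500, 300)))]
        gs = make_geneset(rows)
        scheme = tpm_bins_default(4)
        bins = assign_bins(gs, scheme)
        n_eligible = int((gs.genes["tpm"] >= scheme.edges[0]).sum())
        assert bins.value_counts().sum() == n_eligible
        assert (bins.index.value_counts() == 1).all()

    def test_seven_default_length_bins(self):
        assert len(length_bins_default().labels) == 7
        assert len(tpm_bins_default(4).labels) == 4
        assert len(tpm_bins_default(6).labels) == 6

    def test_edges_must_ascend(self):
        with pytest.raises(ValueError, match="ascending"):
            BinningScheme("tpm", [1.0, 1.0, 10.0])


def test_bed_round_trip_preserves_coordinates(tmp_path):
    gs = make_geneset([("A", "chr1", 5, 1000, "+", 2.0),
                       ("B", "chr2", 0, 99, "-", np.nan)])
    gs.to_bed6(tmp_path / "g.bed")
    back = geneset_from_bed6(tmp_path / "g.bed")
    pd.testing.assert_frame_equal(
        gs.genes[["gene_id", "chrom", "start", "end", "strand"]],
        back.genes[["gene_id", "chrom", "start", "end", "strand"]])
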