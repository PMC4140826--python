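"""Relation/category taxonomy: definitions, precedence, boundaries, oracles."""

import numpy as np
import pytest

from lncsnp.core_io import GenomicInterval, ValidationError
from lncsnp.locus_classify import (
    assign_category,
    build_association_table,
    classify_relation,
)
from lncsnp.synthetic_data import SimulationConfig, generate_locus_fixture
from .conftest import make_gene, make_lnc


def _random_sets(rng, n_lncs, n_genes, span=200_000):
    genes, lncs = [], []
    for i in range(n_genes):
        start = int(rng.integers(0, span))
        length = int(rng.integers(500, 8000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(1, 4))
        bounds = np.sort(rng.integers(0, length, size=2 * n_ex))
        exons = []
        for k in range(n_ex):
            s, e = int(bounds[2 * k]), int(bounds[2 * k + 1])
            if e <= s:
                e = s + 1
            exons.append(GenomicInterval("chr1", start + s, start + e + 1, strand))
        merged = []
        for ex in exons:  # drop overlaps to honor the exon invariants
            if merged and ex.start < merged[-1].end:
                continue
            merged.append(ex)
        span_iv = GenomicInterval("chr1", start, start + length + 2, strand)
        genes.append(make_gene(f"G{i}", start=span_iv.start, end=span_iv.end,
                               strand=strand, exons=tuple(merged)))
    for i in range(n_lncs):
        start = int(rng.integers(0, span))
        length = int(rng.integers(200, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        lncs.append(make_lnc(f"L{i}", start=start, end=start + length,
                             strand=strand))
    return genes, lncs


class TestClassifyRelation:
    def test_full_overlap_same_strand(self):
        gene = make_gene(strand="-")
        lnc = make_lnc(start=2000, end=2300, strand="-")
        relation, overlap, dist = classify_relation(lnc, gene)
        assert relation == "sense_full_overlap"
        assert overlap == 300 and dist == 0

    def test_upstream_antisense_flank(self):
        # lncRNA on -, gene on +, 2 kb upstream, no overlap
        gene = make_gene(strand="+", start=10_000, end=20_000)
        lnc = make_lnc(start=7700, end=8000, strand="-")
        relation, overlap, dist = classify_relation(lnc, gene)
        assert relation == "flanking_antisense"
        assert overlap == 0
        assert dist == -2000  # upstream of a + gene is negative

    @pytest.mark.parametrize("gap,expected", [
        (5000, "flanking_sense"),
        (5001, "none"),
    ])
    def test_flank_boundary_inclusive(self, gap, expected):
        gene = make_gene(start=100_000, end=110_000, strand="+")
        lnc = make_lnc(start=100_000 - gap - 300, end=100_000 - gap, strand="+")
        relation, _, _ = classify_relation(lnc, gene)
        assert relation == expected

    def test_one_nucleotide_overlap_counts(self):
        gene = make_gene(start=1000, end=9000, strand="+")
        lnc = make_lnc(start=700, end=1001, strand="+")
        relation, overlap, _ = classify_relation(lnc, gene)
        assert relation == "sense_intersecting" and overlap == 1

    def test_different_chromosomes_none(self):
        gene = make_gene(chrom="chr2")
        lnc = make_lnc(chrom="chr1", start=2000, end=2300)
        assert classify_relation(lnc, gene)[0] == "none"

    def test_unstranded_rejected(self):
        gene = make_gene(strand=".", exons=(GenomicInterval("chr1", 1000, 9000, "."),))
        lnc = make_lnc(start=2000, end=2300, strand="+")
        with pytest.raises(ValidationError):
            classify_relation(lnc, gene)

    def test_downstream_distance_positive_for_plus_gene(self):
        gene = make_gene(start=1000, end=9000, strand="+")
        lnc = make_lnc(start=10_000, end=10_300, strand="+")
        _, _, dist = classify_relation(lnc, gene)
        assert dist == 1000


class TestAssignCategory:
    def test_exon_overlap_is_sense_exonic(self):
        gene = make_gene()
        lnc = make_lnc(start=1200, end=1500)  # inside exon 1 [1000,1500)
        assert assign_category(lnc, [gene]) == "sense_exonic"

    def test_intronic_same_strand_is_sense_non_exonic(self):
        gene = make_gene()  # intron spans [1500, 8500)
        lnc = make_lnc(start=3000, end=3300)
        assert assign_category(lnc, [gene]) == "sense_non_exonic"

    def test_opposite_strand_overlap_is_antisense(self):
        gene = make_gene(strand="+")
        lnc = make_lnc(start=3000, end=3300, strand="-")
        assert assign_category(lnc, [gene]) == "antisense"

    def test_nearby_no_overlap_is_intergenic(self):
        gene = make_gene(start=10_000, end=20_000)
        lnc = make_lnc(start=6000, end=7000)  # 3 kb upstream
        assert assign_category(lnc, [gene]) == "intergenic"

    def test_far_away_is_unassociated(self):
        gene = make_gene(start=100_000, end=120_000)
        lnc = make_lnc(start=1000, end=2000)
        assert assign_category(lnc, [gene]) == "unassociated"

    def test_precedence_exonic_beats_antisense(self):
        g_plus = make_gene("GP", strand="+")
        g_minus = make_gene("GM", start=1100, end=8000, strand="-",
                            exons=(GenomicInterval("chr1", 1100, 8000, "-"),))
        lnc = make_lnc(start=1200, end=1500, strand="+")
        assert assign_category(lnc, [g_minus, g_plus]) == "sense_exonic"

    def test_category_recovery_on_constructed_fixture(self):
        cfg = SimulationConfig(seed=11, n_genes=40, n_lncs=120)
        genes, lncs, truth, _ = generate_locus_fixture(cfg)
        for lnc in lncs:
            assert assign_category(lnc, genes, cfg.flank) == truth[lnc.gene_id]


class TestAssociationTable:
    def test_no_overlaps_empty(self):
        genes = [make_gene(start=100_000, end=120_000)]
        lncs = [make_lnc(start=1000, end=2000)]
        records, summary = build_association_table(lncs, genes)
        assert records == []
        assert (summary[["n_lncRNA_genes", "n_candidate_genes"]] == 0).all().all()

    def test_full_overlap_counts_in_both_regimes(self):
        genes = [make_gene()]
        lncs = [make_lnc(start=2000, end=2300)]
        _, summary = build_association_table(lncs, genes)
        counts = dict(zip(summary["regime"], summary["n_lncRNA_genes"]))
        assert counts["sense_intersecting"] == 1
        assert counts["sense_full_overlap"] == 1

    def test_matches_bruteforce_all_pairs(self, rng):
        genes, lncs = _random_sets(rng, n_lncs=300, n_genes=60)
        records, _ = build_association_table(lncs, genes)
        expected = set()
        for lnc in lncs:
            for gene in genes:
                relation, overlap, dist = classify_relation(lnc, gene)
                if relation != "none":
                    expected.add((lnc.gene_id, gene.gene_id, relation, overlap, dist))
        got = {(r.lnc_id, r.gene_id, r.relation, r.overlap_bp, r.distance_bp)
               for r in records}
        assert got == expected

    def test_order_invariance(self, rng):
        genes, lncs = _random_sets(rng, n_lncs=80, n_genes=20)
        rec1, sum1 = build_association_table(lncs, genes)
        perm_l = [lncs[i] for i in rng.permutation(len(lncs))]
        perm_g = [genes[i] for i in rng.permutation(len(genes))]
        rec2, sum2 = build_association_table(perm_l, perm_g)
        assert rec1 == rec2
        assert sum1.equals(sum2)

    def test_regime_nesting_subset(self, rng):
        genes, lncs = _random_sets(rng, n_lncs=200, n_genes=50)
        records, _ = build_association_table(lncs, genes)
        full = {(r.lnc_id, r.gene_id) for r in records
                if r.relation == "sense_full_overlap"}
        inter = {(r.lnc_id, r.gene_id) for r in records
                 if r.relation in ("sense_intersecting", "sense_full_overlap")}
        assert full <= inter

    def test_every_lnc_gets_exactly_one_category(self, rng):
        genes, lncs = _random_sets(rng, n_lncs=150, n_genes=40)
        from lncsnp.locus_classify import CATEGORIES

        for lnc in lncs:
            cat = assign_category(lnc, genes)
            assert cat in CATEGORIES
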