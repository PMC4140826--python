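"""Strand-aware classification of lncRNAs against candidate genes.

Two vocabularies are produced:

* **relation** between one lncRNA and one gene — ``sense_full_overlap`` (lncRNA
  span fully inside the gene span on the same strand), ``sense_intersecting``
  (>= 1 nt same-strand overlap), ``antisense_intersecting`` (>= 1 nt
  opposite-strand overlap), ``flanking_sense`` / ``flanking_antisense`` (no
  overlap but gap <= flank, default 5 kb, inclusive), or ``none``.

* **category** of one lncRNA against a whole gene set — ``sense_exonic`` >
  ``sense_non_exonic`` > ``antisense`` > ``intergenic`` > ``unassociated``,
  resolved by that precedence when a lncRNA relates to several genes.

Flank gaps are measured from gene-span boundaries and a gap of exactly
``flank`` still counts as flanking (bedtools-window semantics).  The distance
sign is oriented by the gene strand: negative upstream of the gene start,
positive downstream of the gene end.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core_io import GeneModel, LncRNAGene, ValidationError

RELATIONS = (
    "sense_intersecting",
    "sense_full_overlap",
    "antisense_intersecting",
    "flanking_sense",
    "flanking_antisense",
    "none",
)

CATEGORIES = ("sense_exonic", "sense_non_exonic", "antisense", "intergenic", "unassociated")

#: Regimes reported in the association summary; ``sense_intersecting`` counts
#: include full overlaps (the nesting mirrors the published count pattern).
SUMMARY_REGIMES = (
    "sense_intersecting",
    "sense_full_overlap",
    "antisense_intersecting",
    "flanking_sense",
    "flanking_antisense",
)


@dataclass(frozen=True)
class AssociationRecord:
    lnc_id: str
    gene_id: str
    relation: str
    overlap_bp: int
    distance_bp: int

    def __post_init__(self) -> None:
        overlapping = self.relation in (
            "sense_intersecting",
            "sense_full_overlap",
            "antisense_intersecting",
        )
        if overlapping != (self.overlap_bp > 0):
            raise ValidationError(
                f"{self.lnc_id}/{self.gene_id}: overlap_bp inconsistent with relation"
            )


def _require_stranded(gene: GeneModel) -> None:
    if not gene.interval.stranded:
        raise ValidationError(
            f"{gene.gene_id}: strand-aware classification requires a stranded record"
        )


def _signed_distance(lnc: LncRNAGene, gene: GeneModel) -> int:
    """Gap between non-overlapping spans, oriented by the gene strand."""
    li, gi = lnc.interval, gene.interval
    if li.end <= gi.start:
        gap, left_of_gene = gi.start - li.end, True
    else:
        gap, left_of_gene = li.start - gi.end, False
    upstream = left_of_gene if gi.strand == "+" else not left_of_gene
    return -gap if upstream else gap


def classify_relation(
    lnc: LncRNAGene, gene: GeneModel, flank: int = 5000
) -> tuple[str, int, int]:
    """Classify the (lncRNA, gene) pair; returns (relation, overlap_bp, distance_bp)."""
    _require_stranded(lnc)
    _require_stranded(gene)
    li, gi = lnc.interval, gene.interval
    if li.chrom != gi.chrom:
        return "none", 0, 0
    overlap = li.overlap_bp(gi)
    same_strand = li.strand == gi.strand
    if overlap > 0:
        if same_strand:
            relation = "sense_full_overlap" if gi.contains(li) else "sense_intersecting"
        else:
            relation = "antisense_intersecting"
        return relation, overlap, 0
    distance = _signed_distance(lnc, gene)
    if abs(distance) <= flank:
        return ("flanking_sense" if same_strand else "flanking_antisense"), 0, distance
    return "none", 0, distance


def assign_category(
    lnc: LncRNAGene, genes: Sequence[GeneModel], flank: int = 5000
) -> str:
    """Assign the single positional category of ``lnc`` against a gene set."""
    _require_stranded(lnc)
    li = lnc.interval
    best = "unassociated"
    order = {c: i for i, c in enumerate(CATEGORIES)}
    for gene in genes:
        _require_stranded(gene)
        gi = gene.interval
        if li.chrom != gi.chrom:
            continue
        overlap = li.overlap_bp(gi)
        if overlap > 0:
            if li.strand == gi.strand:
                exonic = any(li.overlap_bp(e) > 0 for e in gene.exons)
                cat = "sense_exonic" if exonic else "sense_non_exonic"
            else:
                cat = "antisense"
        elif abs(_signed_distance(lnc, gene)) <= flank:
            cat = "intergenic"
        else:
            continue
        if order[cat] < order[best]:
            best = cat
            if best == "sense_exonic":
                break
    return best


def _gene_trees(genes: Sequence[GeneModel], flank: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        gi = gene.interval
        # pad by flank + 1 so a gap of exactly `flank` still intersects the tree
        trees[gi.chrom].addi(max(0, gi.start - flank - 1), gi.end + flank + 1, gene)
    return trees


def build_association_table(
    lncs: Sequence[LncRNAGene],
    genes: Sequence[GeneModel],
    flank: int = 5000,
) -> tuple[list[AssociationRecord], pd.DataFrame]:
    """All (lncRNA, gene) pairs with relation != none, plus per-regime counts.

    Candidate genes are found through a per-chromosome interval tree padded by
    ``flank``; every surviving pair is classified with :func:`classify_relation`.
    The summary counts distinct lncRNA ids and distinct gene ids per regime,
    with full overlaps also counted under ``sense_intersecting``.
    """
    trees = _gene_trees(genes, flank)
    records: list[AssociationRecord] = []
    for lnc in lncs:
        li = lnc.interval
        tree = trees.get(li.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(li.start, li.end),
                      key=lambda h: (h.data.interval.start, h.data.gene_id))
        for hit in hits:
            gene = hit.data
            relation, overlap, distance = classify_relation(lnc, gene, flank)
            if relation == "none":
                continue
            records.append(
                AssociationRecord(lnc.gene_id, gene.gene_id, relation, overlap, distance)
            )
    records.sort(key=lambda r: (r.lnc_id, r.gene_id, r.relation))
    summary = summarize_associations(records)
    return records, summary


def summarize_associations(records: Iterable[AssociationRecord]) -> pd.DataFrame:
    """Distinct lncRNA / gene counts per overlap regime."""
    lnc_sets: dict[str, set] = {r: set() for r in SUMMARY_REGIMES}
    gene_sets: dict[str, set] = {r: set() for r in SUMMARY_REGIMES}
    for rec in records:
        regimes = [rec.relation]
        if rec.relation == "sense_full_overlap":
            regimes.append("sense_intersecting")
        for regime in regimes:
            lnc_sets[regime].add(rec.lnc_id)
            gene_sets[regime].add(rec.gene_id)
    return pd.DataFrame(
        {
            "regime": SUMMARY_REGIMES,
            "n_lncRNA_genes": [len(lnc_sets[r]) for r in SUMMARY_REGIMES],
            "n_candidate_genes": [len(gene_sets[r]) for r in SUMMARY_REGIMES],
        }
    )


def associations_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lnc_id": r.lnc_id,
                "gene_id": r.gene_id,
                "relation": r.relation,
                "overlap_bp": r.overlap_bp,
                "distance_bp": r.distance_bp,
            }
            for r in records
        ],
        columns=["lnc_id", "gene_id", "relation", "overlap_bp", "distance_bp"],
    )
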