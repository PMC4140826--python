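"""Nominal-significance filtering and mapping of variants into lncRNA genes.

A variant maps to a lncRNA when its (0-based) position lies inside the lncRNA
gene span.  Exonic hits additionally get a spliced-transcript offset: introns
are removed and, for minus-strand genes, the offset counts from the 3' genomic
end so that it indexes the transcript in sense orientation.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .core_io import LncRNAGene, ValidationError, Variant


@dataclass(frozen=True)
class VariantAssignment:
    variant_id: str
    lnc_id: str
    inside_exon: bool
    offset_in_transcript: Optional[int] = None


def filter_nominal(
    variants: Sequence[Variant], disease: str, alpha: float = 0.01
) -> list[Variant]:
    """Keep variants with ``assoc_p[disease] < alpha`` (strict inequality).

    Variants lacking a p-value for ``disease`` are dropped.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must lie in (0, 1], got {alpha}")
    return [v for v in variants if disease in v.assoc_p and v.assoc_p[disease] < alpha]


def transcript_offset(lnc: LncRNAGene, pos: int) -> Optional[int]:
    """0-based offset of genomic position ``pos`` in the spliced transcript.

    Returns None for intronic positions.  Minus-strand transcripts are indexed
    from the 3' genomic end (sense orientation).
    """
    forward = 0
    for exon in lnc.exons:
        if exon.contains_pos(pos):
            forward += pos - exon.start
            break
        forward += len(exon)
    else:
        return None
    if lnc.interval.strand == "-":
        return lnc.exonic_length - 1 - forward
    return forward


def map_variants(
    variants: Sequence[Variant], lncs: Sequence[LncRNAGene]
) -> list[VariantAssignment]:
    """Assign every variant to every lncRNA whose span contains it.

    Intronic assignments are retained (``inside_exon=False``) so that later
    stages can report them as unscoreable rather than silently dropping them.
    Offsets are emitted only for exonic hits on lncRNAs that carry a
    transcript sequence.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for lnc in lncs:
        iv = lnc.interval
        trees[iv.chrom].addi(iv.start, iv.end, lnc)
    assignments: list[VariantAssignment] = []
    for v in variants:
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.at(v.pos), key=lambda h: h.data.gene_id):
            lnc: LncRNAGene = hit.data
            offset = transcript_offset(lnc, v.pos)
            inside_exon = offset is not None
            if lnc.transcript_seq is None:
                offset = None
            assignments.append(
                VariantAssignment(
                    variant_id=v.id,
                    lnc_id=lnc.gene_id,
                    inside_exon=inside_exon,
                    offset_in_transcript=offset,
                )
            )
    assignments.sort(key=lambda a: (a.variant_id, a.lnc_id))
    return assignments


def shared_variants(
    set_a: Sequence[VariantAssignment], set_b: Sequence[VariantAssignment]
) -> list[str]:
    """Variant ids present in both assignment sets, deduplicated and sorted."""
    ids_a = {a.variant_id for a in set_a}
    ids_b = {b.variant_id for b in set_b}
    return sorted(ids_a & ids_b)


def assignments_to_frame(assignments: Sequence[VariantAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": a.variant_id,
                "lnc_id": a.lnc_id,
                "inside_exon": a.inside_exon,
                "offset": "" if a.offset_in_transcript is None else a.offset_in_transcript,
            }
            for a in assignments
        ],
        columns=["variant_id", "lnc_id", "inside_exon", "offset"],
    )
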