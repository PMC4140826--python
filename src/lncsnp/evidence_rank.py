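"""Annotate structure-disruptive variants with regulatory/eQTL/selection/LD
evidence and rank them.

Ranking is a lexicographic sort over the evidence types in the order they are
prioritized: regulatory score (ordered categories, lower = more evidence,
unknown last), presence of at least one cis-eQTL, recent positive selection
(|iHS| >= 2.5), then the disruption p-value, with a final positional
(chrom, pos, variant_id) tie-break so the order is total and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError, Variant
from .structure_disruption import DisruptionResult

#: RegulomeDB-style ordered score vocabulary, strongest evidence first.
DEFAULT_REGULOME_ORDER = (
    "1a", "1b", "1c", "1d", "1e", "1f",
    "2a", "2b", "2c",
    "3a", "3b",
    "4", "5", "6", "7",
)

DEFAULT_CIS_WINDOW = 1_000_000
DEFAULT_IHS_THRESHOLD = 2.5


@dataclass(frozen=True)
class EvidenceRecord:
    variant_id: str
    regulome_score: Optional[str] = None  # None = unknown
    eqtl_hits: tuple[tuple[str, str, float], ...] = ()  # (gene_id, tissue, p)
    under_selection: bool = False
    ihs: Optional[float] = None
    ld_partners: tuple[tuple[str, float], ...] = ()  # (variant_id, r2)


@dataclass(frozen=True)
class RankedVariant:
    variant_id: str
    rank: int  # 1-based
    disruption: DisruptionResult
    evidence: EvidenceRecord


def attach_evidence(
    variants: Sequence[Variant],
    regulome_table: Optional[pd.DataFrame] = None,
    eqtl_table: Optional[pd.DataFrame] = None,
    ihs_table: Optional[pd.DataFrame] = None,
    tss_table: Optional[pd.DataFrame] = None,
    cis_window: int = DEFAULT_CIS_WINDOW,
    ihs_threshold: float = DEFAULT_IHS_THRESHOLD,
    regulome_order: Sequence[str] = DEFAULT_REGULOME_ORDER,
) -> list[EvidenceRecord]:
    """One evidence record per variant; missing annotations become unknown/absent.

    eQTL rows are kept only when ``|variant_pos - TSS| <= cis_window``
    (inclusive); rows for genes without a TSS entry are dropped.  Annotation
    never changes the variant set.
    """
    vocab = set(regulome_order)
    reg: dict[str, str] = {}
    if regulome_table is not None:
        for row in regulome_table.itertuples(index=False):
            score = str(row.score)
            if score not in vocab:
                raise ValidationError(f"unknown regulatory score {score!r}")
            reg[str(row.variant_id)] = score
    ihs: dict[str, float] = {}
    if ihs_table is not None:
        for row in ihs_table.itertuples(index=False):
            val = float(row.ihs)
            if not np.isfinite(val):
                raise ValidationError(f"non-finite iHS for {row.variant_id}")
            ihs[str(row.variant_id)] = val
    tss: dict[str, int] = {}
    if tss_table is not None:
        for row in tss_table.itertuples(index=False):
            tss[str(row.gene_id)] = int(row.tss_pos)
    eqtl: dict[str, list[tuple[str, str, float]]] = {}
    if eqtl_table is not None:
        for row in eqtl_table.itertuples(index=False):
            eqtl.setdefault(str(row.variant_id), []).append(
                (str(row.gene_id), str(row.tissue), float(row.p))
            )
    records = []
    for v in variants:
        hits = tuple(
            (g, t, p)
            for (g, t, p) in eqtl.get(v.id, [])
            if g in tss and abs(v.pos - tss[g]) <= cis_window
        )
        score = ihs.get(v.id)
        records.append(
            EvidenceRecord(
                variant_id=v.id,
                regulome_score=reg.get(v.id),
                eqtl_hits=hits,
                under_selection=score is not None and abs(score) >= ihs_threshold,
                ihs=score,
            )
        )
    return records


def ld_r2(dosages_a: Sequence[int], dosages_b: Sequence[int]) -> float:
    """Composite LD: squared Pearson correlation of genotype dosages (0/1/2)."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("dosage vectors must be 1-D and of equal length")
    if a.size < 3:
        raise ValidationError("need >= 3 individuals")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValidationError("LD undefined for a constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def rank_key(
    result: DisruptionResult,
    evidence: EvidenceRecord,
    variant: Variant,
    regulome_order: Sequence[str] = DEFAULT_REGULOME_ORDER,
) -> tuple:
    """Explicit comparator tuple; sorting by it defines the ranking."""
    order = {s: i for i, s in enumerate(regulome_order)}
    reg_rank = order.get(evidence.regulome_score, len(order))  # unknown last
    return (
        reg_rank,
        0 if evidence.eqtl_hits else 1,
        0 if evidence.under_selection else 1,
        result.p_value,
        variant.chrom,
        variant.pos,
        variant.id,
    )


def rank_variants(
    results: Sequence[DisruptionResult],
    evidence: Sequence[EvidenceRecord],
    variants: Mapping[str, Variant],
    p_threshold: float = 0.2,
    regulome_order: Sequence[str] = DEFAULT_REGULOME_ORDER,
) -> list[RankedVariant]:
    """Rank significant disruption results by the lexicographic comparator.

    Only results with ``p_value <= p_threshold`` are admitted.  The output
    order is total, deterministic and invariant to input order.
    """
    ev_by_id = {e.variant_id: e for e in evidence}
    admitted = []
    for res in results:
        if res.p_value > p_threshold:
            continue
        ev = ev_by_id.get(res.variant_id, EvidenceRecord(variant_id=res.variant_id))
        admitted.append((res, ev))
    admitted.sort(
        key=lambda pair: rank_key(pair[0], pair[1], variants[pair[0].variant_id],
                                  regulome_order)
    )
    return [
        RankedVariant(variant_id=res.variant_id, rank=i + 1, disruption=res, evidence=ev)
        for i, (res, ev) in enumerate(admitted)
    ]


def ranked_to_frame(ranked: Sequence[RankedVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "variant_id": r.variant_id,
                "lnc_id": r.disruption.lnc_id,
                "p_value": r.disruption.p_value,
                "d": r.disruption.d,
                "regulome": r.evidence.regulome_score or "unknown",
                "n_eqtl": len(r.evidence.eqtl_hits),
                "selection": r.evidence.under_selection,
            }
            for r in ranked
        ],
        columns=["rank", "variant_id", "lnc_id", "p_value", "d", "regulome",
                 "n_eqtl", "selection"],
    )
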