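"""FPKM expression filtering and Spearman correlation analyses.

Genes are called expressed across all tissues when FPKM > threshold (strictly,
default 1.0) in every tissue.  Correlations are Spearman rank correlations
(average ranks for ties, Pearson correlation of the ranks), computed from the
raw FPKM values: the log10 transform used for display is strictly monotone and
therefore cannot change a rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import ValidationError

DEFAULT_FPKM_THRESHOLD = 1.0


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r_s: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("a reported correlation needs n >= 3 tissue pairs")
        if abs(self.r_s) > 1.0 + 1e-12:
            raise ValidationError("|r_s| must be <= 1")


class ExpressionMatrix:
    """Gene x tissue FPKM matrix (non-negative, unique gene ids)."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        numeric = values.astype(float)
        if (numeric.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        self.values = numeric

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)


def expressed_across_all(
    m: ExpressionMatrix, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> set[str]:
    """Genes with FPKM strictly > threshold in every tissue."""
    if m.values.shape[1] < 1:
        raise ValidationError("expression matrix needs >= 1 tissue column")
    mask = (m.values > threshold).all(axis=1)
    return set(m.values.index[mask])


def not_detected_fraction(
    m: ExpressionMatrix, threshold: float = DEFAULT_FPKM_THRESHOLD
) -> float:
    """Fraction of genes with FPKM <= threshold in all tissues."""
    if len(m.genes) == 0:
        return 0.0
    mask = (m.values <= threshold).all(axis=1)
    return float(mask.mean())


def average_ranks(x: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their rank block."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_correlation(
    x: Sequence[float], y: Sequence[float], pair: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired samples must have equal length")
    if x.size < 3:
        raise ValidationError("need n >= 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValidationError("correlation undefined for a constant vector")
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    r = float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
    return CorrelationResult(pair=pair, r_s=r, n=int(x.size))


def host_lnc_correlations(
    m: ExpressionMatrix, pairs: Sequence[tuple[str, str]]
) -> tuple[list[CorrelationResult], list[tuple[str, str]]]:
    """Spearman correlation per (lncRNA, host gene) pair over shared tissues.

    Pairs with a missing member (or a constant expression vector) are returned
    in the skipped list rather than raising.
    """
    results: list[CorrelationResult] = []
    skipped: list[tuple[str, str]] = []
    index = set(m.values.index)
    for lnc_id, gene_id in pairs:
        if lnc_id not in index or gene_id not in index:
            skipped.append((lnc_id, gene_id))
            continue
        x = m.values.loc[lnc_id].to_numpy()
        y = m.values.loc[gene_id].to_numpy()
        try:
            results.append(spearman_correlation(x, y, pair=(lnc_id, gene_id)))
        except ValidationError:
            skipped.append((lnc_id, gene_id))
    return results, skipped


def tissue_correlation_matrix(
    m: ExpressionMatrix, genes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Symmetric tissue x tissue Spearman correlation matrix."""
    sub = m.values.loc[list(genes)] if genes is not None else m.values
    tissues = list(sub.columns)
    k = len(tissues)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            r = spearman_correlation(
                sub.iloc[:, i].to_numpy(), sub.iloc[:, j].to_numpy(),
                pair=(tissues[i], tissues[j]),
            ).r_s
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=tissues, columns=tissues)


def correlations_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"id_a": r.pair[0], "id_b": r.pair[1], "r_s": r.r_s, "n": r.n} for r in results],
        columns=["id_a", "id_b", "r_s", "n"],
    )
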