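"""Length, GC and repeat-class composition statistics for lncRNA sets.

The two comparison tests used throughout are the Welch two-sample t-test
(unequal variances, Welch-Satterthwaite degrees of freedom) and the chi-square
goodness-of-fit test of an observed repeat-class distribution against
background proportions, with per-class adjusted standardized residuals
``(O_i - E_i) / sqrt(E_i (1 - p_i))``; classes with |residual| > 1.96 are
flagged as enriched (positive) or depleted (negative).  The statistics are
computed from their defining formulas; only the t and chi-square distribution
tails come from scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .core_io import (
    GeneModel,
    LncRNAGene,
    REPEAT_CLASSES,
    RepeatRecord,
    ValidationError,
)

RESIDUAL_FLAG_Z = 1.96


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    residuals: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")
        if self.df <= 0:
            raise ValidationError("degrees of freedom must be positive")

    @property
    def flagged_classes(self) -> dict[str, str]:
        """Classes with |adjusted residual| > 1.96, labelled enriched/depleted."""
        if self.residuals is None:
            return {}
        return {
            cls: ("enriched" if r > 0 else "depleted")
            for cls, r in self.residuals.items()
            if abs(r) > RESIDUAL_FLAG_Z
        }


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (#unambiguous bases); ambiguity codes excluded."""
    if not seq:
        raise ValidationError("empty sequence")
    s = seq.upper()
    gc = sum(s.count(b) for b in "GC")
    atu = sum(s.count(b) for b in "ATU")
    denom = gc + atu
    if denom == 0:
        raise ValidationError("sequence has no unambiguous bases")
    return gc / denom


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch two-sample t-test (two-sided)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each sample needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        raise ValidationError("both samples are degenerate (zero variance)")
    sem2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(sem2)
    df = sem2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * _stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=min(1.0, max(p, 5e-324)))


def repeat_composition(
    repeats: Sequence[RepeatRecord], lncs: Sequence[GeneModel]
) -> tuple[dict[str, int], float]:
    """Per-class counts of repeats overlapping lncRNAs, and the harboring fraction.

    A repeat counts toward a lncRNA when their spans overlap by >= 1 bp,
    strand-agnostically (genomic repeats are annotated irrespective of the
    transcript strand).  Each repeat contributes one hit per class regardless
    of how many lncRNAs it touches; the harboring fraction is the share of
    lncRNAs overlapped by at least one repeat.
    """
    counts = {cls: 0 for cls in REPEAT_CLASSES}
    harboring: set[str] = set()
    for rep in repeats:
        hit = False
        for lnc in lncs:
            if rep.interval.overlap_bp(lnc.interval) > 0:
                harboring.add(lnc.gene_id)
                hit = True
        if hit:
            counts[rep.repeat_class] += 1
    frac = len(harboring) / len(lncs) if lncs else 0.0
    return counts, frac


def class_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {cls: 0.0 for cls in counts}
    return {cls: 100.0 * n / total for cls, n in counts.items()}


def chisq_enrichment(
    observed: Mapping[str, int],
    background: Mapping[str, int],
    adjusted_residuals: bool = True,
) -> TestResult:
    """Chi-square goodness of fit of observed class counts vs background.

    Expected counts are ``E_i = N * p_i`` with ``p_i`` the background
    proportions.  Residuals are adjusted, ``(O_i - E_i)/sqrt(E_i (1 - p_i))``,
    by default; plain Pearson residuals ``(O_i - E_i)/sqrt(E_i)`` behind the
    flag.
    """
    classes = [c for c in observed if c in background]
    if len(classes) < 2:
        raise ValidationError("need >= 2 classes shared by observed and background")
    O = np.array([float(observed[c]) for c in classes])
    B = np.array([float(background[c]) for c in classes])
    if (B <= 0).any():
        raise ValidationError("all background counts must be > 0")
    N = O.sum()
    if N <= 0:
        raise ValidationError("observed counts sum to zero")
    p = B / B.sum()
    E = N * p
    x2 = float(((O - E) ** 2 / E).sum())
    df = len(classes) - 1
    pval = float(_stats.chi2.sf(x2, df))
    denom = np.sqrt(E * (1.0 - p)) if adjusted_residuals else np.sqrt(E)
    residuals = {c: float((O[i] - E[i]) / denom[i]) for i, c in enumerate(classes)}
    return TestResult(
        statistic=x2, df=float(df), p_value=min(1.0, max(pval, 5e-324)),
        residuals=residuals,
    )


def composition_summary(lncs: Sequence[LncRNAGene]) -> dict[str, float]:
    """Per-gene (unweighted) mean genomic length and mean transcript GC."""
    lengths = [len(l.interval) for l in lncs]
    gcs = [gc_content(l.transcript_seq) for l in lncs if l.transcript_seq]
    return {
        "n": len(lncs),
        "mean_length": float(np.mean(lengths)) if lengths else 0.0,
        "mean_gc": float(np.mean(gcs)) if gcs else float("nan"),
    }
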