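"""Score single-nucleotide variants for lncRNA secondary-structure disruption.

The procedure mirrors the mode-1 style local-perturbation screen: fold a
window of +/- ``radius`` nt (default 200) of the spliced transcript around the
variant, compute equilibrium base-pair probability matrices for wild type and
mutant, find the local region (containing the variant, minimum length
``min_region``) that maximizes the length-normalized Euclidean distance between
the two matrices, and convert the observed distance into an empirical p-value
against random single-nucleotide substitutions in the same window.  A variant
is called structure-disruptive when the empirical p-value is <= 0.2.

The folding engine is an exact inside-outside partition function over a
uniform pair-energy model (see :mod:`lncsnp._fold`); it is deterministic and
checkable against exhaustive structure enumeration for short sequences.  A
thermodynamic engine could be substituted behind
:func:`base_pair_probabilities` without changing any downstream contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import _fold
from .core_io import LncRNAGene, RNA_COMPLEMENT, ValidationError
from .variant_map import VariantAssignment

DEFAULT_RADIUS = 200
DEFAULT_MIN_REGION = 50
DEFAULT_P_THRESHOLD = 0.2


class NotScoreableError(ValueError):
    """The assignment cannot be folded (intronic, or no transcript)."""


class ReferenceMismatchError(ValueError):
    """Transcript base disagrees with the variant's reference allele."""


@dataclass(frozen=True)
class FoldWindow:
    """A transcript subsequence centred (up to clipping) on a variant."""

    sequence: str
    snp_offset: int
    window_radius: int = DEFAULT_RADIUS
    origin: tuple[str, int] = ("", 0)  # (lnc_id, transcript offset of window start)

    def __post_init__(self) -> None:
        if not (0 <= self.snp_offset < len(self.sequence)):
            raise ValidationError("snp_offset outside window")
        if len(self.sequence) > 2 * self.window_radius + 1:
            raise ValidationError("window longer than 2*radius + 1")


@dataclass(frozen=True)
class BasePairMatrix:
    """Symmetric matrix of equilibrium base-pair probabilities."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = self.P
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValidationError("pair matrix must be square")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValidationError("pair matrix must be symmetric")
        if P.min() < -1e-12 or P.max() > 1.0 + 1e-9:
            raise ValidationError("pair probabilities outside [0, 1]")
        if P.shape[0] and P.sum(axis=1).max() > 1.0 + 1e-9:
            raise ValidationError("a position pairs with total probability > 1")

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class DisruptionResult:
    variant_id: str
    lnc_id: str
    region: tuple[int, int]  # 0-based inclusive window coordinates
    d: float
    p_value: float
    significant: bool
    snp_offset: int = 0
    window_start: int = 0  # transcript offset of window position 0


@dataclass(frozen=True)
class ScoreConfig:
    """Knobs of the disruption screen (defaults follow the published protocol)."""

    radius: int = DEFAULT_RADIUS
    min_region: int = DEFAULT_MIN_REGION
    n_background: int = 1000
    p_threshold: float = DEFAULT_P_THRESHOLD
    wobble: bool = True
    pair_weight: float = _fold.PAIR_WEIGHT
    seed: int = 0


def base_pair_probabilities(
    seq: str, wobble: bool = True, pair_weight: float = _fold.PAIR_WEIGHT
) -> BasePairMatrix:
    """Equilibrium pair probabilities of ``seq`` under the uniform pair model."""
    if not (1 <= len(seq) <= 2000):
        raise ValidationError(f"sequence length {len(seq)} outside [1, 2000]")
    code = _fold.encode(seq)
    P = _fold.pair_probabilities(code, _fold.pair_table(wobble), pair_weight)
    return BasePairMatrix(P=P)


def enumerate_pair_probabilities(
    seq: str, wobble: bool = True, pair_weight: float = _fold.PAIR_WEIGHT
) -> np.ndarray:
    """Reference pair probabilities by exhaustive structure enumeration.

    Every secondary structure (nested pair set with min hairpin loop 3 and no
    lone pairs: each pair stacked on an inner or outer neighbour) is generated
    explicitly and Boltzmann-weighted by ``pair_weight ** n_pairs``.
    Exponential: intended for sequences of length <= ~25 as an independent
    oracle for the partition function.
    """
    n = len(seq)
    code = _fold.encode(seq)
    can = _fold.pair_table(wobble)

    def structures(i: int, j: int):
        # all nested pair sets over positions i..j inclusive (lone pairs are
        # filtered afterwards, keeping the generator independent of the DP)
        if j - i < _fold.MIN_HAIRPIN + 1:
            yield ()
            return
        # position i unpaired
        for s in structures(i + 1, j):
            yield s
        for k in range(i + _fold.MIN_HAIRPIN + 1, j + 1):
            if can[code[i], code[k]]:
                for inner in structures(i + 1, k - 1):
                    for outer in structures(k + 1, j):
                        yield ((i, k),) + inner + outer

    def no_lone_pairs(struct) -> bool:
        pairs = set(struct)
        return all(
            (i + 1, k - 1) in pairs or (i - 1, k + 1) in pairs for i, k in pairs
        )

    P = np.zeros((n, n))
    total = 0.0
    for struct in structures(0, n - 1):
        if not no_lone_pairs(struct):
            continue
        weight = pair_weight ** len(struct)
        total += weight
        for (i, k) in struct:
            P[i, k] += weight
    P /= total
    return P + P.T


def extract_window(
    lnc: LncRNAGene, assignment: VariantAssignment, ref: str, alt: str,
    radius: int = DEFAULT_RADIUS,
) -> tuple[FoldWindow, FoldWindow]:
    """Wild-type and mutant fold windows of +/- ``radius`` nt around the variant.

    ``ref``/``alt`` are the genomic plus-strand DNA alleles; for minus-strand
    genes they are complemented before comparison/substitution, because the
    transcript is stored in sense orientation.  Windows are clipped (never
    discarded) at transcript ends.
    """
    if not assignment.inside_exon or assignment.offset_in_transcript is None:
        raise NotScoreableError(
            f"{assignment.variant_id}/{assignment.lnc_id}: not an exonic position "
            "with transcript sequence"
        )
    seq = lnc.transcript_seq
    if seq is None:
        raise NotScoreableError(f"{lnc.gene_id}: no transcript sequence")
    offset = assignment.offset_in_transcript
    ref_rna = ref.replace("T", "U")
    alt_rna = alt.replace("T", "U")
    if lnc.interval.strand == "-":
        ref_rna = RNA_COMPLEMENT[ref_rna]
        alt_rna = RNA_COMPLEMENT[alt_rna]
    if seq[offset] != ref_rna:
        raise ReferenceMismatchError(
            f"{assignment.variant_id}: transcript base {seq[offset]!r} at offset "
            f"{offset} of {lnc.gene_id} does not match reference allele {ref_rna!r}"
        )
    start = max(0, offset - radius)
    end = min(len(seq), offset + radius + 1)
    wt_seq = seq[start:end]
    snp_offset = offset - start
    mut_seq = wt_seq[:snp_offset] + alt_rna + wt_seq[snp_offset + 1 :]
    origin = (lnc.gene_id, start)
    wt = FoldWindow(wt_seq, snp_offset, radius, origin)
    mut = FoldWindow(mut_seq, snp_offset, radius, origin)
    return wt, mut


def disruption_score(
    P_wt: BasePairMatrix,
    P_mut: BasePairMatrix,
    snp_offset: int,
    min_region: int = DEFAULT_MIN_REGION,
) -> tuple[tuple[int, int], float]:
    """Local region of maximal base-pair probability change and its distance.

    Over all inclusive windows [i, j] with ``j - i + 1 >= min_region`` that
    contain ``snp_offset``::

        d(i, j) = sqrt( sum_{i <= u < v <= j} (Pwt[u,v] - Pmut[u,v])^2 ) / (j - i + 1)

    Returns the maximizing region (ties: smallest i, then smallest j) and d.
    For windows shorter than ``min_region`` the whole window is the only
    admissible region.
    """
    n = P_wt.n
    if P_mut.n != n:
        raise ValidationError(f"matrix dimension mismatch: {n} vs {P_mut.n}")
    if not (0 <= snp_offset < n):
        raise ValidationError("snp_offset outside matrices")
    min_region = min(min_region, n)
    diff2 = np.triu((P_wt.P - P_mut.P) ** 2, k=1)
    # 2-D prefix sums padded with a leading zero row/column
    C = np.zeros((n + 1, n + 1))
    C[1:, 1:] = diff2.cumsum(axis=0).cumsum(axis=1)

    i_vals = np.arange(0, snp_offset + 1)  # candidate region starts
    j_vals = np.arange(snp_offset, n)  # candidate region ends
    # rectangle sum of diff2 over rows i..j, cols i..j (upper triangle only)
    ii = i_vals[:, None]
    jj = j_vals[None, :]
    S = C[jj + 1, jj + 1] - C[ii, jj + 1] - C[jj + 1, ii] + C[ii, ii]
    lengths = jj - ii + 1
    with np.errstate(invalid="ignore"):
        D = np.sqrt(np.maximum(S, 0.0)) / lengths
    D[lengths < min_region] = -1.0
    flat = int(np.argmax(D))  # first occurrence in row-major order = smallest i then j
    bi, bj = divmod(flat, D.shape[1])
    region = (int(i_vals[bi]), int(j_vals[bj]))
    return region, float(D[bi, bj])


def _random_substitution(seq: str, rng: np.random.Generator) -> tuple[int, str]:
    pos = int(rng.integers(len(seq)))
    alts = [b for b in "ACGU" if b != seq[pos]]
    return pos, alts[int(rng.integers(3))]


def empirical_pvalue(
    d_obs: float,
    wt_window: FoldWindow,
    n_background: int = 1000,
    seed: int | None = None,
    min_region: int = DEFAULT_MIN_REGION,
    wobble: bool = True,
    pair_weight: float = _fold.PAIR_WEIGHT,
    P_wt: BasePairMatrix | None = None,
) -> float:
    """Empirical p-value of ``d_obs`` against random substitutions in the window.

    Draws ``n_background`` random single-nucleotide substitutions (position
    uniform over the window, alternative uniform over the three non-reference
    bases), scores each against the wild type with the same region search, and
    returns ``(1 + #{d_bg >= d_obs}) / (n_background + 1)`` (add-one smoothing,
    so p is never 0 and never below ``1/(n+1)``).
    """
    if n_background < 19:
        raise ValidationError("n_background must be >= 19")
    rng = np.random.default_rng(seed)
    if P_wt is None:
        P_wt = base_pair_probabilities(wt_window.sequence, wobble, pair_weight)
    seq = wt_window.sequence
    exceed = 0
    for _ in range(n_background):
        pos, alt = _random_substitution(seq, rng)
        mut = seq[:pos] + alt + seq[pos + 1 :]
        P_bg = base_pair_probabilities(mut, wobble, pair_weight)
        _, d_bg = disruption_score(P_wt, P_bg, pos, min_region)
        if d_bg >= d_obs:
            exceed += 1
    return (1 + exceed) / (n_background + 1)


def score_variant(
    lnc: LncRNAGene,
    assignment: VariantAssignment,
    ref: str,
    alt: str,
    config: ScoreConfig = ScoreConfig(),
) -> DisruptionResult:
    """Full disruption screen for one exonic variant assignment."""
    wt, mut = extract_window(lnc, assignment, ref, alt, config.radius)
    P_wt = base_pair_probabilities(wt.sequence, config.wobble, config.pair_weight)
    P_mut = base_pair_probabilities(mut.sequence, config.wobble, config.pair_weight)
    region, d = disruption_score(P_wt, P_mut, wt.snp_offset, config.min_region)
    p = empirical_pvalue(
        d,
        wt,
        n_background=config.n_background,
        seed=config.seed,
        min_region=config.min_region,
        wobble=config.wobble,
        pair_weight=config.pair_weight,
        P_wt=P_wt,
    )
    return DisruptionResult(
        variant_id=assignment.variant_id,
        lnc_id=lnc.gene_id,
        region=region,
        d=d,
        p_value=p,
        significant=p <= config.p_threshold,
        snp_offset=wt.snp_offset,
        window_start=wt.origin[1],
    )


# ---------------------------------------------------------------------------
# Calibration utilities
# ---------------------------------------------------------------------------

def substitution_distance_table(
    window: FoldWindow,
    min_region: int = DEFAULT_MIN_REGION,
    wobble: bool = True,
    pair_weight: float = _fold.PAIR_WEIGHT,
) -> np.ndarray:
    """Disruption distance of every possible substitution in the window.

    Returns an (L, 3) array: row = position, column = index into the three
    non-reference bases in A<C<G<U order.  Because the engine is deterministic,
    this table fully characterizes the background distribution that
    :func:`empirical_pvalue` samples from.
    """
    seq = window.sequence
    P_wt = base_pair_probabilities(seq, wobble, pair_weight)
    table = np.zeros((len(seq), 3))
    for pos in range(len(seq)):
        alts = [b for b in "ACGU" if b != seq[pos]]
        for a_idx, alt in enumerate(alts):
            mut = seq[:pos] + alt + seq[pos + 1 :]
            P_mut = base_pair_probabilities(mut, wobble, pair_weight)
            _, d = disruption_score(P_wt, P_mut, pos, min_region)
            table[pos, a_idx] = d
    return table


def null_pvalue_sample(
    window: FoldWindow,
    n_background: int,
    n_replicates: int,
    seed: int | None = None,
    min_region: int = DEFAULT_MIN_REGION,
    wobble: bool = True,
) -> np.ndarray:
    """Empirical p-values when the "observed" variant is itself a null draw.

    Each replicate draws one observed substitution and ``n_background``
    background substitutions, all iid uniform over (position, alternative), and
    computes the add-one-smoothed p-value.  Distances are looked up in the
    precomputed :func:`substitution_distance_table`, which is exactly the
    computation :func:`empirical_pvalue` performs draw by draw.  Used to verify
    that the p-values are calibrated (uniform under the null).
    """
    table = substitution_distance_table(window, min_region, wobble)
    flat = table.ravel()
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_replicates)
    for r in range(n_replicates):
        d_obs = flat[int(rng.integers(flat.size))]
        d_bg = flat[rng.integers(flat.size, size=n_background)]
        pvals[r] = (1 + int((d_bg >= d_obs).sum())) / (n_background + 1)
    return pvals


def results_to_frame(results: Sequence[DisruptionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "lnc_id": r.lnc_id,
                "region_start": r.region[0],
                "region_end": r.region[1],
                "d": r.d,
                "p_value": r.p_value,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=[
            "variant_id", "lnc_id", "region_start", "region_end", "d",
            "p_value", "significant",
        ],
    )


def dot_plot_frame(P_wt: BasePairMatrix, P_mut: BasePairMatrix) -> pd.DataFrame:
    """Dot-plot-style matrix: upper triangle wild type, lower triangle mutant."""
    if P_wt.n != P_mut.n:
        raise ValidationError("matrix dimension mismatch")
    M = np.triu(P_wt.P, k=1) + np.tril(P_mut.P, k=-1)
    return pd.DataFrame(M)
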