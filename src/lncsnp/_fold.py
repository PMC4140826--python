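"""Inside-outside partition-function kernel for the uniform-energy helix model.

Every admissible base pair (AU, UA, GC, CG and optionally GU, UG) contributes
the same Boltzmann weight ``w``; hairpin loops must enclose at least three
unpaired bases; lone pairs are forbidden — every helix must stack at least two
pairs (the ``--noLP`` simplification of thermodynamic folders), which gives
the model helix cooperativity; there are no dangle or multiloop terms.

The inside recursion uses an unambiguous decomposition with four quantities
(spans are inclusive ``[i, j]``; empty spans score 1):

    Q(i, j)  = u * Q(i+1, j) + sum_k Qh(i, k) * Q(k+1, j)   any structure
    Qh(i, j) = wp(i, j) * H(i+1, j-1)                        outer helix pair
    H(a, b)  = wp(a, b) * ( Qn(a+1, b-1) + H(a+1, b-1) )     helix continuation
    Qn(a, b) = Q(a, b) - Qh(a, b)                            (a, b) not mutually
                                                             paired (helix ends)

``wp(i, j)`` is the pair weight when ``i``/``j`` can pair and ``j - i >= 4``,
else 0.  The matching outside pass yields exact pair probabilities.  Each
position is rescaled by ``1/s`` to keep the numbers in double range; the scale
cancels in every probability.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: kcal/mol per kelvin times 310.15 K (37 C)
RT = 0.0019872 * 310.15

#: Boltzmann weight per base pair: -2 kcal/mol per pair at 37 C, a compromise
#: between strong GC and weak AU stacks under a uniform-energy model.
PAIR_WEIGHT = float(np.exp(2.0 / RT))

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

MIN_HAIRPIN = 3  # unpaired bases a hairpin loop must enclose
MIN_HELIX = 2  # stacked pairs a helix must contain (no lone pairs)


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"invalid RNA base {exc.args[0]!r}; alphabet is A/C/G/U") from exc


def pair_table(wobble: bool = True) -> np.ndarray:
    can = np.zeros((4, 4), dtype=np.bool_)
    for a, b in ("AU", "UA", "GC", "CG"):
        can[_BASE_CODE[a], _BASE_CODE[b]] = True
    if wobble:
        for a, b in ("GU", "UG"):
            can[_BASE_CODE[a], _BASE_CODE[b]] = True
    return can


@njit(cache=True)
def _inside_outside(code, can, w, scale):  # pragma: no cover - exercised via wrapper
    n = code.size
    P = np.zeros((n, n))
    # smallest helix: 2 pairs + 3-nt loop = span of 7 positions
    if n < 2 * MIN_HELIX + MIN_HAIRPIN:
        return P, 1.0
    u = 1.0 / scale
    wp = w / (scale * scale)
    Q = np.zeros((n, n))
    Qh = np.zeros((n, n))
    H = np.zeros((n, n))

    def _q(i, j):
        return Q[i, j] if i <= j else 1.0

    for d in range(n):
        for i in range(n - d):
            j = i + d
            pairable = d >= MIN_HAIRPIN + 1 and can[code[i], code[j]]
            if pairable:
                # helix continuation at (i, j): end here (interior must not
                # extend the stack) or stack one more pair inward
                qn_in = (_q(i + 1, j - 1) - Qh[i + 1, j - 1]) if i + 1 <= j - 1 else 1.0
                H[i, j] = wp * (qn_in + H[i + 1, j - 1])
                Qh[i, j] = wp * H[i + 1, j - 1]
            v = u * (Q[i + 1, j] if d >= 1 else 1.0)
            for k in range(i + 2 * MIN_HELIX + MIN_HAIRPIN - 1, j + 1):
                qh = Qh[i, k]
                if qh != 0.0:
                    v += qh * (Q[k + 1, j] if k + 1 <= j else 1.0)
            Q[i, j] = v
    total = Q[0, n - 1]
    if not np.isfinite(total) or total <= 0.0:
        return P, total

    OQ = np.zeros((n, n))
    OQh = np.zeros((n, n))
    OH = np.zeros((n, n))
    OQn = np.zeros((n, n))
    OQ[0, n - 1] = 1.0
    for d in range(n - 1, -1, -1):
        for i in range(n - d):
            j = i + d
            # expand Qn(i, j) = Q(i, j) - Qh(i, j)
            oqn = OQn[i, j]
            if oqn != 0.0:
                OQ[i, j] += oqn
                OQh[i, j] -= oqn
            oq = OQ[i, j]
            if oq != 0.0:
                if d >= 1:
                    OQ[i + 1, j] += u * oq
                for k in range(i + 2 * MIN_HELIX + MIN_HAIRPIN - 1, j + 1):
                    if Qh[i, k] != 0.0:
                        OQh[i, k] += oq * (Q[k + 1, j] if k + 1 <= j else 1.0)
                        if k + 1 <= j:
                            OQ[k + 1, j] += oq * Qh[i, k]
            pairable = d >= MIN_HAIRPIN + 1 and can[code[i], code[j]]
            if pairable:
                oqh = OQh[i, j]
                oh = OH[i, j]
                if oqh != 0.0:
                    OH[i + 1, j - 1] += wp * oqh
                if oh != 0.0:
                    OQn[i + 1, j - 1] += wp * oh
                    OH[i + 1, j - 1] += wp * oh
                # pair emissions at (i, j): outer pair of a helix, or
                # continuation pair inside a helix
                qn_in = (_q(i + 1, j - 1) - Qh[i + 1, j - 1]) if i + 1 <= j - 1 else 1.0
                h_in = H[i + 1, j - 1]
                p = (oqh * wp * h_in + oh * wp * (qn_in + h_in)) / total
                if p > 0.0:
                    P[i, j] = p
                    P[j, i] = p
    return P, total


def pair_probabilities(
    code: np.ndarray, can: np.ndarray, w: float = PAIR_WEIGHT
) -> np.ndarray:
    """Pair-probability matrix, retrying the rescale factor on over/underflow."""
    n = code.size
    # short-circuit sequences with no admissible pair at any admissible span
    pairable = False
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            if can[code[i], code[j]]:
                pairable = True
                break
        if pairable:
            break
    if not pairable:
        return np.zeros((n, n))
    base = float(np.sqrt(w))
    for scale in (base, base * 1.6, base * 0.6, base * 2.6, 1.1, base * 4.0):
        P, total = _inside_outside(code, can, w, scale)
        if np.isfinite(total) and total > 0.0:
            return P
    raise FloatingPointError(
        f"partition function out of double range for n={n}; no rescale factor worked"
    )
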