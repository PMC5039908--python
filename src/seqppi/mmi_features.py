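"""Multivariate mutual information (MMI) sequence descriptors.

A protein sequence is first re-coded over the seven functional groups,
then scanned with sliding windows of length 2 and 3.  Each window is
typed by the *unordered multiset* of its group codes, so there are
C(8,2) = 28 two-gram types and C(9,3) = 84 three-gram types.  From the
window counts we compute, per type,

    I(a,b)   = f(a,b) ln( f(a,b) / (f(a) f(b)) )
    I(a,b,c) = I(a,b) - [ H(a|c) - H(a|b,c) ]
    H(a|c)   = -( f(a,c)/f(c) ) ln( f(a,c)/f(c) )
    H(a|b,c) = -( f(a,b,c)/f(b,c) ) ln( f(a,b,c)/f(b,c) )

with every frequency estimated with a +1 pseudocount, f = (n+1)/(W+1)
over the W windows of the relevant width (W = L for single categories),
so no logarithm ever sees zero.  All logs are natural.  Appending the
seven pseudocount group frequencies gives the 84 + 28 + 7 = 119-value
per-protein descriptor; a protein pair is the 238-value concatenation.

The equations are evaluated per *single* sequence (one "event" per
window type), not over an ensemble, and the printed frequency ratios
f(a,c)/f(c) are not bounded by 1 because numerator and denominator use
different window counts; the conditional-"entropy" terms may therefore
be negative.  They are computed exactly as defined.
"""

from __future__ import annotations

from itertools import combinations_with_replacement
from math import log
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import N_GROUPS, encode_sequence

__all__ = [
    "enumerate_types",
    "count_kgrams",
    "pseudo_frequency",
    "mi2",
    "mi3",
    "mmi_vector",
    "mmi_pair",
    "mmi_feature_names",
    "MMIEncoder",
]


def enumerate_types(k: int) -> list[tuple[int, ...]]:
    """All multisets of ``k`` group codes as sorted tuples, lexicographic.

    k=1 -> 7 types, k=2 -> 28, k=3 -> 84.  The order is frozen: it defines
    the within-block feature ordering of the descriptor vector.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    return list(combinations_with_replacement(range(N_GROUPS), k))


# frozen type -> position maps, shared by counting and vector assembly
_TYPES = {k: enumerate_types(k) for k in (1, 2, 3)}
_TYPE_INDEX = {k: {t: i for i, t in enumerate(ts)} for k, ts in _TYPES.items()}


def count_kgrams(codes: Sequence[int] | np.ndarray, k: int) -> dict[tuple[int, ...], int]:
    """Sliding-window multiset counts of ``k`` consecutive group codes.

    Returns a dict over *all* types of size ``k`` (absent types count 0).
    The window count is ``L - k + 1``.
    """
    codes = np.asarray(codes, dtype=np.int64)
    L = codes.size
    if k not in (1, 2, 3):
        raise ValueError(f"k must be 1, 2 or 3, got {k}")
    if L < k:
        raise ValueError(f"sequence shorter than window: L={L} < k={k}")
    if k == 1:
        windows = codes[:, None]
    else:
        windows = np.sort(
            np.stack([codes[i : L - k + 1 + i] for i in range(k)], axis=1), axis=1
        )
    flat = windows @ (N_GROUPS ** np.arange(k - 1, -1, -1))
    hist = np.bincount(flat, minlength=N_GROUPS**k)
    counts = {}
    for t in _TYPES[k]:
        key = 0
        for c in t:
            key = key * N_GROUPS + c
        counts[t] = int(hist[key])
    return counts


def pseudo_frequency(count: int, windows: int) -> float:
    """Pseudocount frequency (count+1)/(windows+1), strictly in (0, 1]."""
    if windows < 0:
        raise ValueError(f"negative window count: {windows}")
    if not 0 <= count <= windows + 0:
        raise ValueError(f"count {count} outside [0, {windows}]")
    return (count + 1) / (windows + 1)


def mi2(fab: float, fa: float, fb: float) -> float:
    """Pairwise term f(a,b) ln( f(a,b) / (f(a) f(b)) ), natural log."""
    if fab <= 0 or fa <= 0 or fb <= 0:
        raise ValueError("frequencies must be positive")
    return fab * log(fab / (fa * fb))


def _neg_xlogx(ratio: float) -> float:
    return -ratio * log(ratio)


def mi3(
    kgram_type: tuple[int, int, int],
    counts2: dict[tuple[int, ...], int],
    counts3: dict[tuple[int, ...], int],
    singles: dict[tuple[int, ...], int] | Sequence[int],
    L: int,
    role_mode: str = "canonical",
) -> float:
    """Three-way term I(a,b,c) = I(a,b) - [H(a|c) - H(a|b,c)] for one type.

    The defining equations are not symmetric under permutation of the
    three categories, while a window type is an unordered multiset; the
    roles are therefore fixed by convention.  ``role_mode="canonical"``
    takes (a, b, c) as the sorted tuple itself; ``"average"`` averages
    over the three choices of which element plays c (a sensitivity mode).
    """
    t = tuple(sorted(kgram_type))
    if len(t) != 3:
        raise ValueError("kgram_type must have exactly 3 categories")
    if L < 3:
        raise ValueError("sequence shorter than a 3-gram window")
    if not isinstance(singles, dict):
        singles = {(g,): int(n) for g, n in enumerate(singles)}
    W2, W3 = L - 1, L - 2

    def one(a: int, b: int, c: int) -> float:
        fa = pseudo_frequency(singles[(a,)], L)
        fb = pseudo_frequency(singles[(b,)], L)
        fc = pseudo_frequency(singles[(c,)], L)
        fab = pseudo_frequency(counts2[tuple(sorted((a, b)))], W2)
        fac = pseudo_frequency(counts2[tuple(sorted((a, c)))], W2)
        fbc = pseudo_frequency(counts2[tuple(sorted((b, c)))], W2)
        fabc = pseudo_frequency(counts3[t], W3)
        i_ab = mi2(fab, fa, fb)
        h_a_c = _neg_xlogx(fac / fc)
        h_a_bc = _neg_xlogx(fabc / fbc)
        return i_ab - (h_a_c - h_a_bc)

    if role_mode == "canonical":
        return one(t[0], t[1], t[2])
    if role_mode == "average":
        rolls = [(t[0], t[1], t[2]), (t[0], t[2], t[1]), (t[1], t[2], t[0])]
        return sum(one(a, b, c) for a, b, c in rolls) / 3.0
    raise ValueError(f"unknown role_mode {role_mode!r}")


def mmi_vector(
    seq: str | Sequence[int] | np.ndarray,
    role_mode: str = "canonical",
    on_nonstandard: str = "error",
) -> np.ndarray:
    """The 119-value MMI descriptor of one protein.

    Layout: 84 three-gram terms, 28 two-gram terms, 7 pseudocount group
    frequencies — each block in the frozen lexicographic type order.
    Accepts a residue string or a pre-encoded group-code array.
    """
    if isinstance(seq, str):
        codes = encode_sequence(seq, on_nonstandard=on_nonstandard)
    else:
        codes = np.asarray(seq, dtype=np.int64)
    L = int(codes.size)
    if L < 3:
        raise ValueError(f"sequence too short for 3-gram windows: L={L}")
    singles = count_kgrams(codes, 1)
    counts2 = count_kgrams(codes, 2)
    counts3 = count_kgrams(codes, 3)
    W2 = L - 1

    out = np.empty(119, dtype=float)
    for i, t in enumerate(_TYPES[3]):
        out[i] = mi3(t, counts2, counts3, singles, L, role_mode=role_mode)
    for i, t in enumerate(_TYPES[2]):
        a, b = t
        fab = pseudo_frequency(counts2[t], W2)
        fa = pseudo_frequency(singles[(a,)], L)
        fb = pseudo_frequency(singles[(b,)], L)
        out[84 + i] = mi2(fab, fa, fb)
    for g in range(N_GROUPS):
        out[112 + g] = pseudo_frequency(singles[(g,)], L)
    return out


def mmi_pair(
    seqA: str | Sequence[int],
    seqB: str | Sequence[int],
    role_mode: str = "canonical",
    on_nonstandard: str = "error",
) -> np.ndarray:
    """238-value descriptor of an ordered protein pair: [MMI(A) | MMI(B)]."""
    return np.concatenate(
        [
            mmi_vector(seqA, role_mode=role_mode, on_nonstandard=on_nonstandard),
            mmi_vector(seqB, role_mode=role_mode, on_nonstandard=on_nonstandard),
        ]
    )


def mmi_feature_names() -> list[str]:
    """Column names for the 119 per-protein MMI features."""
    names = [f"mi3_{''.join(f'C{c}' for c in t)}" for t in _TYPES[3]]
    names += [f"mi2_{''.join(f'C{c}' for c in t)}" for t in _TYPES[2]]
    names += [f"f_C{g}" for g in range(N_GROUPS)]
    return names


class MMIEncoder(BaseEstimator, TransformerMixin):
    """Stateless transformer: residue strings -> 119-column MMI matrix.

    Parameters
    ----------
    role_mode : {"canonical", "average"}
        Role assignment inside the three-way term (see :func:`mi3`).
    on_nonstandard : {"error", "drop"}
        Policy for residues outside the 20-letter alphabet.
    """

    def __init__(self, role_mode: str = "canonical", on_nonstandard: str = "error"):
        self.role_mode = role_mode
        self.on_nonstandard = on_nonstandard

    def fit(self, X: Iterable[str], y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        return np.array(
            [
                mmi_vector(s, role_mode=self.role_mode, on_nonstandard=self.on_nonstandard)
                for s in X
            ]
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(mmi_feature_names(), dtype=object)
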