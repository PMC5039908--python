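"""Independent brute-force oracles for the descriptor math.

Everything here is a literal, loop-level transcription of the defining
formulas, sharing no code with the package: window counting by explicit
enumeration, frequencies and logs evaluated term by term.  Used only to
cross-check the vectorized implementations.
"""

from itertools import combinations_with_replacement
from math import log, sqrt

# Independent copy of the 7-group classification.
_GROUP_OF = {}
for _g, _members in enumerate(["AGV", "C", "DE", "FILP", "HNQW", "KR", "MSTY"]):
    for _res in _members:
        _GROUP_OF[_res] = _g

_RES_ORDER = "ACDEFGHIKLMNPQRSTVWY"


def oracle_mmi_vector(sequence: str) -> list[float]:
    """119 MMI values by explicit window enumeration and term-by-term
    evaluation of the mutual-information equations."""
    codes = [_GROUP_OF[ch] for ch in sequence.upper()]
    L = len(codes)
    counts = {}
    for k in (1, 2, 3):
        c = {}
        for i in range(L - k + 1):
            t = tuple(sorted(codes[i : i + k]))
            c[t] = c.get(t, 0) + 1
        counts[k] = c

    def f(t):
        k = len(t)
        windows = L - k + 1
        return (counts[k].get(tuple(sorted(t)), 0) + 1) / (windows + 1)

    out = []
    for a, b, c in combinations_with_replacement(range(7), 3):
        i_ab = f((a, b)) * log(f((a, b)) / (f((a,)) * f((b,))))
        r1 = f((a, c)) / f((c,))
        h_a_c = -r1 * log(r1)
        r2 = f((a, b, c)) / f((b, c))
        h_a_bc = -r2 * log(r2)
        out.append(i_ab - (h_a_c - h_a_bc))
    for a, b in combinations_with_replacement(range(7), 2):
        out.append(f((a, b)) * log(f((a, b)) / (f((a,)) * f((b,)))))
    for g in range(7):
        out.append(f((g,)))
    return out


def oracle_nmbac(sequence: str, raw_table, lg: int = 30) -> list[float]:
    """6*lg + 20 autocorrelation values by double loop over positions.

    ``raw_table`` is the 20x6 grid of raw property values, rows in
    alphabetical residue order; normalization (population z-score) is
    redone here from scratch.
    """
    norm = []
    for j in range(6):
        col = [raw_table[i][j] for i in range(20)]
        mean = sum(col) / 20
        sd = sqrt(sum((v - mean) ** 2 for v in col) / 20)
        norm.append([(v - mean) / sd for v in col])
    seq = sequence.upper()
    idx = [_RES_ORDER.index(ch) for ch in seq]
    n = len(idx)
    out = []
    for j in range(6):
        for lag in range(1, lg + 1):
            total = 0.0
            for i in range(n - lag):
                total += norm[j][idx[i]] * norm[j][idx[i + lag]]
            out.append(total / (n - lag))
    for res in _RES_ORDER:
        out.append(seq.count(res) / n)
    return out


def oracle_auroc(scores, labels) -> float:
    """Pairwise concordance AUROC: P(score_pos > score_neg), ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
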