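"""Shared independent oracle: exhaustive global-alignment enumeration."""
import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(a: str, b: str, alphabet: str,
                           gap_open: float = 10.0,
                           gap_extend: float = 0.5) -> float:
    """Best score over every global alignment, enumerated as move
    sequences with affine gap costs (length-L gap: open + (L-1)*extend).
    Deliberately recurrence-free: independent of any DP implementation."""
    def sub(x, y):
        if alphabet == "protein":
            return float(_B62[x, y])
        return 2.0 if x == y else -3.0

    best = [-np.inf]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub(a[i], b[j]), "D")
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if last == "U" else gap_open),
                "U")
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if last == "L" else gap_open),
                "L")

    rec(0, 0, 0.0, None)
    return best[0]
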