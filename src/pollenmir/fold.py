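"""RNA secondary structure by weighted base-pair maximization.

miRNA precursors are recognised by their fold-back (stem-loop) structure.
This module predicts the maximum-weight *nested* secondary structure of a
sequence with a Nussinov-style dynamic program over weighted base pairs:

    G-C = 3,  A-U = 2,  G-U = 1

with a minimum hairpin loop of 3 unpaired bases.  The optimum is exact for
nested structures (no pseudoknots) and deterministic: when several
structures attain the maximum weight, the traceback pairs the base with the
smaller 5' index.  The weight model is a deliberately self-contained stand-in
for a thermodynamic folding energy — it ranks stems by their hydrogen-bond
content, which is all the downstream hairpin criteria consume — and the
module contract (dot-bracket string plus score) admits a thermodynamic
backend without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqs import encode

#: minimum number of unpaired bases enclosed by a hairpin loop
MIN_LOOP = 3

# pair weight lookup over the A/C/G/T(U)/N encoding of seqs.encode
_WEIGHTS = np.zeros((5, 5), dtype=np.int32)
_WEIGHTS[0, 3] = _WEIGHTS[3, 0] = 2  # A-U
_WEIGHTS[1, 2] = _WEIGHTS[2, 1] = 3  # C-G
_WEIGHTS[2, 3] = _WEIGHTS[3, 2] = 1  # G-U wobble


@dataclass(frozen=True)
class FoldResult:
    structure: str          # dot-bracket notation
    score: int              # total pair weight of the optimum
    pairs: tuple            # pairs[i] = partner index, or -1 if unpaired

    def pair_map(self) -> list[int]:
        return list(self.pairs)


@njit(cache=False)
def _fill(code, weights, min_loop):  # pragma: no cover - exercised via fold()
    n = code.shape[0]
    m = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = weights[code[i], code[k]]
                if w > 0:
                    s = w + m[i + 1, k - 1]
                    if k + 1 <= j:
                        s += m[k + 1, j]
                    if s > best:
                        best = s
            m[i, j] = best
    return m


def _traceback(code: np.ndarray, m: np.ndarray, min_loop: int) -> list[int]:
    n = len(code)
    pairs = [-1] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = m[i, j]
        chosen = -1
        for k in range(i + min_loop + 1, j + 1):
            w = _WEIGHTS[code[i], code[k]]
            if w > 0:
                s = w + m[i + 1, k - 1] + (m[k + 1, j] if k + 1 <= j else 0)
                if s == target:
                    chosen = k
                    break
        if chosen >= 0:
            pairs[i] = chosen
            pairs[chosen] = i
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        else:
            stack.append((i + 1, j))
    return pairs


def fold(sequence: str, max_len: int = 400) -> FoldResult:
    """Fold ``sequence`` and return the maximum-weight nested structure.

    Parameters
    ----------
    sequence:
        DNA or RNA string; T and U are equivalent.
    max_len:
        Guard against accidentally folding huge sequences (the dynamic
        program is cubic).  Precursor windows in this pipeline are at most
        a few hundred nucleotides.
    """
    n = len(sequence)
    if n == 0 or n > max_len:
        raise ValueError(f"sequence length {n} outside foldable range 1..{max_len}")
    code = encode(sequence)
    m = _fill(code, _WEIGHTS, MIN_LOOP)
    pairs = _traceback(code, m, MIN_LOOP)
    struct = "".join(
        "(" if (q := pairs[i]) > i else ")" if 0 <= q < i else "."
        for i in range(n)
    )
    return FoldResult(structure=struct, score=int(m[0, n - 1]), pairs=tuple(pairs))
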