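"""Toy RNA secondary-structure folder.

Nussinov-style maximum base pairing with a minimum hairpin loop of 3 and
deterministic tie-breaking (prefer the 5'-most pair).  No energy model:
this folder exists so that synthetic assays are self-contained; it makes
no claim of parity with a thermodynamic folder such as RNAfold.
"""

from __future__ import annotations

import numpy as np

from .sequences import CANONICAL_PAIRS, normalize_rna

MIN_LOOP = 3


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def fold_toy(seq: str, min_loop: int = MIN_LOOP) -> str:
    """Maximum-pairing dot-bracket structure for ``seq``.

    Dynamic program over intervals; ties resolved by preferring (in order)
    leaving position i unpaired last, and pairing i with the smallest
    admissible j — which yields the 5'-most pairing among optima.
    """
    s = normalize_rna(seq)
    n = len(s)
    if n == 0:
        return ""
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = dp[i + 1, k - 1] if k - 1 > i + 1 else 0
                    rest = dp[k + 1, j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + rest)
            dp[i, j] = best

    struct = ["."] * n

    def traceback(i: int, j: int) -> None:
        # pair position i with the smallest admissible partner whenever doing
        # so still achieves the optimum (5'-most preference), else leave it
        # unpaired and move on
        while i < j:
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    inner = dp[i + 1, k - 1]
                    rest = dp[k + 1, j] if k + 1 <= j else 0
                    if 1 + inner + rest == dp[i, j]:
                        struct[i], struct[k] = "(", ")"
                        traceback(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    traceback(0, n - 1)
    return "".join(struct)


def max_pairs_bruteforce(seq: str, min_loop: int = MIN_LOOP) -> int:
    """Exhaustive maximum pairing count for tiny sequences (test oracle)."""
    s = normalize_rna(seq)

    def rec(positions: tuple[int, ...]) -> int:
        best = 0
        if len(positions) < 2:
            return 0
        i = positions[0]
        rest = positions[1:]
        best = rec(rest)  # i unpaired
        for idx, j in enumerate(rest):
            if j - i > min_loop and _can_pair(s[i], s[j]):
                inner = tuple(p for p in rest[:idx] if i < p < j)
                outer = tuple(p for p in rest[idx + 1:])
                # non-crossing: everything between i and j must nest
                between = tuple(p for p in rest[:idx])
                if between != inner:
                    continue
                best = max(best, 1 + rec(inner) + rec(outer))
        return best

    return rec(tuple(range(len(s))))
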