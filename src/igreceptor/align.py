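"""Global pairwise alignment with a fixed simple scoring scheme.

One Needleman-Wunsch routine backs both the percent-identity computation
and the star alignment of Ig domains onto a profile anchor.  Scoring is
linear-gap (match +2, mismatch -1, gap -2) and traceback ties are resolved
deterministically: diagonal > up (gap in second sequence) > left.
"""

from __future__ import annotations

import numpy as np

MATCH = 2
MISMATCH = -1
GAP = -2


def needleman_wunsch(
    a: str,
    b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
) -> tuple[str, str, int]:
    """Globally align two sequences.

    Returns ``(aligned_a, aligned_b, score)`` where the aligned strings are
    equal length and use ``'-'`` for gaps.

    Raises
    ------
    ValueError
        If either sequence is empty.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    n, m = len(a), len(b)
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)

    F = np.empty((n + 1, m + 1), dtype=np.int64)
    # pointers: 0 diag, 1 up (consume a), 2 left (consume b)
    P = np.zeros((n + 1, m + 1), dtype=np.uint8)
    F[0, :] = gap * np.arange(m + 1)
    F[:, 0] = gap * np.arange(n + 1)
    P[0, 1:] = 2
    P[1:, 0] = 1
    for i in range(1, n + 1):
        sub = np.where(bb == aa[i - 1], match, mismatch)
        diag = F[i - 1, :-1] + sub
        up = F[i - 1, 1:] + gap
        # left has a row-sequential dependency; resolve in a scalar loop but
        # with diag/up precomputed
        row = F[i]
        prow = P[i]
        prev = row[0]
        for j in range(1, m + 1):
            d = diag[j - 1]
            u = up[j - 1]
            left = prev + gap
            if d >= u and d >= left:
                prev = d
                prow[j] = 0
            elif u >= left:
                prev = u
                prow[j] = 1
            else:
                prev = left
                prow[j] = 2
            row[j] = prev

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = P[i, j]
        if p == 0 and i > 0 and j > 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1 and i > 0:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(F[n, m])
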