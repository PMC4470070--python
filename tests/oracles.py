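"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive (dense scans, exhaustive
enumeration) and shares no code with the package's algorithms.
"""

from __future__ import annotations

import numpy as np


def dense_match_coverage(a: np.ndarray, b: np.ndarray, w: int) -> tuple[int, int]:
    """Coverage of each sequence by exact matches >= w, by dense diagonal scan.

    Scans every diagonal of the full comparison matrix on both strands
    and marks positions inside runs of length >= w.  Returns the number
    of covered positions on A and on B.
    """
    comp = np.array([3, 2, 1, 0], dtype=np.uint8)
    na, nb = len(a), len(b)
    cov_a = np.zeros(na, dtype=bool)
    cov_b = np.zeros(nb, dtype=bool)
    for codes_b, reverse in ((b, False), (comp[b[::-1]], True)):
        for d in range(-(nb - 1), na):
            i0, j0 = max(0, d), max(0, -d)
            L = min(na - i0, nb - j0)
            if L < w:
                continue
            eq = a[i0:i0 + L] == codes_b[j0:j0 + L]
            # run-length scan
            run = 0
            for k in range(L + 1):
                if k < L and eq[k]:
                    run += 1
                    continue
                if run >= w:
                    lo = k - run
                    cov_a[i0 + lo:i0 + k] = True
                    if reverse:
                        # map revcomp coordinates back to forward B
                        cov_b[nb - (j0 + k):nb - (j0 + lo)] = True
                    else:
                        cov_b[j0 + lo:j0 + k] = True
                run = 0
    return int(cov_a.sum()), int(cov_b.sum())


def brute_n50(lengths) -> int:
    """Definition-by-enumeration: largest L with sum(x >= L) >= total/2."""
    total = sum(lengths)
    candidates = sorted(set(lengths), reverse=True)
    for L in candidates:
        if sum(x for x in lengths if x >= L) >= total / 2:
            return L
    raise ValueError("empty input")


def exhaustive_best_chain(anchors, max_gap, max_diag_drift):
    """Optimal single co-monotone chain by O(n^2) dynamic programming.

    Score is total anchor length; anchors must be increasing in both
    coordinates with gaps <= max_gap and diagonal drift <= max_diag_drift
    between consecutive members.  Returns the best chain's score.
    """
    items = sorted(anchors, key=lambda a: a.x)
    n = len(items)
    best = [a.length for a in items]
    for i in range(n):
        for j in range(i):
            a, b = items[j], items[i]
            gx = b.x - (a.x + a.length)
            gy = b.y - (a.y + a.length)
            drift = abs((b.y - b.x) - (a.y - a.x))
            if gx < 0 or gy < 0 or gx > max_gap or gy > max_gap or drift > max_diag_drift:
                continue
            best[i] = max(best[i], best[j] + b.length)
    return max(best) if best else 0


def local_alignment_coverage(a, b, window: int = 200, min_identity: float = 0.85) -> float:
    """Coverage of A by local alignments to B, by windowed infix alignment.

    Chops A into fixed windows and asks an edit-distance aligner whether
    each window aligns somewhere in B above the identity floor.  Crude
    (window granularity) but entirely independent of the anchor/chaining
    path it is used to check.
    """
    import edlib

    from haplotile.sequtil import decode

    a_str, b_str = decode(a), decode(b)
    covered = 0
    for i in range(0, len(a_str) - window + 1, window):
        res = edlib.align(a_str[i:i + window], b_str, mode="HW", task="distance")
        if 1.0 - res["editDistance"] / window >= min_identity:
            covered += window
    return covered


def interval_union_length(intervals) -> int:
    """Total covered length of a set of [lo, hi) intervals."""
    total = 0
    end = None
    for lo, hi in sorted(intervals):
        if end is None or lo > end:
            total += hi - lo
            end = hi
        elif hi > end:
            total += hi - end
            end = hi
    return total
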