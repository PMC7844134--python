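"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: the alignment
oracle is a plain dynamic-programming Smith-Waterman, the breakpoint oracle
counts conserved adjacencies by enumeration, and the segmentation oracle is
a direct maximal-run scan.
"""

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_GAP_OPEN_TOTAL = 12   # cost of a length-1 gap (open 11 + extend 1)
_GAP_EXTEND = 1


def smith_waterman_score(a: str, b: str) -> float:
    """Optimal local alignment score, affine gaps (11 + k for length k)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    best = 0.0
    prev_m = [0.0] * (m + 1)
    prev_x = [neg] * (m + 1)
    prev_y = [neg] * (m + 1)
    for i in range(1, n + 1):
        cur_m = [0.0] * (m + 1)
        cur_x = [neg] * (m + 1)   # gap in b (vertical)
        cur_y = [neg] * (m + 1)   # gap in a (horizontal)
        for j in range(1, m + 1):
            cur_x[j] = max(prev_m[j] - _GAP_OPEN_TOTAL, prev_x[j] - _GAP_EXTEND)
            cur_y[j] = max(cur_m[j - 1] - _GAP_OPEN_TOTAL,
                           cur_y[j - 1] - _GAP_EXTEND)
            sub = _BLOSUM62[a[i - 1]][b[j - 1]]
            cur_m[j] = max(0.0,
                           max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1]) + sub)
            if cur_m[j] > best:
                best = cur_m[j]
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


def breakpoint_distance(order_a: list, order_b: list) -> int:
    """Unsigned breakpoints: adjacent pairs of *shared* blocks in ``order_a``
    not adjacent (in either direction) in ``order_b``."""
    shared = set(order_a) & set(order_b)
    sa = [x for x in order_a if x in shared]
    sb = [x for x in order_b if x in shared]
    adj_b = {frozenset(p) for p in zip(sb, sb[1:])}
    return sum(1 for p in zip(sa, sa[1:]) if frozenset(p) not in adj_b)


def maximal_runs(labels: list) -> list[tuple]:
    """Maximal runs of equal labels: [(label, length), ...]."""
    runs = []
    for label in labels:
        if runs and runs[-1][0] == label:
            runs[-1] = (label, runs[-1][1] + 1)
        else:
            runs.append((label, 1))
    return runs
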