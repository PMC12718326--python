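"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by enumeration or closed form,
without touching the implementation paths they check.
"""

from functools import lru_cache


def affine_alignment_score(a: str, b: str, match: float, mismatch: float,
                           gap_open: float, gap_extend: float) -> float:
    """Optimal global affine-gap alignment score by exhaustive recursion
    over the alignment-move graph (memoized; still visits every state).

    A gap of length k scores gap_open + (k - 1) * gap_extend. States track
    whether the previous column gapped sequence a or b, so run continuation
    is charged gap_extend and a fresh run gap_open.
    """

    NONE, GAP_A, GAP_B = 0, 1, 2  # previous column type

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        candidates = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            candidates.append(s + best(i + 1, j + 1, NONE))
        if j < len(b):  # gap in a, consume b[j]
            cost = gap_extend if state == GAP_A else gap_open
            candidates.append(cost + best(i, j + 1, GAP_A))
        if i < len(a):  # gap in b, consume a[i]
            cost = gap_extend if state == GAP_B else gap_open
            candidates.append(cost + best(i + 1, j, GAP_B))
        return max(candidates)

    return best(0, 0, 0)


def all_strings(alphabet: str, max_len: int) -> list[str]:
    out = [""]
    frontier = [""]
    for _ in range(max_len):
        frontier = [s + c for s in frontier for c in alphabet]
        out.extend(frontier)
    return out
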