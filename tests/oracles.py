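"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools
from math import comb

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def gotoh_local(a: str, b: str, gap_open: float = -11.0, gap_extend: float = -1.0):
    """Affine-gap Smith-Waterman by the Gotoh recurrences.

    The first residue of a gap scores ``gap_open``, each further residue
    ``gap_extend`` (matching the convention of the implementation under
    test).  Returns (max score, DP matrices) for traceback.
    """
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (move along b)
    F = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (move along a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best, (H, E, F)


def gotoh_identities(a: str, b: str, gap_open: float = -11.0,
                     gap_extend: float = -1.0, cap: int = 20000) -> set[tuple[int, int]]:
    """(identities, alignment length) over all co-optimal local alignments.

    Exhaustive traceback over every cell attaining the optimal score,
    following every co-optimal predecessor, capped at ``cap`` states.
    """
    best, (H, E, F) = gotoh_local(a, b, gap_open, gap_extend)
    if best <= 0:
        return {(0, 0)}
    results: set[tuple[int, int]] = set()
    stack = []
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            if H[i][j] == best:
                stack.append(("H", i, j, 0, 0))
    seen = 0
    while stack:
        seen += 1
        if seen > cap:  # pragma: no cover - guard for pathological cases
            break
        state, i, j, ident, length = stack.pop()
        if state == "H":
            if H[i][j] == 0:
                results.add((ident, length))
                continue
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            if i and j and H[i][j] == H[i - 1][j - 1] + s:
                stack.append(
                    ("H", i - 1, j - 1, ident + (a[i - 1] == b[j - 1]), length + 1)
                )
            if H[i][j] == E[i][j]:
                stack.append(("E", i, j, ident, length))
            if H[i][j] == F[i][j]:
                stack.append(("F", i, j, ident, length))
        elif state == "E":
            if E[i][j] == H[i][j - 1] + gap_open:
                stack.append(("H", i, j - 1, ident, length + 1))
            if E[i][j] == E[i][j - 1] + gap_extend:
                stack.append(("E", i, j - 1, ident, length + 1))
        else:
            if F[i][j] == H[i - 1][j] + gap_open:
                stack.append(("H", i - 1, j, ident, length + 1))
            if F[i][j] == F[i - 1][j] + gap_extend:
                stack.append(("F", i - 1, j, ident, length + 1))
    return results


def naive_motif_scan(sequence: str, elements) -> list[int]:
    """Position-by-position degenerate pattern matcher."""
    seq = sequence.upper()
    out = []
    for start in range(len(seq) - len(elements) + 1):
        if all(
            el is None or seq[start + k] in el for k, el in enumerate(elements)
        ):
            out.append(start)
    return out


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by enumerating every size-n draw from an N-element urn."""
    population = [1] * K + [0] * (N - K)
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(population[i] for i in draw) >= k
    )
    return hits / comb(N, n)


def ranksum_pvalue_by_enumeration(bin_values, background_values) -> float:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    Assumes no ties.  The p-value is the fraction of assignments whose
    rank-sum is at least as extreme (either tail) as observed, matching
    the doubled-smaller-tail convention.
    """
    values = sorted(list(bin_values) + list(background_values))
    ranks = {v: i + 1 for i, v in enumerate(values)}
    nb = len(bin_values)
    observed = sum(ranks[v] for v in bin_values)
    sums = [
        sum(combo) for combo in itertools.combinations(range(1, len(values) + 1), nb)
    ]
    ge = sum(s >= observed for s in sums) / len(sums)
    le = sum(s <= observed for s in sums) / len(sums)
    return min(1.0, 2 * min(ge, le))


def venn_regions_by_membership(leaf: set, stem: set, root: set) -> dict[str, int]:
    """Seven-region counts by scanning every element of the union."""
    counts = dict.fromkeys(
        ["leaf_only", "stem_only", "root_only", "leaf_stem", "leaf_root",
         "stem_root", "common"], 0
    )
    for g in leaf | stem | root:
        key = {
            (True, False, False): "leaf_only",
            (False, True, False): "stem_only",
            (False, False, True): "root_only",
            (True, True, False): "leaf_stem",
            (True, False, True): "leaf_root",
            (False, True, True): "stem_root",
            (True, True, True): "common",
        }[(g in leaf, g in stem, g in root)]
        counts[key] += 1
    return counts
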