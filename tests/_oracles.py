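"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration rather than
calling the implementation paths they check.
"""

from itertools import permutations

from venomseq.masses import RESIDUE_MASS

_MAX_RES = max(RESIDUE_MASS.values())


def brute_force_best_ladder(mzs, tol):
    """Best (n_positions, n_gaps) score over ALL peak paths, by enumeration.

    Edge semantics mirror the ladder-reading contract: a single-residue step
    when the gap matches a residue mass, otherwise a two-residue bridge when
    the gap exceeds the largest residue mass and matches a residue-pair sum.
    Exponential, only for peak lists of about a dozen peaks.
    """
    n = len(mzs)
    edges = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = mzs[j] - mzs[i]
            if any(abs(m - d) <= tol for m in RESIDUE_MASS.values()):
                edges[i].append((j, 1, 0))
            elif d > _MAX_RES + tol and any(
                abs(m1 + m2 - d) <= tol
                for m1 in RESIDUE_MASS.values()
                for m2 in RESIDUE_MASS.values()
            ):
                edges[i].append((j, 2, 1))
    best = (0, 0)

    def dfs(i, pos, gaps):
        nonlocal best
        if (pos, -gaps) > (best[0], -best[1]):
            best = (pos, gaps)
        for j, p, g in edges[i]:
            dfs(j, pos + p, gaps + g)

    for i in range(n):
        dfs(i, 0, 0)
    return best


def brute_force_substitutions(delta, tol):
    """All ordered non-isobaric residue pairs explaining a mass difference."""
    out = set()
    for a, b in permutations(RESIDUE_MASS, 2):
        if RESIDUE_MASS[a] == RESIDUE_MASS[b]:
            continue
        if abs(RESIDUE_MASS[b] - RESIDUE_MASS[a] - delta) <= tol:
            out.add((a, b))
    return out
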