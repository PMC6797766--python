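"""Independent exhaustive folding oracle for short sequences.

Enumerates every nested structure (min hairpin loop 3) and scores it with
its own implementation of the energy model, sharing no code with the DP
under test."""

from functools import lru_cache

PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MINLOOP = 3


def enumerate_structures(seq: str):
    n = len(seq)

    @lru_cache(maxsize=None)
    def go(i: int, j: int):
        if j - i < MINLOOP + 1:
            return (frozenset(),)
        out = list(go(i, j - 1))
        for k in range(i, j - MINLOOP):
            if (seq[k], seq[j]) in PAIRS:
                lefts = go(i, k - 1) if k > i else (frozenset(),)
                for left in lefts:
                    for inner in go(k + 1, j - 1):
                        out.append(left | inner | {(k, j)})
        return tuple(out)

    return go(0, n - 1) if n else (frozenset(),)


def _ptype(a: str, b: str) -> int:
    if {a, b} == {"G", "U"}:
        return 2
    if {a, b} == {"A", "U"}:
        return 1
    return 0


def score_structure(seq: str, pairs) -> int:
    """Deci-kcal energy of a nested structure: stacks -33/-21/-14 by pair
    class, unstacked pairs -10, hairpin loops +30, bulges +20."""
    pset = set(pairs)
    partner = {}
    for i, j in pset:
        partner[i] = j
        partner[j] = i
    e = 0
    for i, j in pset:
        if (i + 1, j - 1) in pset:
            t1, t2 = _ptype(seq[i], seq[j]), _ptype(seq[i + 1], seq[j - 1])
            e += -14 if 2 in (t1, t2) else (-21 if 1 in (t1, t2) else -33)
        else:
            e += -10
        branches = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not branches:
            e += 30
        elif len(branches) == 1:
            bk, bl = branches[0]
            if ((bk - i - 1) == 0) != ((j - bl - 1) == 0):
                e += 20
    return e


def brute_force_mfe(seq: str) -> int:
    """Exhaustive minimum energy in deci-kcal (0 for the open structure)."""
    best = 0
    for s in enumerate_structures(seq):
        best = min(best, score_structure(seq, s))
    return best
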