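"""RNA secondary-structure prediction for miRNA precursor candidates.

Implements a minimum-energy nested-structure dynamic program over a compact
nearest-neighbour-style energy model (see below), plus the derived per-sequence
statistics used to screen pre-miRNA hairpins: MFE (kcal/mol), AMFE (MFE per
100 nt) and MFEI (|AMFE| / GC%).

Energy model
------------
Scores are assigned to a nested set of base pairs (Watson-Crick plus G.U
wobble, minimum hairpin loop 3 nt):

* a pair stacked directly on an inner pair scores the stack energy of the two
  pairs: -3.3 kcal/mol if both are GC/CG, -2.1 if either is AU/UA,
  -1.4 if either is a G.U wobble;
* a pair with no directly adjacent inner pair scores -1.0;
* each hairpin loop costs +3.0 and each bulge (unpaired run on exactly one
  side between consecutive helices) +2.0; interior loops and multiloops carry
  no extra penalty;
* interior/bulge loops are bounded at 30 unpaired nt total (standard DP bound).

This is intentionally a small, exhaustively verifiable model: on short
sequences the DP optimum is checked against brute-force enumeration of every
nested structure.  It is not the Turner-2004 parameter set.

All energies are handled internally as integer tenths of kcal/mol so that
co-optimal structures tie exactly and tie-breaking (fewer pairs, then first
candidate in a fixed scan order) is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from ._seq import to_rna

# integer energies, tenths of kcal/mol
STACK_GC = -33
STACK_AU = -21
STACK_GU = -14
PAIR_UNSTACKED = -10
HAIRPIN_PENALTY = 30
BULGE_PENALTY = 20
MIN_HAIRPIN_LOOP = 3
MAX_INTERIOR_SPAN = 30  # max total unpaired nt in a bulge/interior loop
MIN_LEN = 20
MAX_LEN = 400

_INF = 10**8
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

# pair type: -1 not pairable, 0 GC/CG, 1 AU/UA, 2 GU/UG
_PTYPE = np.full((4, 4), -1, dtype=np.int8)
for _a, _b, _t in [("G", "C", 0), ("C", "G", 0), ("A", "U", 1), ("U", "A", 1),
                   ("G", "U", 2), ("U", "G", 2)]:
    _PTYPE[_CODE[_a], _CODE[_b]] = _t


@dataclass(frozen=True)
class HairpinFold:
    """A folded sequence with its optimal nested structure and hairpin statistics.

    ``pairs`` are 1-based (i, j) with i < j; ``mfe`` is kcal/mol (<= 0);
    ``amfe`` = mfe / length * 100; ``mfei`` = |amfe| / gc_pct (NaN when
    gc_pct is 0).
    """

    sequence: str
    pairs: tuple[tuple[int, int], ...]
    dot_bracket: str
    mfe: float
    amfe: float
    gc_pct: float
    mfei: float

    def partner_map(self) -> dict[int, int]:
        """0-based position -> 0-based partner for every paired base."""
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i - 1] = j - 1
            m[j - 1] = i - 1
        return m


def _stack_energy(t_outer: int, t_inner: int) -> int:
    if t_outer == 2 or t_inner == 2:
        return STACK_GU
    if t_outer == 1 or t_inner == 1:
        return STACK_AU
    return STACK_GC


@njit(cache=True)
def _fill(codes, ptype):  # pragma: no cover - exercised via fold_mfe
    n = codes.shape[0]
    Ve = np.full((n, n), _INF, dtype=np.int32)
    Vp = np.zeros((n, n), dtype=np.int32)
    Vcase = np.full((n, n), -1, dtype=np.int32)
    Vk = np.zeros((n, n), dtype=np.int32)
    Vl = np.zeros((n, n), dtype=np.int32)
    WMe = np.full((n, n), _INF, dtype=np.int32)
    WMp = np.zeros((n, n), dtype=np.int32)
    WMcase = np.full((n, n), -1, dtype=np.int32)
    WMk = np.zeros((n, n), dtype=np.int32)

    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # --- V: best structure with (i, j) paired ---
            tij = ptype[codes[i], codes[j]]
            if tij >= 0 and span >= MIN_HAIRPIN_LOOP + 1:
                be = PAIR_UNSTACKED + HAIRPIN_PENALTY
                bp = 1
                bc = 0
                bk = 0
                bl = 0
                # stack on (i+1, j-1)
                if span >= MIN_HAIRPIN_LOOP + 3:
                    tin = ptype[codes[i + 1], codes[j - 1]]
                    if tin >= 0 and Ve[i + 1, j - 1] < _INF:
                        if tij == 2 or tin == 2:
                            se = STACK_GU
                        elif tij == 1 or tin == 1:
                            se = STACK_AU
                        else:
                            se = STACK_GC
                        e = se + Ve[i + 1, j - 1]
                        p = 1 + Vp[i + 1, j - 1]
                        if e < be or (e == be and p < bp):
                            be, bp, bc, bk, bl = e, p, 1, i + 1, j - 1
                # single inner branch with a bulge or interior loop
                kmax = min(i + 1 + MAX_INTERIOR_SPAN, j - 1)
                for k in range(i + 1, kmax + 1):
                    g1 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - (MAX_INTERIOR_SPAN - g1))
                    for l in range(lmin, j):
                        if k == i + 1 and l == j - 1:
                            continue
                        if Ve[k, l] < _INF:
                            g2 = j - l - 1
                            pen = 0
                            if (g1 == 0) != (g2 == 0):
                                pen = BULGE_PENALTY
                            e = PAIR_UNSTACKED + pen + Ve[k, l]
                            p = 1 + Vp[k, l]
                            if e < be or (e == be and p < bp):
                                be, bp, bc, bk, bl = e, p, 2, k, l
                # multiloop: >= 2 branches inside
                for m in range(i + 2, j - 2):
                    if WMe[i + 1, m] < _INF and WMe[m + 1, j - 1] < _INF:
                        e = PAIR_UNSTACKED + WMe[i + 1, m] + WMe[m + 1, j - 1]
                        p = 1 + WMp[i + 1, m] + WMp[m + 1, j - 1]
                        if e < be or (e == be and p < bp):
                            be, bp, bc, bk, bl = e, p, 3, m, 0
                Ve[i, j] = be
                Vp[i, j] = bp
                Vcase[i, j] = bc
                Vk[i, j] = bk
                Vl[i, j] = bl
            # --- WM: >= 1 branch somewhere in [i, j] ---
            we = _INF
            wp = 0
            wc = -1
            wk = 0
            if j - 1 >= i and WMe[i, j - 1] < _INF:
                we, wp, wc = WMe[i, j - 1], WMp[i, j - 1], 0
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                if Ve[k, j] < _INF:
                    e = Ve[k, j]
                    p = Vp[k, j]
                    if e < we or (e == we and p < wp):
                        we, wp, wc, wk = e, p, 1, k
                    if k > i and WMe[i, k - 1] < _INF:
                        e2 = WMe[i, k - 1] + Ve[k, j]
                        p2 = WMp[i, k - 1] + Vp[k, j]
                        if e2 < we or (e2 == we and p2 < wp):
                            we, wp, wc, wk = e2, p2, 2, k
            if wc >= 0:
                WMe[i, j] = we
                WMp[i, j] = wp
                WMcase[i, j] = wc
                WMk[i, j] = wk
    return Ve, Vp, Vcase, Vk, Vl, WMe, WMp, WMcase, WMk


def _traceback(n, tables) -> tuple[int, list[tuple[int, int]]]:
    Ve, Vp, Vcase, Vk, Vl, WMe, WMp, WMcase, WMk = tables
    # exterior loop over prefixes, minimizing (energy, pairs)
    We = [0] * (n + 1)  # We[j+1] = best for prefix [0, j]
    Wp = [0] * (n + 1)
    Wch = [(-1, 0)] * (n + 1)  # (-1, _) = last base unpaired; (k, _) = pair (k, j)
    for j in range(n):
        be, bp, bch = We[j], Wp[j], (-1, 0)
        for k in range(0, j - MIN_HAIRPIN_LOOP):
            if Ve[k, j] < _INF:
                e = We[k] + int(Ve[k, j])
                p = Wp[k] + int(Vp[k, j])
                if e < be or (e == be and p < bp):
                    be, bp, bch = e, p, (k, j)
        We[j + 1], Wp[j + 1], Wch[j + 1] = be, bp, bch

    pairs: list[tuple[int, int]] = []

    def trace_v(i: int, j: int) -> None:
        pairs.append((i, j))
        c = Vcase[i, j]
        if c == 1 or c == 2:
            trace_v(int(Vk[i, j]), int(Vl[i, j]))
        elif c == 3:
            m = int(Vk[i, j])
            trace_wm(i + 1, m)
            trace_wm(m + 1, j - 1)

    def trace_wm(i: int, j: int) -> None:
        while True:
            c = WMcase[i, j]
            if c == 0:
                j -= 1
            elif c == 1:
                trace_v(int(WMk[i, j]), j)
                return
            else:
                k = int(WMk[i, j])
                trace_v(k, j)
                j = k - 1

    j = n
    while j > 0:
        k, jj = Wch[j]
        if k < 0:
            j -= 1
        else:
            trace_v(k, jj)
            j = k
    return We[n], sorted(pairs)


def fold_mfe(sequence: str) -> HairpinFold:
    """Fold ``sequence`` (RNA or DNA alphabet; T converted to U) and return the
    minimum-energy nested structure with hairpin statistics.

    Raises ``ValueError`` on invalid characters (positions listed) or lengths
    outside [20, 400].
    """
    rna = to_rna(sequence)
    if not (MIN_LEN <= len(rna) <= MAX_LEN):
        raise ValueError(f"sequence length {len(rna)} outside [{MIN_LEN}, {MAX_LEN}]")
    bad = [i + 1 for i, c in enumerate(rna) if c not in _CODE]
    if bad:
        raise ValueError(f"invalid characters at 1-based positions {bad}")
    codes = np.array([_CODE[c] for c in rna], dtype=np.int8)
    tables = _fill(codes, _PTYPE)
    e10, pairs0 = _traceback(len(rna), tables)
    e10 = min(e10, 0)
    if e10 == 0:
        pairs0 = []
    pairs1 = tuple((i + 1, j + 1) for i, j in pairs0)
    db = ["."] * len(rna)
    for i, j in pairs0:
        db[i] = "("
        db[j] = ")"
    mfe = e10 / 10.0
    amfe = mfe / len(rna) * 100.0
    gc = gc_content(rna)
    return HairpinFold(
        sequence=rna,
        pairs=pairs1,
        dot_bracket="".join(db),
        mfe=mfe,
        amfe=amfe,
        gc_pct=gc,
        mfei=mfei(mfe, len(rna), gc),
    )


def gc_content(sequence: str) -> float:
    """Percent G+C of a sequence (0..100)."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def mfei(mfe: float, length: int, gc_pct: float) -> float:
    """Minimal folding energy index |MFE / length * 100| / GC%.

    Reported as a positive magnitude; returns NaN when gc_pct is 0 (undefined).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if gc_pct == 0:
        return math.nan
    return abs(mfe / length * 100.0) / gc_pct


def structure_energy(sequence: str, pairs) -> float:
    """Energy (kcal/mol) of an explicit nested structure under the package's model.

    Used for consistency checks: the DP traceback's structure must score its
    reported MFE.  ``pairs`` are 1-based (i, j).
    """
    rna = to_rna(sequence)
    pset = {(i - 1, j - 1) for i, j in pairs}
    e = 0
    partner = {}
    for i, j in pset:
        if not (0 <= i < j < len(rna)):
            raise ValueError(f"pair ({i + 1}, {j + 1}) out of range")
        if j - i - 1 < MIN_HAIRPIN_LOOP:
            raise ValueError(f"pair ({i + 1}, {j + 1}) violates min hairpin loop")
        partner[i] = j
        partner[j] = i
    for i, j in pset:
        t = _PTYPE[_CODE[rna[i]], _CODE[rna[j]]]
        if t < 0:
            raise ValueError(f"non-canonical pair at ({i + 1}, {j + 1})")
        if (i + 1, j - 1) in pset:
            tin = _PTYPE[_CODE[rna[i + 1]], _CODE[rna[j - 1]]]
            e += _stack_energy(int(t), int(tin))
        else:
            e += PAIR_UNSTACKED
        # loop closed by (i, j): find directly-inner branches
        branches = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not branches:
            e += HAIRPIN_PENALTY
        elif len(branches) == 1:
            (k, l) = branches[0]
            g1, g2 = k - i - 1, j - l - 1
            if (g1 == 0) != (g2 == 0):
                e += BULGE_PENALTY
    return e / 10.0
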