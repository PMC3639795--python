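"""Independent brute-force oracles used by the property tests.

Each oracle re-derives an expected result from first principles with a
different algorithm than the implementation under test: the iORF oracle
walks backwards per amber codon instead of a forward sweep, the edit
oracle enumerates explicit edit scripts, the folding oracle enumerates
nested structures, and the component oracle is a plain union-find.
"""

from __future__ import annotations

import math

import numpy as np

STARTS = {"TTG", "CTG", "ATT", "ATC", "ATA", "ATG", "GTG"}
STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_iorfs(seq: str, min_downstream: int = 100) -> set[tuple[str, int, int, int]]:
    """All grammar-conforming iORFs as (strand, start, uag_pos, stop_end),
    strand-local coordinates.  For every in-frame TAG, scan forward for
    the terminal stop and backwards for the 5'-most valid start."""
    out = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            codons = [(p, s[p : p + 3]) for p in range(frame, n - 2, 3)]
            for ai, (ap, ac) in enumerate(codons):
                if ac != "TAG":
                    continue
                term = None
                for tp, tc in codons[ai + 1 :]:
                    if tc in STOPS:
                        term = tp
                        break
                if term is None or term - (ap + 3) < min_downstream:
                    continue
                best = None
                for sp, sc in reversed(codons[:ai]):
                    if sc in STOPS:
                        break
                    if sc in STARTS:
                        best = sp
                if best is not None:
                    out.add((strand, best, ap, term + 3))
    return out


def oracle_dist_m(s: str, t: str, m: int, max_cost: int = 10) -> float:
    """Minimal-cost edit script by exhaustive depth-first enumeration.

    States carry the currently open run type and its length mod m; a
    substitution/match or the end of the script requires the open run to
    have closed at a multiple of m.  Scripts costlier than ``max_cost``
    are not explored (returns inf if nothing cheaper exists).
    """
    best = [math.inf]

    def rec(i: int, j: int, run: str | None, phase: int, cost: float) -> None:
        if cost >= best[0] or cost > max_cost:
            return
        bound = abs((len(s) - i) - (len(t) - j))
        if cost + (bound > 0) > best[0]:
            return
        if i == len(s) and j == len(t):
            if phase == 0:
                best[0] = cost
            return
        if i < len(s) and j < len(t) and phase == 0:
            rec(i + 1, j + 1, None, 0, cost + (s[i] != t[j]))
        if j < len(t) and (phase == 0 or run == "I"):
            old = phase if run == "I" else 0
            rec(i, j + 1, "I", (old + 1) % m, cost + 1)
        if i < len(s) and (phase == 0 or run == "D"):
            old = phase if run == "D" else 0
            rec(i + 1, j, "D", (old + 1) % m, cost + 1)

    rec(0, 0, None, 0, 0.0)
    return best[0]


def oracle_basepair_probs(seq: str, pair_weight, min_hairpin: int = 3) -> np.ndarray:
    """Pairing probabilities by exhaustive enumeration of nested structures."""
    n = len(seq)

    def gen(lo: int, hi: int):
        if hi - lo <= 0:
            yield []
            return
        yield from gen(lo + 1, hi)
        for j in range(lo + min_hairpin + 1, hi):
            if pair_weight(seq[lo], seq[j]) > 0:
                for inner in gen(lo + 1, j):
                    for outer in gen(j + 1, hi):
                        yield [(lo, j)] + inner + outer

    Z = 0.0
    P = np.zeros((n, n))
    for pairs in gen(0, n):
        w = 1.0
        for i, j in pairs:
            w *= pair_weight(seq[i], seq[j])
        Z += w
        for i, j in pairs:
            P[i, j] += w
    return P / Z


def oracle_components(nodes, edges) -> set[frozenset]:
    """Connected components (size >= 2) via plain union-find."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict = {}
    for v in nodes:
        groups.setdefault(find(v), set()).add(v)
    return {frozenset(g) for g in groups.values() if len(g) > 1}
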