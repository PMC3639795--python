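"""Base-pairing probability matrices, structural alignment, and NJ trees.

Structural similarity of two PYLIS regions is measured without
committing to any single predicted structure: each sequence is folded
into its base-pairing probability matrix (equilibrium probability that
positions i and j pair, from the partition function over all nested
structures), and the two matrices are aligned with a Sankoff-style
simultaneous-folding dynamic program that rewards matched base pairs by
the geometric mean of their probabilities.

The built-in folding backend uses a deliberately simplified
thermodynamic model (per-pair energies, no stacking or loop entropies)
so that its probabilities can be verified exactly against exhaustive
structure enumeration; parity with full nearest-neighbour folders such
as RNAfold is not claimed, and any external tool emitting a dot-plot
probability matrix can be substituted through the ``backend`` hook.

Cluster-level structural similarity (``f_structure``) is the mean
pairwise alignment score; hierarchical grouping of PYLIS regions uses
neighbor joining on distances 1/score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numba import njit
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

# --- simplified thermodynamic model -----------------------------------------
#: Pairing energies in kcal/mol-like units; kT in the same units.
PAIR_ENERGY = {("G", "C"): -3.0, ("A", "T"): -2.0, ("G", "T"): -1.0}
KT = 0.6
MIN_HAIRPIN = 3  # unpaired positions enclosed by a pair, so j - i >= 4

# --- alignment defaults ------------------------------------------------------
P_MIN = 1e-4  # noise floor: pairs below this probability carry no signal
SIGMA_MATCH = 0.0  # bonus for aligning two unpaired positions
GAP = -0.1  # per gapped position
BAND_WIDTH = 30  # |i - k| band of the simultaneous alignment
MAX_PAIRS_PER_POS = 10  # sparsification: strongest pairs kept per position
DISTANCE_CAP = 1e6  # distance assigned when the alignment score is <= 0


def pair_weight(a: str, b: str) -> float:
    """Boltzmann weight of pairing bases a,b (0 if not complementary)."""
    e = PAIR_ENERGY.get((a, b)) or PAIR_ENERGY.get((b, a))
    return float(np.exp(-e / KT)) if e is not None else 0.0


@dataclass
class BasePairMatrix:
    """Upper-triangular matrix of pairing probabilities for one sequence."""

    seq: str
    P: np.ndarray

    def __post_init__(self) -> None:
        if self.P.shape != (len(self.seq), len(self.seq)):
            raise ValueError("probability matrix does not match sequence length")

    def __len__(self) -> int:
        return len(self.seq)


@njit(cache=True)
def _inside_outside(w: np.ndarray):  # pragma: no cover - exercised via wrapper
    n = w.shape[0]
    # Q[i][j]: partition function of the half-open region [i, j)
    Q = np.ones((n + 1, n + 1))
    for j in range(1, n + 1):
        for i in range(j - 1, -1, -1):
            val = Q[i][j - 1]
            for h in range(i, j - 4):
                if w[h][j - 1] > 0.0:
                    val += Q[i][h] * w[h][j - 1] * Q[h + 1][j - 1]
            Q[i][j] = val
    qtot = Q[0][n]
    # Qext[i][j]: weight of everything outside pair (i, j)
    P = np.zeros((n, n))
    Qext = np.zeros((n, n))
    for span in range(n - 1, 3, -1):
        for i in range(0, n - span):
            j = i + span
            if w[i][j] <= 0.0:
                continue
            acc = Q[0][i] * Q[j + 1][n]
            for p in range(0, i):
                for q in range(j + 1, n):
                    if w[p][q] > 0.0 and Qext[p][q] > 0.0:
                        acc += w[p][q] * Qext[p][q] * Q[p + 1][i] * Q[j + 1][q]
            Qext[i][j] = acc
            P[i][j] = w[i][j] * Q[i + 1][j] * acc / qtot
    return P


def basepair_probabilities(
    seq: str,
    backend: str | Callable[[str], np.ndarray] = "builtin",
) -> BasePairMatrix:
    """Equilibrium base-pairing probabilities of a sequence.

    The builtin backend evaluates the McCaskill inside/outside recursion
    over all nested structures under the simplified pair-energy model
    (min hairpin 3, no lone-pair prohibition).  A callable backend must
    map the sequence to an upper-triangular probability matrix.
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    dna = seq.upper().replace("U", "T")
    if callable(backend):
        return BasePairMatrix(dna, np.asarray(backend(dna), dtype=float))
    if backend != "builtin":
        raise ValueError(f"unknown folding backend {backend!r}")
    n = len(dna)
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + MIN_HAIRPIN + 1, n):
            w[i, j] = pair_weight(dna[i], dna[j])
    return BasePairMatrix(dna, _inside_outside(w))


def _sparse_pairs_by_right_end(P: np.ndarray, p_min: float, cap: int):
    """CSR-like lists of (left end, prob) for each right-end position."""
    n = P.shape[0]
    lefts: list[np.ndarray] = []
    probs: list[np.ndarray] = []
    for r in range(n):
        col = P[:, r]
        idx = np.nonzero(col >= p_min)[0]
        idx = idx[idx < r]  # pairs are upper-triangular: left end < right end
        if len(idx) > cap:
            idx = idx[np.argsort(col[idx])[::-1][:cap]]
            idx = np.sort(idx)
        lefts.append(idx.astype(np.int64))
        probs.append(col[idx].astype(np.float64))
    indptr = np.zeros(n + 1, dtype=np.int64)
    for r in range(n):
        indptr[r + 1] = indptr[r] + len(lefts[r])
    flat_left = np.concatenate(lefts) if n else np.zeros(0, dtype=np.int64)
    flat_prob = np.concatenate(probs) if n else np.zeros(0)
    return indptr, flat_left, flat_prob


@njit(cache=True)
def _pmcomp_dp(
    n, m, band, gap, sigma,
    a_ptr, a_left, a_prob,
    b_ptr, b_left, b_prob,
):  # pragma: no cover - exercised via wrapper
    NEG = -1.0e30
    width = 2 * band + 1
    # S[i, j, k-i+band, l-j+band] for spans [i,j) x [k,l)
    S = np.full((n + 1, n + 1, width, width), NEG, dtype=np.float64)
    for i in range(n + 1):
        for k in range(max(0, i - band), min(m, i + band) + 1):
            S[i, i, k - i + band, k - i + band] = 0.0
    for j in range(n + 1):
        for i in range(j, -1, -1):
            for k in range(max(0, i - band), min(m, i + band) + 1):
                dk = k - i + band
                for l in range(max(k, j - band), min(m, j + band) + 1):
                    dl = l - j + band
                    if j == i and l == k:
                        continue
                    best = NEG
                    # a[j-1] unaligned
                    if j > i and abs(l - (j - 1)) <= band:
                        v = S[i, j - 1, dk, l - (j - 1) + band]
                        if v > NEG and v + gap > best:
                            best = v + gap
                    # b[l-1] unaligned
                    if l > k:
                        v = S[i, j, dk, (l - 1) - j + band]
                        if v > NEG and v + gap > best:
                            best = v + gap
                    # a[j-1] ~ b[l-1] unpaired match
                    if j > i and l > k and abs((l - 1) - (j - 1)) <= band:
                        v = S[i, j - 1, dk, (l - 1) - (j - 1) + band]
                        if v > NEG and v + sigma > best:
                            best = v + sigma
                    # matched base pairs ending at a[j-1] and b[l-1]
                    if j > i and l > k:
                        for ai in range(a_ptr[j - 1], a_ptr[j]):
                            h = a_left[ai]
                            if h < i:
                                continue
                            pa = a_prob[ai]
                            for bi in range(b_ptr[l - 1], b_ptr[l]):
                                q = b_left[bi]
                                if q < k or abs(q - h) > band:
                                    continue
                                outer = S[i, h, dk, q - h + band]
                                if outer <= NEG:
                                    continue
                                inner = S[h + 1, j - 1, q + 1 - (h + 1) + band,
                                          (l - 1) - (j - 1) + band]
                                if inner <= NEG:
                                    continue
                                v = outer + inner + np.sqrt(pa * b_prob[bi])
                                if v > best:
                                    best = v
                    S[i, j, dk, dl] = best
    return S[0, n, band, m - n + band]


def pmcomp_score(
    pa: BasePairMatrix,
    pb: BasePairMatrix,
    p_min: float = P_MIN,
    sigma_match: float = SIGMA_MATCH,
    gap: float = GAP,
    band: int = BAND_WIDTH,
    max_pairs_per_pos: int = MAX_PAIRS_PER_POS,
) -> float:
    """Simultaneous-alignment score of two base-pair probability matrices.

    Maximizes the sum over matched pairs-of-pairs of sqrt(p_a * p_b)
    (pairs below ``p_min`` carry no signal), plus ``sigma_match`` per
    matched unpaired position, with a per-position gap cost.  The O(n^4)
    span dynamic program is banded: positions further than ``band``
    apart are never aligned.  Pass ``band >= max(len_a, len_b)`` for the
    exact, unbanded computation (intended for sequences <= 60 nt).
    """
    n, m = len(pa), len(pb)
    if pa.P.shape != (n, n) or pb.P.shape != (m, m):
        raise ValueError("matrix dimensions disagree with their sequence lengths")
    if abs(n - m) > band:
        raise ValueError(f"length difference {abs(n - m)} exceeds band width {band}")
    band = int(min(band, max(n, m)))
    a_ptr, a_left, a_prob = _sparse_pairs_by_right_end(pa.P, p_min, max_pairs_per_pos)
    b_ptr, b_left, b_prob = _sparse_pairs_by_right_end(pb.P, p_min, max_pairs_per_pos)
    return float(
        _pmcomp_dp(n, m, band, float(gap), float(sigma_match),
                   a_ptr, a_left, a_prob, b_ptr, b_left, b_prob)
    )


@dataclass(frozen=True)
class StructScore:
    a_id: str
    b_id: str
    score: float

    @property
    def distance(self) -> float:
        return struct_distance(self.score)


def struct_distance(score: float, cap: float = DISTANCE_CAP) -> float:
    """1/score, with non-positive scores mapped to a finite cap."""
    if score <= 0:
        return cap
    return min(1.0 / score, cap)


def f_structure(
    scores: Sequence[float],
) -> float:
    """Mean pairwise alignment score of the unordered member pairs.

    ``scores`` holds one alignment score per unordered pair; because the
    score is symmetric this equals the ordered-pair mean with the
    1/(n^2-n) normalizer.
    """
    if not scores:
        raise ValueError("f_structure needs at least one pair (cluster size >= 2)")
    return float(np.mean(scores))


@dataclass
class PhyloTree:
    """An unrooted NJ tree over PYLIS-region leaves."""

    newick: str
    labels: tuple[str, ...]


def neighbor_joining(distance_matrix: np.ndarray, labels: Sequence[str]) -> PhyloTree:
    """Canonical neighbor joining (Saitou-Nei) with non-negative branches.

    The input must be a symmetric, hollow, non-negative matrix; negative
    branch length estimates are clamped to zero.
    """
    d = np.asarray(distance_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(labels):
        raise ValueError("distance matrix must be square and match the label list")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    dm = DistanceMatrix(d, ids=list(labels))
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return PhyloTree(newick=str(tree).strip(), labels=tuple(labels))


__all__ = [
    "BAND_WIDTH",
    "BasePairMatrix",
    "DISTANCE_CAP",
    "GAP",
    "KT",
    "MIN_HAIRPIN",
    "P_MIN",
    "PAIR_ENERGY",
    "PhyloTree",
    "SIGMA_MATCH",
    "StructScore",
    "basepair_probabilities",
    "f_structure",
    "neighbor_joining",
    "pair_weight",
    "pmcomp_score",
    "struct_distance",
]
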