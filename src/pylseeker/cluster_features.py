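"""Per-cluster features, min-max normalization, and combined features.

Eight raw features describe each cluster of amber-interrupted ORFs:

==============  =============================================================
f_size          number of member iORFs
f_organisms     number of distinct genomes represented
f_diversity     mean pairwise DIST_3 between the 100-nt PYLIS regions
f_syn_codons    mean pairwise amino-acid similarity of the PYLIS peptides
f_upstream      mean nt distance from the start codon to the amber codon
f_downstream    mean nt distance from the amber codon to the terminal stop
f_structure     mean pairwise base-pair-matrix alignment score
f_coding        mean member coding potential (see coding_potential)
==============  =============================================================

DIST_m is an edit distance whose insertion and deletion runs must come
in multiples of m; DIST_3 therefore tolerates codon-sized indels while
charging frameshifting gaps heavily, and DIST_1 is plain Levenshtein.

All features are min-max normalized to [0,1] across clusters, and two
combined features are added: the geometric mean of normalized coding
and upstream, and the cube-root geometric mean of normalized structure,
diversity and synonymous-codon similarity.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .homology_clustering import Cluster
from .iorf_extraction import PylisRegion

logger = logging.getLogger(__name__)

RAW_FEATURES = (
    "f_size",
    "f_organisms",
    "f_diversity",
    "f_syn_codons",
    "f_upstream",
    "f_downstream",
    "f_structure",
    "f_coding",
)
COMBINED_FEATURES = ("c_coding_upstream", "c_structure_diversity_syn")
ALL_FEATURES = RAW_FEATURES + COMBINED_FEATURES


@njit(cache=True)
def _dist_m_dp(a: np.ndarray, b: np.ndarray, m: int) -> int:  # pragma: no cover
    """Edit distance with indel runs constrained to multiples of m.

    State: positions (i, j) consumed plus the phase of the currently
    open insertion/deletion run (a maximal run may only close, via a
    substitution/match or the end of the script, at phase 0).
    """
    n1, n2 = len(a), len(b)
    BIG = 1 << 30
    # layers: 0 = no open run (phase 0), 1..m-1 open ins run phase, ...
    # encode state phase: 0 closed; 1..m-1 ins phase; m..2m-2 del phase
    nstates = 2 * m - 1
    prev = np.full((n2 + 1, nstates), BIG, dtype=np.int64)
    cur = np.full((n2 + 1, nstates), BIG, dtype=np.int64)
    prev[0, 0] = 0
    # row i=0: only insertions of b
    for j in range(1, n2 + 1):
        for s in range(nstates):
            if prev[j - 1, s] >= BIG or (s >= m):  # can't be in a del run here
                continue
            ph = (s + 1) % m
            ns = 0 if ph == 0 else ph
            c = prev[j - 1, s] + 1
            if c < prev[j, ns]:
                prev[j, ns] = c
    for i in range(1, n1 + 1):
        for j in range(n2 + 1):
            for s in range(nstates):
                cur[j, s] = BIG
        for j in range(n2 + 1):
            # deletion of a[i-1]: allowed from closed or open-del states
            for s in range(nstates):
                v = prev[j, s]
                if v >= BIG:
                    continue
                if s == 0 or s >= m:
                    ph = ((0 if s == 0 else s - m + 1) + 1) % m
                    ns = 0 if ph == 0 else m + ph - 1
                    if v + 1 < cur[j, ns]:
                        cur[j, ns] = v + 1
            if j > 0:
                # insertion of b[j-1]: from closed or open-ins states
                for s in range(m):
                    v = cur[j - 1, s]
                    if v >= BIG:
                        continue
                    ph = (s + 1) % m
                    ns = 0 if ph == 0 else ph
                    if v + 1 < cur[j, ns]:
                        cur[j, ns] = v + 1
                # substitution/match: only from closed state
                v = prev[j - 1, 0]
                if v < BIG:
                    cost = 0 if a[i - 1] == b[j - 1] else 1
                    if v + cost < cur[j, 0]:
                        cur[j, 0] = v + cost
        tmp = prev
        prev = cur
        cur = tmp
    return prev[n2, 0]


def dist_m(s: str, t: str, m: int) -> float:
    """Minimal edit cost transforming s into t with unit costs, where
    every maximal run of insertions (and of deletions) must have length
    divisible by m.  dist_m(s, t, 1) is the classical Levenshtein
    distance.

    Because substitutions preserve length and constrained runs change it
    by multiples of m, no valid script exists when len(s) - len(t) is
    not a multiple of m; the minimum over the empty script set is
    returned as ``inf``.  (Equal-length inputs, such as two 100-nt PYLIS
    regions, always have finite distance.)
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    a = np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int64)
    b = np.frombuffer(t.encode("ascii"), dtype=np.uint8).astype(np.int64)
    res = int(_dist_m_dp(a, b, m))
    if res >= (1 << 30):
        return float("inf")
    return res


def f_diversity(regions: list[PylisRegion]) -> float:
    """Mean pairwise DIST_3 between the nucleotide PYLIS regions."""
    if len(regions) < 2:
        raise ValueError("f_diversity needs a cluster of size >= 2")
    vals = [
        dist_m(a.nt, b.nt, 3) for a, b in itertools.combinations(regions, 2)
    ]
    return float(np.mean(vals))


def f_syn_codons(regions: list[PylisRegion], variant: str = "percent_identity") -> float:
    """Amino-acid-level similarity of the PYLIS peptides.

    ``percent_identity`` (default): mean over pairs of
    100 * (1 - DIST_1(s', t') / 33), clamped to [0, 100] -- a percent
    scale on which identical peptides score 100.  ``reciprocal``: mean
    of 1 / max(DIST_1, 1), the literal reciprocal-distance form.
    """
    if len(regions) < 2:
        raise ValueError("f_syn_codons needs a cluster of size >= 2")
    vals = []
    for a, b in itertools.combinations(regions, 2):
        d = dist_m(a.aa, b.aa, 1)
        if variant == "percent_identity":
            vals.append(min(max(100.0 * (1.0 - d / len(a.aa)), 0.0), 100.0))
        elif variant == "reciprocal":
            vals.append(1.0 / max(d, 1))
        else:
            raise ValueError(f"unknown f_syn_codons variant {variant!r}")
    return float(np.mean(vals))


def simple_features(cluster: Cluster) -> tuple[float, float, float, float]:
    """(f_size, f_organisms, f_upstream, f_downstream) of a cluster.

    Upstream spans start codon to amber (the start codon's 3 nt count);
    downstream spans amber to terminal stop, excluding both codons.
    """
    ups = [m.orf.upstream_nt for m in cluster.members]
    downs = [m.orf.downstream_nt for m in cluster.members]
    return (
        float(cluster.n),
        float(len(cluster.genome_ids)),
        float(np.mean(ups)),
        float(np.mean(downs)),
    )


@dataclass
class FeatureVector:
    cluster_id: str
    raw: dict[str, float]
    normalized: dict[str, float] = field(default_factory=dict)


def normalize_features(vectors: list[FeatureVector]) -> list[FeatureVector]:
    """Min-max normalize each feature to [0,1] across clusters, in place.

    A constant feature (max == min) normalizes to all zeros with a
    warning.  Combined features are then attached to the normalized
    values.
    """
    if len(vectors) < 2:
        raise ValueError("normalization needs at least 2 clusters")
    for feat in RAW_FEATURES:
        vals = np.array([v.raw[feat] for v in vectors], dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            logger.warning("feature %s is constant across clusters; normalized to 0", feat)
            normed = np.zeros_like(vals)
        else:
            normed = (vals - lo) / (hi - lo)
        for v, x in zip(vectors, normed):
            v.normalized[feat] = float(x)
    for v in vectors:
        c1, c2 = combined_features(v.normalized)
        v.normalized["c_coding_upstream"] = c1
        v.normalized["c_structure_diversity_syn"] = c2
    return vectors


def combined_features(normalized: dict[str, float]) -> tuple[float, float]:
    """Geometric-mean combinations of normalized features.

    c1 = sqrt(f_coding * f_upstream);
    c2 = (f_structure * f_diversity * f_syn_codons)^(1/3).
    """
    c1 = float(np.sqrt(normalized["f_coding"] * normalized["f_upstream"]))
    c2 = float(
        (normalized["f_structure"] * normalized["f_diversity"] * normalized["f_syn_codons"])
        ** (1.0 / 3.0)
    )
    return c1, c2


__all__ = [
    "ALL_FEATURES",
    "COMBINED_FEATURES",
    "FeatureVector",
    "RAW_FEATURES",
    "combined_features",
    "dist_m",
    "f_diversity",
    "f_syn_codons",
    "normalize_features",
    "simple_features",
]
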