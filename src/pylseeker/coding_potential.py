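"""Codon-HMM coding potential of iORFs.

The model is a first-order HMM whose hidden states are amino acids; each
state emits only the synonymous codons of its amino acid (translation
table 11), so a codon sequence determines its state path uniquely and
the likelihood is a single product of initial, transition, emission and
gene-length terms:

    P(codons | model) = length(L) * init(a1) * prod emis(c_t|a_t) * prod trans(a_t|a_{t-1})

Trained per genome on its annotated protein-coding genes (maximum
likelihood with Laplace smoothing), the model assigns every iORF a
log-odds coding potential against a uniform-nucleotide null:

    HMM_g(i) = log2 P(codons of i, amber removed | model_g) - log2 P(i | null)

The amber codon is removed before decoding (it can be emitted by any
state with no effect on probability), while the null term covers the
full nucleotide length of the iORF.  Logs are base 2; the choice of
base only rescales the feature, which is min-max normalized downstream.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome_io import GenomeRecord, START_CODONS, STOP_CODONS, reverse_complement, translate
from .homology_clustering import Cluster
from .iorf_extraction import LocatedIORF

logger = logging.getLogger(__name__)

LOG2_QUARTER = math.log2(0.25)

#: Synonymous codons per amino acid under translation table 11.
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {}
for _c in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
    if _c not in STOP_CODONS:
        _aa = translate(_c)
        SYNONYMOUS_CODONS.setdefault(_aa, ())
        SYNONYMOUS_CODONS[_aa] += (_c,)

AMINO_ACIDS = tuple(sorted(SYNONYMOUS_CODONS))
N_SENSE_CODONS = 61

LENGTH_MIN, LENGTH_MAX = 10, 3000
LENGTH_BANDWIDTH = 10.0
LENGTH_FLOOR_MIX = 1e-3


def _smooth_length_distribution(lengths: list[int]) -> np.ndarray:
    """Gaussian-kernel-smoothed empirical distribution of gene lengths
    (in codons), truncated to [LENGTH_MIN, LENGTH_MAX] and floored by a
    small uniform mixture so every supported length has positive mass."""
    grid = np.arange(LENGTH_MIN, LENGTH_MAX + 1)
    dens = np.zeros_like(grid, dtype=float)
    for L in lengths:
        dens += np.exp(-0.5 * ((grid - L) / LENGTH_BANDWIDTH) ** 2)
    total = dens.sum()
    if total > 0:
        dens /= total
    else:
        dens[:] = 1.0 / len(grid)
    dens = (1.0 - LENGTH_FLOOR_MIX) * dens + LENGTH_FLOOR_MIX / len(grid)
    return dens / dens.sum()


@dataclass
class CodingModel:
    """Trained amino-acid-state codon HMM with gene-length model."""

    genome_id: str
    emission: dict[str, dict[str, float]]
    transition: dict[str, dict[str, float]]
    initial: dict[str, float]
    length_model: np.ndarray  # P(L codons) for L in [length_min, length_min + size)
    pseudocount: float = 1.0
    length_min: int = LENGTH_MIN

    def length_log2(self, n_codons: int) -> float:
        lo, hi = self.length_min, self.length_min + len(self.length_model) - 1
        idx = int(np.clip(n_codons, lo, hi)) - lo
        return math.log2(self.length_model[idx])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genome_id": self.genome_id,
            "emission": self.emission,
            "transition": self.transition,
            "initial": self.initial,
            "length_model": self.length_model.tolist(),
            "pseudocount": self.pseudocount,
            "length_min": self.length_min,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CodingModel":
        payload = json.loads(Path(path).read_text())
        payload["length_model"] = np.asarray(payload["length_model"])
        return cls(**payload)


@dataclass(frozen=True)
class CodingScore:
    iorf_id: str
    log_odds: float


def extract_training_cds(genome: GenomeRecord) -> list[str]:
    """Pull annotated protein-coding sequences suitable for training.

    Features whose sequence is not a clean gene (length not a codon
    multiple, missing start, internal stops) are skipped with a warning;
    unreliably annotated ("hypothetical" etc.) features still train the
    model, mirroring training on the full annotation set.
    """
    out = []
    for ft in genome.features:
        if ft.kind != "protein_coding":
            continue
        seq = genome.sequence[ft.start : ft.end]
        if ft.strand == "-":
            seq = reverse_complement(seq)
        if len(seq) % 3 or len(seq) < 6:
            logger.warning("%s: CDS at %d-%d not codon-aligned, skipped",
                           genome.genome_id, ft.start, ft.end)
            continue
        body = seq[:-3] if seq[-3:] in STOP_CODONS else seq
        if body[:3] not in START_CODONS:
            logger.warning("%s: CDS at %d-%d lacks a start codon, skipped",
                           genome.genome_id, ft.start, ft.end)
            continue
        aa = translate(body)
        if "*" in aa or "X" in aa:
            logger.warning("%s: CDS at %d-%d has internal stop or N, skipped",
                           genome.genome_id, ft.start, ft.end)
            continue
        out.append(seq)
    return out


def train_coding_model(
    cds_sequences: list[str],
    genome_id: str = "",
    pseudocount: float = 1.0,
) -> CodingModel:
    """Maximum-likelihood HMM parameters with Laplace smoothing.

    Terminal stop codons are stripped (the model has no stop state);
    non-ATG start codons are emitted by the state of the amino acid they
    literally encode.
    """
    if not cds_sequences:
        raise ValueError("cannot train a coding model on an empty CDS set")
    emis_counts = {aa: {c: 0.0 for c in codons} for aa, codons in SYNONYMOUS_CODONS.items()}
    trans_counts = {a: {b: 0.0 for b in AMINO_ACIDS} for a in AMINO_ACIDS}
    init_counts = {a: 0.0 for a in AMINO_ACIDS}
    lengths = []
    for seq in cds_sequences:
        if len(seq) % 3:
            raise ValueError("training CDS length must be a multiple of 3")
        if seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        aas = [translate(c) for c in codons]
        if any(a in "*X" for a in aas):
            raise ValueError("training CDS contains internal stop or ambiguous codon")
        lengths.append(len(codons))
        init_counts[aas[0]] += 1
        for codon, aa in zip(codons, aas):
            emis_counts[aa][codon] += 1
        for a, b in zip(aas, aas[1:]):
            trans_counts[a][b] += 1
    emission = {
        aa: {
            c: (cnt + pseudocount) / (sum(row.values()) + pseudocount * len(row))
            for c, cnt in row.items()
        }
        for aa, row in emis_counts.items()
    }
    transition = {
        a: {
            b: (cnt + pseudocount) / (sum(row.values()) + pseudocount * len(row))
            for b, cnt in row.items()
        }
        for a, row in trans_counts.items()
    }
    tot_init = sum(init_counts.values())
    initial = {
        a: (cnt + pseudocount) / (tot_init + pseudocount * len(init_counts))
        for a, cnt in init_counts.items()
    }
    return CodingModel(
        genome_id=genome_id,
        emission=emission,
        transition=transition,
        initial=initial,
        length_model=_smooth_length_distribution(lengths),
        pseudocount=pseudocount,
    )


def sequence_log2_prob(model: CodingModel, codons: list[str]) -> float:
    """log2 P(codon string | model), along the unique decoding path.

    Codons containing N contribute a maximum-entropy emission (1/61)
    and uniform transitions into and out of their unknowable state.
    """
    if not codons:
        raise ValueError("empty codon sequence")
    logp = model.length_log2(len(codons))
    prev: str | None = None
    first = True
    for codon in codons:
        if "N" in codon:
            aa = None
            logp += math.log2(1.0 / N_SENSE_CODONS)
            logger.debug("N-containing codon scored at maximum entropy")
        else:
            aa = translate(codon)
            if aa == "*":
                raise ValueError(f"stop codon {codon} inside the scored region")
            logp += math.log2(model.emission[aa][codon])
        if first:
            logp += math.log2(model.initial[aa]) if aa else math.log2(1.0 / len(AMINO_ACIDS))
            first = False
        else:
            if prev is None or aa is None:
                logp += math.log2(1.0 / len(AMINO_ACIDS))
            else:
                logp += math.log2(model.transition[prev][aa])
        prev = aa
    return logp


def score_codons(model: CodingModel, codons: list[str], null_nt_len: int) -> float:
    """Log-odds of a codon string against the uniform nucleotide null.

    ``null_nt_len`` is the nucleotide length charged to the null model
    (for an iORF: its full length, amber and stop codons included).
    """
    return sequence_log2_prob(model, codons) - null_nt_len * LOG2_QUARTER


def score_iorf(model: CodingModel, located: LocatedIORF) -> CodingScore:
    """Coding potential of one iORF under its genome's model.

    The amber codon is deleted before decoding and the terminal stop is
    stripped (the model has no stop state); the null term covers the
    full iORF including both.
    """
    orf = located.orf
    seq = orf.nt_seq
    rel_uag = orf.uag_pos - orf.start
    codons = [seq[i : i + 3] for i in range(0, len(seq) - 3, 3) if i != rel_uag]
    log_odds = score_codons(model, codons, null_nt_len=len(seq))
    return CodingScore(iorf_id=located.iorf_id, log_odds=log_odds)


def f_coding(cluster: Cluster, scores: dict[str, float]) -> float:
    """Mean member coding potential; ``scores`` maps iORF id to log-odds
    computed with the member's own genome model."""
    return float(np.mean([scores[m] for m in cluster.member_ids]))


def filter_clusters_by_coding(
    clusters: list[Cluster],
    f_values: dict[str, float],
    rule: str = "negative",
) -> list[Cluster]:
    """Retain clusters by the coding-potential predicate.

    ``rule='negative'`` keeps clusters with f_coding < 0 (the literal
    published retention rule); ``rule='positive'`` keeps f_coding > 0,
    the sign under which gene-like clusters survive.  See the methods
    note for why both ship.
    """
    if rule == "negative":
        return [c for c in clusters if f_values[c.cluster_id] < 0]
    if rule == "positive":
        return [c for c in clusters if f_values[c.cluster_id] > 0]
    if rule == "none":
        return list(clusters)
    raise ValueError(f"unknown coding filter rule {rule!r}")


__all__ = [
    "AMINO_ACIDS",
    "CodingModel",
    "CodingScore",
    "SYNONYMOUS_CODONS",
    "extract_training_cds",
    "f_coding",
    "filter_clusters_by_coding",
    "score_codons",
    "score_iorf",
    "sequence_log2_prob",
    "train_coding_model",
]
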