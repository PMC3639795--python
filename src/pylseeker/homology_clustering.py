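"""Translated homology search between PYLIS regions and cluster building.

Every iORF's 33-residue PYLIS peptide is searched against the iORF
regions of all candidate genomes.  Matches passing the e-value threshold
become edges of an undirected graph over iORFs; clusters are the
connected components with more than one node.  Two pruning rules then
remove clusters that are likely artefacts of overlapping known genes:

  (a) a member's 100-bp downstream region lies completely inside a
      reliably annotated protein-coding gene in a different reading
      frame (shadow ORFs);
  (b) a member's downstream region overlaps a reliably annotated
      functional RNA gene.

Same-frame overlaps never trigger removal: genuine pyrrolysine genes are
annotated in the same frame as their iORF (often truncated at the UAG).

The built-in search backend is a local Smith-Waterman over the PYLIS
peptides (BLOSUM62, gap open 11 / extend 1) with Karlin-Altschul
e-values, prefiltered by shared amino-acid words in the spirit of
BLAST's seed-and-extend.  Precomputed hits from an external six-frame
search tool can be supplied instead in standard 12-column tabular form.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from Bio.Align import PairwiseAligner, substitution_matrices

from .iorf_extraction import LocatedIORF, PylisRegion

DEFAULT_E_THRESHOLD = 1e-6
#: Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041
#: Exact-match word length for the seed prefilter of the built-in backend.
WORD_SIZE = 4


@dataclass(frozen=True)
class HomologyMatch:
    """A directional translated-homology hit between two iORFs."""

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    aligned_span: tuple[int, int] = (0, 0)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # first gap position costs 11+1, each further position 1 (BLAST convention)
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def evalue_from_score(score: float, query_len: int, db_len: int) -> float:
    """Karlin-Altschul expectation for a raw Smith-Waterman score."""
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def bitscore_from_score(score: float) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)


def search_backend(
    pylis: list[PylisRegion],
    total_target_nt: int,
    e_threshold: float = DEFAULT_E_THRESHOLD,
    word_size: int = WORD_SIZE,
) -> list[HomologyMatch]:
    """All-against-all translated search over the PYLIS peptides.

    ``total_target_nt`` is the summed nucleotide length of the searched
    genomes; the Karlin-Altschul search space is query length x the
    six-frame translated database size (2 x total nt).  Hits of a query
    to its own iORF are discarded; restricting subjects to PYLIS regions
    implements the discard of hits to non-iORF regions.
    """
    aligner = _make_aligner()
    db_len = 2 * total_target_nt
    # invert the e-value once into a raw-score cutoff: E <= t  <=>  S >= s_min
    items = [(p.parent.iorf_id, p.aa.replace("*", "X")) for p in pylis]
    # seed index: word -> indices of peptides containing it
    index: dict[str, list[int]] = {}
    for idx, (_id, aa) in enumerate(items):
        for w in {aa[i : i + word_size] for i in range(len(aa) - word_size + 1)}:
            index.setdefault(w, []).append(idx)
    candidate_pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) > 1:
            candidate_pairs.update(itertools.combinations(hits, 2))
    matches: list[HomologyMatch] = []
    for a, b in sorted(candidate_pairs):
        qid, qaa = items[a]
        sid, saa = items[b]
        if qid == sid:
            continue
        score = aligner.score(qaa, saa)
        ev = evalue_from_score(score, len(qaa), db_len)
        if ev <= e_threshold:
            bits = bitscore_from_score(score)
            matches.append(HomologyMatch(qid, sid, ev, bits))
            matches.append(HomologyMatch(sid, qid, ev, bits))
    return matches


def read_blast_hits(
    path: str | Path,
    iorfs: list[LocatedIORF],
    e_threshold: float = DEFAULT_E_THRESHOLD,
) -> list[HomologyMatch]:
    """Load hits in blast outfmt-6 and map them onto extracted iORFs.

    Expected columns: qseqid (an iORF id), sseqid (a genome id), pident,
    length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore, with subject coordinates 1-based on the forward strand.
    Hits that do not overlap any extracted iORF of the subject genome
    are discarded, as are hits back to the query's own iORF.
    """
    by_genome: dict[str, list[LocatedIORF]] = {}
    for li in iorfs:
        by_genome.setdefault(li.orf.genome_id, []).append(li)
    matches: list[HomologyMatch] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 tab-separated columns")
            qid, sgenome = cols[0], cols[1]
            sstart, send = int(cols[8]), int(cols[9])
            evalue, bits = float(cols[10]), float(cols[11])
            if evalue > e_threshold:
                continue
            lo, hi = min(sstart, send) - 1, max(sstart, send)
            for li in by_genome.get(sgenome, ()):
                if li.iorf_id != qid and li.fwd_start < hi and lo < li.fwd_end:
                    matches.append(HomologyMatch(qid, li.iorf_id, evalue, bits, (lo, hi)))
    return matches


@dataclass
class Cluster:
    """A connected component of reciprocally matched iORFs (size >= 2)."""

    cluster_id: str
    members: list[LocatedIORF] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def member_ids(self) -> list[str]:
        return [m.iorf_id for m in self.members]

    @property
    def genome_ids(self) -> set[str]:
        return {m.orf.genome_id for m in self.members}


def build_clusters(
    matches: list[HomologyMatch],
    all_iorfs: list[LocatedIORF],
    strict_reciprocal: bool = False,
) -> list[Cluster]:
    """Connected components of the iORF match graph, singletons dropped.

    With ``strict_reciprocal`` an edge requires hits in both directions;
    by default any single directional hit connects two iORFs (querying
    every iORF makes symmetric hits co-occur in practice).
    """
    by_id = {li.iorf_id: li for li in all_iorfs}
    directed: set[tuple[str, str]] = set()
    for m in matches:
        if m.query_id == m.subject_id:
            continue
        if m.query_id not in by_id or m.subject_id not in by_id:
            raise KeyError(f"match references unknown iORF {m.query_id}/{m.subject_id}")
        directed.add((m.query_id, m.subject_id))
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for a, b in directed:
        if not strict_reciprocal or (b, a) in directed:
            graph.add_edge(a, b)
    clusters = []
    for comp in nx.connected_components(graph):
        if len(comp) < 2:
            continue
        ids = sorted(comp)
        clusters.append(Cluster(cluster_id=ids[0], members=[by_id[i] for i in ids]))
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def _member_is_shadowed(member: LocatedIORF, features) -> bool:
    lo, hi = member.pylis_fwd_start, member.pylis_fwd_end
    for ft in features:
        if ft.kind == "protein_coding" and ft.is_confident:
            if ft.start <= lo and hi <= ft.end and ft.frame_class != member.frame_class:
                return True
    return False


def _member_hits_rna(member: LocatedIORF, features) -> bool:
    lo, hi = member.pylis_fwd_start, member.pylis_fwd_end
    for ft in features:
        if ft.kind == "rna_gene" and ft.is_confident and ft.start < hi and lo < ft.end:
            return True
    return False


def prune_clusters(
    clusters: list[Cluster],
    annotations_by_genome: dict[str, list],
) -> list[Cluster]:
    """Drop clusters containing shadow-ORF or RNA-gene-overlapping members.

    A cluster is removed if any member's 100-bp downstream region is (a)
    fully inside a confident protein-coding feature in a different
    reading frame (opposite strand counts as different), or (b) overlaps
    a confident RNA gene by at least one nucleotide.
    """
    kept = []
    for cl in clusters:
        bad = False
        for member in cl.members:
            feats = annotations_by_genome.get(member.orf.genome_id, ())
            if _member_is_shadowed(member, feats) or _member_hits_rna(member, feats):
                bad = True
                break
        if not bad:
            kept.append(cl)
    return kept


__all__ = [
    "Cluster",
    "DEFAULT_E_THRESHOLD",
    "HomologyMatch",
    "KA_K",
    "KA_LAMBDA",
    "bitscore_from_score",
    "build_clusters",
    "evalue_from_score",
    "prune_clusters",
    "read_blast_hits",
    "search_backend",
]
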