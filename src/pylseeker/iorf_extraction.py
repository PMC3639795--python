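"""Scanning genomes for amber-interrupted ORFs (iORFs).

An iORF is a maximal open reading frame whose first in-frame stop-like
codon is the amber codon TAG and which then runs on to a genuine
terminal stop:

    iORF  ::=  start  not-stop*  TAG  not-stop*  stop

with start in {TTG, CTG, ATT, ATC, ATA, ATG, GTG} (translation table 11)
and stop in {TAA, TAG, TGA}.  Only iORFs with at least ``min_downstream``
nucleotides strictly between the amber codon and the terminal stop are
kept, so a putative PYLIS structure fits inside the coding region.  The
100-nt stretch immediately 3' of the amber codon is the PYLIS region.

Genomes are treated as linear; origin-spanning iORFs on circular
chromosomes are not detected.  Codons containing N never act as start,
amber or stop, but are tolerated inside the not-stop stretches.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import (
    AMBER,
    GenomeRecord,
    START_CODONS,
    STOP_CODONS,
    reverse_complement,
    translate,
)

PYLIS_LENGTH = 100
DEFAULT_MIN_DOWNSTREAM = 100


@dataclass(frozen=True)
class InterruptedORF:
    """One amber-interrupted ORF in strand-local coordinates.

    ``start``, ``uag_pos`` and ``stop_end`` are 0-based positions on the
    strand the iORF is read from (for '-' iORFs: on the reverse
    complement of the genome).  ``fwd_start``/``fwd_end`` map the iORF
    back onto the forward strand of the genome.
    """

    genome_id: str
    strand: str
    start: int
    uag_pos: int
    stop_end: int
    nt_seq: str

    def __post_init__(self) -> None:
        if (self.uag_pos - self.start) % 3 or (self.stop_end - 3 - self.uag_pos) % 3:
            raise ValueError("iORF coordinates are not codon-aligned")

    @property
    def iorf_id(self) -> str:
        return f"{self.genome_id}:{self.strand}:{self.start}-{self.stop_end}"

    @property
    def upstream_nt(self) -> int:
        """Distance in nt from the start codon to the amber codon."""
        return self.uag_pos - self.start

    @property
    def downstream_nt(self) -> int:
        """Distance in nt from the amber codon to the terminal stop,
        excluding both."""
        return self.stop_end - 3 - (self.uag_pos + 3)


@dataclass(frozen=True)
class LocatedIORF:
    """An iORF plus its projection onto the forward strand."""

    orf: InterruptedORF
    fwd_start: int  # 0-based, inclusive, forward strand
    fwd_end: int  # exclusive
    pylis_fwd_start: int  # forward-strand interval of the 100-nt PYLIS region
    pylis_fwd_end: int

    @property
    def iorf_id(self) -> str:
        return self.orf.iorf_id

    @property
    def frame_class(self) -> tuple[str, int]:
        """Reading-frame identity comparable with AnnotatedFeature.frame_class."""
        if self.orf.strand == "+":
            return ("+", self.fwd_start % 3)
        return ("-", self.fwd_end % 3)


@dataclass(frozen=True)
class PylisRegion:
    """The 100-nt region 3' of the amber codon and its 33-aa translation."""

    nt: str
    aa: str
    parent: LocatedIORF

    def __post_init__(self) -> None:
        if len(self.nt) != PYLIS_LENGTH:
            raise ValueError(f"PYLIS region must be {PYLIS_LENGTH} nt, got {len(self.nt)}")


def _scan_strand(seq: str, genome_id: str, strand: str, min_downstream: int):
    """Yield (start, uag_pos, stop_end) triples for one strand-local sequence.

    Because the grammar forbids stop codons between start and amber, the
    amber is the first in-frame stop-like codon after the start, and the
    terminal stop is the next in-frame stop after the amber; a single
    left-to-right pass per frame with a running "first start since the
    last stop" suffices.
    """
    n = len(seq)
    for frame in range(3):
        # Positions of stop-like codons in this frame, for downstream lookup.
        stop_positions = [
            p for p in range(frame, n - 2, 3) if seq[p : p + 3] in STOP_CODONS
        ]
        stop_idx = 0
        current_start = None
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if codon in STOP_CODONS:
                if codon == AMBER and current_start is not None:
                    # find next stop strictly after the amber
                    while stop_idx < len(stop_positions) and stop_positions[stop_idx] <= p:
                        stop_idx += 1
                    if stop_idx < len(stop_positions):
                        term = stop_positions[stop_idx]
                        if term - (p + 3) >= min_downstream:
                            yield current_start, p, term + 3
                else:
                    while stop_idx < len(stop_positions) and stop_positions[stop_idx] <= p:
                        stop_idx += 1
                current_start = None
            elif current_start is None and codon in START_CODONS:
                current_start = p


def find_iorfs(
    genome: GenomeRecord, min_downstream: int = DEFAULT_MIN_DOWNSTREAM
) -> list[LocatedIORF]:
    """Scan both strands of a genome for interrupted ORFs.

    For every in-frame TAG with a valid upstream start (no intervening
    in-frame stop) and at least ``min_downstream`` nt to the next
    in-frame stop, exactly one iORF is emitted, anchored at the 5'-most
    valid start codon.
    """
    seq = genome.sequence
    n = len(seq)
    out: list[LocatedIORF] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for start, uag, stop_end in _scan_strand(s, genome.genome_id, strand, min_downstream):
            orf = InterruptedORF(
                genome_id=genome.genome_id,
                strand=strand,
                start=start,
                uag_pos=uag,
                stop_end=stop_end,
                nt_seq=s[start:stop_end],
            )
            if strand == "+":
                fwd_start, fwd_end = start, stop_end
                py_s, py_e = uag + 3, uag + 3 + PYLIS_LENGTH
            else:
                fwd_start, fwd_end = n - stop_end, n - start
                py_s, py_e = n - (uag + 3 + PYLIS_LENGTH), n - (uag + 3)
            out.append(LocatedIORF(orf, fwd_start, fwd_end, py_s, py_e))
    out.sort(key=lambda li: (li.orf.strand, li.orf.start))
    return out


def extract_pylis(located: LocatedIORF) -> PylisRegion:
    """Cut out the 100-nt region immediately 3' of the amber codon.

    The first 33 complete codons (nt 1-99) are translated; the 100th nt
    is retained at nucleotide level only.
    """
    orf = located.orf
    if orf.downstream_nt < PYLIS_LENGTH:
        raise ValueError(
            f"iORF {orf.iorf_id} has only {orf.downstream_nt} nt downstream of the amber"
        )
    rel = orf.uag_pos + 3 - orf.start
    nt = orf.nt_seq[rel : rel + PYLIS_LENGTH]
    return PylisRegion(nt=nt, aa=translate(nt), parent=located)


__all__ = [
    "DEFAULT_MIN_DOWNSTREAM",
    "InterruptedORF",
    "LocatedIORF",
    "PYLIS_LENGTH",
    "PylisRegion",
    "extract_pylis",
    "find_iorfs",
]
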