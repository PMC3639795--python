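"""Reading/writing genomes and annotations, plus elementary sequence ops.

Coordinates are 0-based half-open everywhere inside the package; the
1-based inclusive convention of GFF3 is converted at the file boundary
and nowhere else.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

#: Nucleotide alphabet accepted throughout the pipeline.  Other IUPAC
#: ambiguity codes are rejected at load time because the iORF grammar is
#: defined on unambiguous codons (N is tolerated as "assembly gap").
VALID_NT = frozenset("ACGTN")

#: Words in a product description that mark an annotation as unreliable.
#: Features whose product contains any of these (case-insensitively) are
#: not treated as known genes by the cluster pruning rules.
UNRELIABLE_PRODUCT_WORDS = (
    "pseudo",
    "predicted",
    "putative",
    "unknown",
    "possible",
    "hypothetical",
    "probable",
)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
#: Start codons of translation table 11 (bacterial/archaeal).
START_CODONS = frozenset(_TABLE11.start_codons)
#: The three stop codons.
STOP_CODONS = frozenset(_TABLE11.stop_codons)
#: The amber stop codon, read through as pyrrolysine in Pyl organisms.
AMBER = "TAG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def product_is_confident(product: str) -> bool:
    """True unless the product description contains an unreliable word."""
    low = product.lower()
    return not any(w in low for w in UNRELIABLE_PRODUCT_WORDS)


@dataclass
class AnnotatedFeature:
    """A gene annotation attached to a genome.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    ``kind`` is one of ``protein_coding``, ``rna_gene`` or ``other``.
    """

    start: int
    end: int
    strand: str
    kind: str
    product: str = ""
    is_confident: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature interval [{self.start},{self.end})")

    @property
    def frame_class(self) -> tuple[str, int]:
        """Reading-frame identity: (strand, codon-boundary phase).

        Two coding features translate the same codons only if they are on
        the same strand and their codon starts fall on the same residue
        class mod 3 (computed on forward-strand coordinates).
        """
        if self.strand == "+":
            return ("+", self.start % 3)
        return ("-", self.end % 3)


@dataclass
class GenomeRecord:
    """A genome sequence with its annotations."""

    genome_id: str
    sequence: str
    features: list[AnnotatedFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id}: empty sequence")
        bad = set(self.sequence) - VALID_NT
        if bad:
            raise ValueError(
                f"genome {self.genome_id}: unsupported characters {sorted(bad)}; "
                "only A, C, G, T and N are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_sequence(raw: str) -> str:
    return raw.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into genome records, sequences only.

    Sequences are uppercased and U is mapped to T.  Characters outside
    {A,C,G,T,N} raise a ``ValueError``.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(GenomeRecord(rec.id, _normalize_sequence(str(rec.seq))))
    if not records and path.stat().st_size > 0:
        raise ValueError(f"{path}: no FASTA records found (line 1 not a header?)")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.genome_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_KIND_BY_GFF_TYPE = {
    "CDS": "protein_coding",
    "gene": "protein_coding",
    "tRNA": "rna_gene",
    "rRNA": "rna_gene",
    "ncRNA": "rna_gene",
    "tmRNA": "rna_gene",
    "SRP_RNA": "rna_gene",
    "RNase_P_RNA": "rna_gene",
    "antisense_RNA": "rna_gene",
}


def _parse_gff_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        key, value = chunk.split("=", 1)
        attrs[key] = urllib.parse.unquote(value)
    return attrs


def read_annotations(
    path: str | Path, genome: GenomeRecord | None = None, genome_id: str | None = None
) -> list[AnnotatedFeature]:
    """Read GFF3 features for one genome.

    Features are filtered to the named genome (seqid column).  A feature
    whose coordinates fall outside the sequence is dropped with a warning
    rather than aborting the run.  ``is_confident`` is derived from the
    ``product`` attribute word list and the ``pseudo`` flag.
    """
    if genome is not None:
        genome_id = genome.genome_id
    if genome_id is None:
        raise ValueError("either genome or genome_id must be given")
    feats: list[AnnotatedFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attr_field = cols
            if seqid != genome_id:
                continue
            kind = _KIND_BY_GFF_TYPE.get(ftype, "other")
            if ftype == "region":
                continue
            try:
                start1i, end1i = int(start1), int(end1)
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from err
            attrs = _parse_gff_attributes(attr_field)
            product = attrs.get("product", "")
            pseudo = attrs.get("pseudo", "").lower() in ("true", "1") or "pseudogene" in attrs
            confident = product_is_confident(product) and not pseudo
            if strand not in "+-":
                logger.warning("%s:%d: strandless feature dropped", path, lineno)
                continue
            start0, end0 = start1i - 1, end1i  # 1-based inclusive -> 0-based half-open
            if start0 < 0 or start0 >= end0 or (genome is not None and end0 > len(genome)):
                logger.warning(
                    "%s:%d: feature [%d,%d] outside sequence bounds, dropped",
                    path,
                    lineno,
                    start1i,
                    end1i,
                )
                continue
            feats.append(AnnotatedFeature(start0, end0, strand, kind, product, confident))
    return feats


def write_annotations(
    features: Iterable[AnnotatedFeature], genome_id: str, path: str | Path, append: bool = False
) -> None:
    """Write features as GFF3 (coordinates converted back to 1-based)."""
    kind_to_type = {"protein_coding": "CDS", "rna_gene": "ncRNA", "other": "misc_feature"}
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("##gff-version 3\n")
        for ft in features:
            attrs = f"product={urllib.parse.quote(ft.product, safe=' ')}" if ft.product else "."
            fh.write(
                "\t".join(
                    [
                        genome_id,
                        "pylseeker",
                        kind_to_type[ft.kind],
                        str(ft.start + 1),
                        str(ft.end),
                        ".",
                        ft.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def reverse_complement(seq: str) -> str:
    """Standard reverse complement over {A,C,G,T,N}."""
    bad = set(seq) - VALID_NT
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt_seq: str, amber_as_pyl: bool = False) -> str:
    """Translate with table 11; a trailing partial codon is dropped.

    In-frame TAG is rendered as the pyrrolysine placeholder 'O' when
    ``amber_as_pyl`` is set, '*' otherwise.  Codons containing N
    translate to 'X'.
    """
    n = len(nt_seq) - len(nt_seq) % 3
    out = []
    fwd = _TABLE11.forward_table
    for i in range(0, n, 3):
        codon = nt_seq[i : i + 3]
        if codon == AMBER:
            out.append("O" if amber_as_pyl else "*")
        elif codon in STOP_CODONS:
            out.append("*")
        elif "N" in codon:
            out.append("X")
        else:
            out.append(fwd[codon])
    return "".join(out)


def gc_content(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


__all__ = [
    "AMBER",
    "AnnotatedFeature",
    "GenomeRecord",
    "START_CODONS",
    "STOP_CODONS",
    "UNRELIABLE_PRODUCT_WORDS",
    "VALID_NT",
    "gc_content",
    "product_is_confident",
    "read_annotations",
    "read_fasta",
    "reverse_complement",
    "translate",
    "write_annotations",
    "write_fasta",
]
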