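"""Synthetic genomes with planted amber-interrupted gene families.

The generator builds prokaryote-like genomes (random background at a
target GC, annotated codon-biased protein-coding genes) and plants
homologous families of amber-interrupted ORFs with controlled
nucleotide divergence, synonymous-codon bias and an optional conserved
hairpin in the 100-nt region downstream of the amber codon.  Every
planted member satisfies the iORF grammar by construction (an in-frame
TAA guard immediately 5' of the start codon pins the scanner to the
intended start), and the ground truth is recorded so each pipeline
stage can be tested without external data.

The default benchmark emulates the study conditions of the real screen
at desk scale: 13 genomes; six positive families patterned on the known
pyrrolysine gene clusters (many organisms, long upstream regions,
gene-like codon usage, partly with a conserved hairpin); several dozen
non-positive "decoy" families that emulate the conserved spurious iORF
clusters real genomes produce (few members, one or two organisms, short
upstream regions); and a handful of families arranged to trigger the
shadow-ORF and RNA-gene pruning rules.  Decoy singleton iORFs also
arise naturally from the random background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .coding_potential import SYNONYMOUS_CODONS
from .genome_io import (
    AMBER,
    AnnotatedFeature,
    GenomeRecord,
    STOP_CODONS,
    reverse_complement,
    translate,
)

GUARD = "TAA"  # in-frame stop planted 5' of each member's start codon
HAIRPIN_STEM = 12
HAIRPIN_LOOP = 6
PLANT_MARGIN = 6

_PRODUCTS = (
    "DNA-directed RNA polymerase subunit",
    "elongation factor Tu",
    "ABC transporter ATP-binding protein",
    "30S ribosomal protein S4",
    "methylmalonyl-CoA mutase",
    "aspartate aminotransferase",
    "cell division protein FtsZ",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "preprotein translocase subunit SecY",
    "hypothetical protein",  # unreliable annotation, roughly 1 in 10
)


class CodonUsage:
    """A fixed coding-sequence process shared by all genomes.

    Amino acids follow a first-order Markov chain (each residue prefers
    a fixed successor with probability ``chain_bias``, the rest being
    uniform) and, within each amino acid, synonymous codons get
    geometrically decaying weights (ratio 1/3).  Both dependencies are
    learnable by the codon HMM, so simulated genes carry a coding signal
    that codon shuffling destroys, as in real coding sequence.
    """

    def __init__(self, ratio: float = 1 / 3, chain_bias: float = 0.35):
        self.amino_acids = tuple(sorted(SYNONYMOUS_CODONS))
        self.chain_bias = chain_bias
        self.weights: dict[str, tuple[np.ndarray, tuple[str, ...]]] = {}
        for aa, codons in SYNONYMOUS_CODONS.items():
            w = np.array([ratio**i for i in range(len(codons))])
            self.weights[aa] = (w / w.sum(), codons)

    def sample_codon(self, aa: str, rng: np.random.Generator) -> str:
        p, codons = self.weights[aa]
        return codons[rng.choice(len(codons), p=p)]

    def sample_protein(self, n: int, rng: np.random.Generator) -> list[str]:
        """n amino acids from the first-order chain."""
        k = len(self.amino_acids)
        aas = [self.amino_acids[rng.integers(k)]]
        for _ in range(n - 1):
            if rng.random() < self.chain_bias:
                nxt = (self.amino_acids.index(aas[-1]) + 1) % k
                aas.append(self.amino_acids[nxt])
            else:
                aas.append(self.amino_acids[rng.integers(k)])
        return aas

    def sample_codons(self, n: int, rng: np.random.Generator) -> list[str]:
        """n codons whose amino acids follow the chain."""
        return [self.sample_codon(aa, rng) for aa in self.sample_protein(n, rng)]


DEFAULT_USAGE = CodonUsage()


@dataclass
class PlantedMember:
    genome_id: str
    strand: str
    local_start: int  # strand-local 0-based position of the start codon
    local_stop_end: int  # one past the terminal stop codon
    uag_offset: int  # nt from start codon to amber codon

    @property
    def iorf_id(self) -> str:
        return f"{self.genome_id}:{self.strand}:{self.local_start}-{self.local_stop_end}"


@dataclass
class PlantedFamily:
    family_id: str
    is_positive: bool
    members: list[PlantedMember]
    template_nt: str
    sub_rate: float
    syn_bias: float
    hairpin: bool
    prune_reason: str | None = None  # "shadow" / "rna" for rule-a/b fixtures

    @property
    def member_ids(self) -> list[str]:
        return [m.iorf_id for m in self.members]


@dataclass
class SyntheticTruth:
    seed: int
    families: list[PlantedFamily] = field(default_factory=list)

    @property
    def positives(self) -> list[PlantedFamily]:
        return [f for f in self.families if f.is_positive]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "families": [
                {
                    "family_id": f.family_id,
                    "is_positive": f.is_positive,
                    "sub_rate": f.sub_rate,
                    "syn_bias": f.syn_bias,
                    "hairpin": f.hairpin,
                    "prune_reason": f.prune_reason,
                    "members": [m.__dict__ for m in f.members],
                }
                for f in self.families
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_background(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _gene_sequence(n_codons: int, usage: CodonUsage, rng: np.random.Generator) -> str:
    body = "".join(usage.sample_codons(n_codons - 2, rng))
    stop = ("TAA", "TGA")[rng.integers(2)]
    return "ATG" + body + stop


def generate_background_genome(
    length: int,
    gc: float = 0.45,
    gene_density: float = 0.5,
    seed: int | None = None,
    genome_id: str = "synthetic",
    usage: CodonUsage = DEFAULT_USAGE,
) -> GenomeRecord:
    """A random genome with annotated, codon-biased protein-coding genes.

    Genes (60-600 codons) are laid down left to right with random
    intergenic gaps sized so genes cover about ``gene_density`` of the
    sequence; both strands are used.  Annotated genes have valid starts
    and stops and no internal stop codons, so they can train the coding
    model directly.  About one gene in ten is annotated as a
    "hypothetical protein" (an unreliable annotation).
    """
    if not 0 < gene_density < 0.9:
        raise ValueError("gene_density must be in (0, 0.9)")
    rng = np.random.default_rng(seed)
    arr = _random_background(length, gc, rng)
    features: list[AnnotatedFeature] = []
    mean_gene_nt = 3 * 330
    mean_gap = mean_gene_nt * (1 - gene_density) / gene_density
    pos = int(rng.integers(50, max(51, int(mean_gap) + 50)))
    while True:
        n_codons = int(rng.integers(60, 601))
        gene = _gene_sequence(n_codons, usage, rng)
        if pos + len(gene) + 50 > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        insert = gene if strand == "+" else reverse_complement(gene)
        arr[pos : pos + len(gene)] = np.frombuffer(insert.encode(), dtype=np.uint8)
        product = _PRODUCTS[rng.integers(len(_PRODUCTS))]
        features.append(
            AnnotatedFeature(pos, pos + len(gene), strand, "protein_coding", product)
        )
        features[-1].is_confident = "hypothetical" not in product
        pos += len(gene) + max(30, int(rng.exponential(mean_gap)))
    if not features:
        raise ValueError(f"genome of length {length} too short for any gene")
    return GenomeRecord(genome_id, arr.tobytes().decode(), features)


def _occupied_intervals(genome: GenomeRecord) -> list[tuple[int, int]]:
    return sorted((f.start, f.end) for f in genome.features)


def _find_slot(
    genome: GenomeRecord,
    occupied: list[tuple[int, int]],
    size: int,
    rng: np.random.Generator,
    attempts: int = 200,
) -> int:
    n = len(genome)
    for _ in range(attempts):
        pos = int(rng.integers(0, max(1, n - size)))
        lo, hi = pos - PLANT_MARGIN, pos + size + PLANT_MARGIN
        if all(e <= lo or s >= hi for s, e in occupied):
            return pos
    raise ValueError(
        f"no intergenic slot of {size} nt found in genome {genome.genome_id}"
    )


def _sample_hairpin(rng: np.random.Generator) -> str:
    """A 12-bp stem / 6-nt loop hairpin whose sequence avoids creating
    stop codons in any frame of the overwritten window."""
    for _ in range(500):
        stem = "".join(rng.choice(list("GC"), size=HAIRPIN_STEM - 2)) + "AC"
        loop = "".join(rng.choice(list("ACGT"), size=HAIRPIN_LOOP))
        hp = stem + loop + reverse_complement(stem)
        if not any(hp[i : i + 3] in STOP_CODONS for i in range(len(hp) - 2)):
            return hp
    raise RuntimeError("could not sample a stop-free hairpin")


def _build_template(
    upstream_codons: int,
    downstream_codons: int,
    hairpin: bool,
    usage: CodonUsage,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, int] | None]:
    """Template iORF: ATG + upstream + TAG + downstream + stop.

    Returns the nucleotide string and the (start, end) window of the
    planted hairpin relative to the template, if any.
    """
    if downstream_codons < 34:
        raise ValueError("downstream_codons must be >= 34 for the 100-nt rule")
    up = "".join(usage.sample_codons(upstream_codons, rng))
    down = "".join(usage.sample_codons(downstream_codons, rng))
    stop = ("TAA", "TGA")[rng.integers(2)]
    hp_window = None
    if hairpin:
        hp = _sample_hairpin(rng)
        offset = 6  # keep the hairpin inside the first 100 nt, codon-aligned
        down = down[:offset] + hp + down[offset + len(hp) :]
        uag_pos = 3 + 3 * upstream_codons
        hp_window = (uag_pos + 3 + offset, uag_pos + 3 + offset + len(hp))
        for i in range(0, len(down) - 2, 3):
            if down[i : i + 3] in STOP_CODONS:
                raise RuntimeError("hairpin introduced an in-frame stop")
    return "ATG" + up + AMBER + down + stop, hp_window


def _mutate_member(
    template: str,
    sub_rate: float,
    syn_bias: float,
    hp_window: tuple[int, int] | None,
    rng: np.random.Generator,
) -> str:
    """Site-independent substitution with a synonymous-forcing bias.

    The start codon, the amber codon, the terminal stop, and the hairpin
    window (if any) are never touched; a mutation that would create an
    in-frame stop codon is redrawn as a synonymous change.
    """
    codons = [template[i : i + 3] for i in range(0, len(template), 3)]
    # the amber is the unique in-frame TAG between start and terminal stop
    uag_idx = None
    for idx, c in enumerate(codons):
        if c == AMBER and 0 < idx < len(codons) - 1:
            uag_idx = idx
            break
    assert uag_idx is not None
    bases = "ACGT"
    out = list(codons)
    for idx in range(1, len(codons) - 1):
        if idx == uag_idx:
            continue
        codon = codons[idx]
        span = (idx * 3, idx * 3 + 3)
        if hp_window and span[1] > hp_window[0] and span[0] < hp_window[1]:
            continue
        hit_sites = [k for k in range(3) if rng.random() < sub_rate]
        if not hit_sites:
            continue
        aa = translate(codon)
        if rng.random() < syn_bias:
            syns = SYNONYMOUS_CODONS[aa]
            out[idx] = syns[rng.integers(len(syns))]
        else:
            mutated = list(codon)
            for k in hit_sites:
                mutated[k] = bases[rng.integers(4)]
            cand = "".join(mutated)
            if cand in STOP_CODONS:
                syns = SYNONYMOUS_CODONS[aa]
                cand = syns[rng.integers(len(syns))]
            out[idx] = cand
    return "".join(out)


def plant_cluster(
    genomes: list[GenomeRecord],
    n_members: int,
    upstream_codons: int,
    downstream_codons: int,
    sub_rate: float = 0.05,
    syn_bias: float = 0.5,
    hairpin: bool = False,
    seed: int | None = None,
    family_id: str = "family",
    is_positive: bool = True,
    n_organisms: int | None = None,
    usage: CodonUsage = DEFAULT_USAGE,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
) -> PlantedFamily:
    """Plant one homologous iORF family into the given genomes (in place).

    Members are mutated copies of a common template inserted by
    overwriting intergenic windows (genome length and existing feature
    coordinates are preserved); each insertion is preceded by an
    in-frame TAA guard so the scanner reports exactly the planted
    coordinates.  ``n_organisms`` caps how many distinct genomes the
    members are spread over (default: as many as possible).  When
    planting several families, pass a shared ``occupied`` interval
    registry so families do not overwrite each other.
    """
    rng = np.random.default_rng(seed)
    template, hp_window = _build_template(
        upstream_codons, downstream_codons, hairpin, usage, rng
    )
    if n_organisms is None:
        n_organisms = min(n_members, len(genomes))
    hosts = list(rng.choice(len(genomes), size=min(n_organisms, len(genomes)), replace=False))
    if occupied is None:
        occupied = {g.genome_id: _occupied_intervals(g) for g in genomes}
    else:
        for g in genomes:
            occupied.setdefault(g.genome_id, _occupied_intervals(g))
    members: list[PlantedMember] = []
    uag_offset = 3 + 3 * upstream_codons
    for i in range(n_members):
        genome = genomes[hosts[i % len(hosts)]]
        member_core = _mutate_member(template, sub_rate, syn_bias, hp_window, rng)
        full = GUARD + member_core
        strand = "+" if rng.random() < 0.5 else "-"
        pos = _find_slot(genome, occupied[genome.genome_id], len(full), rng)
        insert = full if strand == "+" else reverse_complement(full)
        genome.sequence = (
            genome.sequence[:pos] + insert + genome.sequence[pos + len(full) :]
        )
        occupied[genome.genome_id].append((pos - PLANT_MARGIN, pos + len(full) + PLANT_MARGIN))
        occupied[genome.genome_id].sort()
        glen = len(genome)
        if strand == "+":
            local_start = pos + len(GUARD)
        else:
            local_start = glen - (pos + len(full)) + len(GUARD)
        members.append(
            PlantedMember(
                genome_id=genome.genome_id,
                strand=strand,
                local_start=local_start,
                local_stop_end=local_start + len(member_core),
                uag_offset=uag_offset,
            )
        )
    return PlantedFamily(
        family_id=family_id,
        is_positive=is_positive,
        members=members,
        template_nt=template,
        sub_rate=sub_rate,
        syn_bias=syn_bias,
        hairpin=hairpin,
    )


def _attach_shadow_annotation(genome: GenomeRecord, member: PlantedMember) -> None:
    """Overlay a confident CDS annotation in a shifted reading frame that
    fully covers the member's PYLIS region (pruning rule-a fixture)."""
    if member.strand == "+":
        fwd_uag = member.local_start + member.uag_offset
        py_lo, py_hi = fwd_uag + 3, fwd_uag + 3 + 100
        frame_anchor = member.local_start
    else:
        glen = len(genome)
        fwd_end = glen - member.local_start
        fwd_uag_end = fwd_end - member.uag_offset
        py_hi, py_lo = fwd_uag_end - 3, fwd_uag_end - 3 - 100
        frame_anchor = glen - member.local_stop_end
    start = max(0, py_lo - 31)
    while start % 3 == frame_anchor % 3:  # force a different frame on the same strand
        start += 1
    end = min(len(genome), py_hi + 30)
    genome.features.append(
        AnnotatedFeature(start, end, "+", "protein_coding", "transposase fragment")
    )


def _attach_rna_annotation(genome: GenomeRecord, member: PlantedMember) -> None:
    """Overlay a confident RNA-gene annotation overlapping the member's
    PYLIS region by a few nucleotides (pruning rule-b fixture)."""
    if member.strand == "+":
        fwd_uag = member.local_start + member.uag_offset
        py_hi = fwd_uag + 3 + 100
    else:
        glen = len(genome)
        fwd_end = glen - member.local_start
        py_hi = fwd_end - member.uag_offset - 3
    start = max(0, py_hi - 5)
    genome.features.append(
        AnnotatedFeature(start, min(len(genome), start + 80), "+", "rna_gene", "tRNA-Lys")
    )


@dataclass
class BenchmarkConfig:
    """Study conditions of the default synthetic benchmark."""

    n_genomes: int = 13
    genome_length: int = 60_000
    gc: float = 0.45
    gene_density: float = 0.30
    n_positive_families: int = 6
    n_decoy_families: int = 72
    n_shadow_families: int = 3
    n_rna_overlap_families: int = 2
    positive_members: tuple[int, int] = (8, 14)
    positive_upstream: tuple[int, int] = (100, 340)
    positive_downstream: tuple[int, int] = (110, 380)
    positive_sub_rate: float = 0.05
    positive_syn_bias: float = 0.6
    decoy_members: tuple[int, int] = (2, 4)
    decoy_organisms: tuple[int, int] = (1, 2)
    decoy_upstream: tuple[int, int] = (2, 30)
    decoy_downstream: tuple[int, int] = (34, 60)
    decoy_sub_rate: float = 0.06
    decoy_syn_bias: float = 0.25

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown benchmark config keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


def make_benchmark(
    config: BenchmarkConfig | dict | None = None,
    seed: int = 0,
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """A complete runnable instance with recorded ground truth.

    Returns the genomes (annotations attached) and the truth table of
    planted families.  Positive families emulate the known pyrrolysine
    gene clusters; decoy families emulate conserved spurious iORF
    clusters; shadow and RNA-overlap families exist to be pruned.
    """
    if config is None:
        config = BenchmarkConfig()
    elif isinstance(config, dict):
        config = BenchmarkConfig.from_dict(config)
    rng = np.random.default_rng(seed)
    genomes = [
        generate_background_genome(
            config.genome_length,
            config.gc,
            config.gene_density,
            seed=int(rng.integers(2**31)),
            genome_id=f"g{i:02d}",
        )
        for i in range(config.n_genomes)
    ]
    truth = SyntheticTruth(seed=seed)
    occupied = {g.genome_id: _occupied_intervals(g) for g in genomes}

    def ri(lohi: tuple[int, int]) -> int:
        return int(rng.integers(lohi[0], lohi[1] + 1))

    for i in range(config.n_positive_families):
        fam = plant_cluster(
            genomes,
            n_members=ri(config.positive_members),
            upstream_codons=ri(config.positive_upstream),
            downstream_codons=ri(config.positive_downstream),
            sub_rate=config.positive_sub_rate,
            syn_bias=config.positive_syn_bias,
            hairpin=i % 2 == 0,  # half the positives carry a conserved hairpin
            seed=int(rng.integers(2**31)),
            family_id=f"pos{i:02d}",
            is_positive=True,
            occupied=occupied,
        )
        truth.families.append(fam)
    for i in range(config.n_decoy_families):
        fam = plant_cluster(
            genomes,
            n_members=ri(config.decoy_members),
            upstream_codons=ri(config.decoy_upstream),
            downstream_codons=ri(config.decoy_downstream),
            sub_rate=config.decoy_sub_rate,
            syn_bias=config.decoy_syn_bias,
            hairpin=False,
            seed=int(rng.integers(2**31)),
            family_id=f"dec{i:02d}",
            is_positive=False,
            n_organisms=ri(config.decoy_organisms),
            occupied=occupied,
        )
        truth.families.append(fam)
    for i in range(config.n_shadow_families):
        fam = plant_cluster(
            genomes,
            n_members=2,
            upstream_codons=ri(config.decoy_upstream),
            downstream_codons=ri(config.decoy_downstream),
            sub_rate=config.decoy_sub_rate,
            syn_bias=config.decoy_syn_bias,
            seed=int(rng.integers(2**31)),
            family_id=f"shadow{i:02d}",
            is_positive=False,
            n_organisms=1,
            occupied=occupied,
        )
        fam.prune_reason = "shadow"
        by_id = {g.genome_id: g for g in genomes}
        _attach_shadow_annotation(by_id[fam.members[0].genome_id], fam.members[0])
        truth.families.append(fam)
    for i in range(config.n_rna_overlap_families):
        fam = plant_cluster(
            genomes,
            n_members=2,
            upstream_codons=ri(config.decoy_upstream),
            downstream_codons=ri(config.decoy_downstream),
            sub_rate=config.decoy_sub_rate,
            syn_bias=config.decoy_syn_bias,
            seed=int(rng.integers(2**31)),
            family_id=f"rna{i:02d}",
            is_positive=False,
            n_organisms=1,
            occupied=occupied,
        )
        fam.prune_reason = "rna"
        by_id = {g.genome_id: g for g in genomes}
        _attach_rna_annotation(by_id[fam.members[0].genome_id], fam.members[0])
        truth.families.append(fam)
    return genomes, truth


__all__ = [
    "BenchmarkConfig",
    "CodonUsage",
    "DEFAULT_USAGE",
    "PlantedFamily",
    "PlantedMember",
    "SyntheticTruth",
    "generate_background_genome",
    "make_benchmark",
    "plant_cluster",
]
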