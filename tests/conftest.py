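import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from pylseeker import synthetic_data as sd


SMALL_BENCHMARK = dict(
    n_genomes=4,
    genome_length=20_000,
    n_positive_families=2,
    n_decoy_families=12,
    n_shadow_families=1,
    n_rna_overlap_families=1,
    positive_members=(4, 6),
    positive_upstream=(80, 160),
    positive_downstream=(60, 120),
)


@pytest.fixture(scope="session")
def small_benchmark():
    """A reduced planted-truth instance shared by integration tests."""
    genomes, truth = sd.make_benchmark(SMALL_BENCHMARK, seed=11)
    return genomes, truth


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_benchmark):
    """The small benchmark written to disk plus a completed pipeline run."""
    from pylseeker import genome_io, pipeline

    genomes, truth = small_benchmark
    out = tmp_path_factory.mktemp("smallrun")
    genome_io.write_fasta(genomes, out / "genomes.fasta")
    gff = out / "annotations.gff3"
    for i, g in enumerate(genomes):
        genome_io.write_annotations(g.features, g.genome_id, gff, append=i > 0)
    with open(out / "positives.txt", "w") as fh:
        for fam in truth.positives:
            for mid in fam.member_ids:
                fh.write(mid + "\n")
    cfg = pipeline.RunConfig(
        fasta=str(out / "genomes.fasta"),
        gff=str(gff),
        positives=str(out / "positives.txt"),
        outdir=str(out / "run"),
        seed=7,
    )
    rundir = pipeline.run_pipeline(cfg)
    return cfg, truth, rundir
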