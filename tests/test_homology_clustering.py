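import numpy as np
import pytest

from oracles import oracle_components
from pylseeker.genome_io import AnnotatedFeature, GenomeRecord
from pylseeker.homology_clustering import (
    HomologyMatch,
    build_clusters,
    evalue_from_score,
    prune_clusters,
    read_blast_hits,
    search_backend,
)
from pylseeker.iorf_extraction import extract_pylis, find_iorfs
from pylseeker import synthetic_data as sd


def planted_iorfs(seed=0, n_genomes=3, n_members=3, sub_rate=0.03):
    """Small genomes with one planted family; returns (iorfs, pylis, truth)."""
    rng = np.random.default_rng(seed)
    genomes = [
        sd.generate_background_genome(8000, 0.45, 0.3, seed=int(rng.integers(2**31)),
                                      genome_id=f"g{i}")
        for i in range(n_genomes)
    ]
    fam = sd.plant_cluster(
        genomes, n_members=n_members, upstream_codons=40, downstream_codons=50,
        sub_rate=sub_rate, syn_bias=0.5, seed=int(rng.integers(2**31)),
    )
    iorfs = [li for g in genomes for li in find_iorfs(g)]
    pylis = [extract_pylis(li) for li in iorfs]
    return genomes, iorfs, pylis, fam


class TestSearchBackend:
    def test_identical_regions_match_far_below_threshold(self):
        genomes, iorfs, pylis, fam = planted_iorfs(sub_rate=0.0)
        total_nt = sum(len(g) for g in genomes)
        matches = search_backend(pylis, total_nt)
        planted = set(fam.member_ids)
        hit_pairs = {(m.query_id, m.subject_id) for m in matches}
        for a in planted:
            for b in planted:
                if a != b:
                    assert (a, b) in hit_pairs
        assert all(m.evalue < 1e-8 for m in matches if m.query_id in planted
                   and m.subject_id in planted)

    def test_no_self_hits(self):
        genomes, iorfs, pylis, fam = planted_iorfs()
        matches = search_backend(pylis, sum(len(g) for g in genomes))
        assert all(m.query_id != m.subject_id for m in matches)

    def test_random_unrelated_regions_do_not_match(self):
        # empirical null: independent random background genomes share no
        # 33-mer homology at the 1e-6 e-value cut
        genomes = [
            sd.generate_background_genome(8000, 0.45, 0.3, seed=s, genome_id=f"g{s}")
            for s in (1, 2, 3)
        ]
        iorfs = [li for g in genomes for li in find_iorfs(g)]
        pylis = [extract_pylis(li) for li in iorfs]
        matches = search_backend(pylis, sum(len(g) for g in genomes))
        cross = [m for m in matches
                 if m.query_id.split(":")[0] != m.subject_id.split(":")[0]]
        assert cross == []

    def test_evalue_monotone_in_score(self):
        assert evalue_from_score(150, 33, 10**6) < evalue_from_score(100, 33, 10**6)
        assert evalue_from_score(150, 33, 10**6) < 1e-6 < evalue_from_score(60, 33, 10**6)


class TestBuildClusters:
    def _iorfs(self, n):
        genomes, iorfs, _, _ = planted_iorfs()
        assert len(iorfs) >= n
        return iorfs[:n]

    def test_transitive_components(self):
        iorfs = self._iorfs(5)
        ids = [li.iorf_id for li in iorfs]
        matches = [
            HomologyMatch(ids[0], ids[1], 1e-9, 50),
            HomologyMatch(ids[1], ids[2], 1e-9, 50),
            HomologyMatch(ids[3], ids[4], 1e-9, 50),
        ]
        clusters = build_clusters(matches, iorfs)
        got = {frozenset(c.member_ids) for c in clusters}
        assert got == {frozenset(ids[:3]), frozenset(ids[3:5])}
        assert all(c.cluster_id == min(c.member_ids) for c in clusters)

    def test_no_matches_no_clusters(self):
        assert build_clusters([], self._iorfs(3)) == []

    def test_match_order_and_direction_invariance(self):
        iorfs = self._iorfs(6)
        ids = [li.iorf_id for li in iorfs]
        edges = [(0, 1), (1, 2), (4, 5)]
        fwd = [HomologyMatch(ids[a], ids[b], 1e-9, 50) for a, b in edges]
        rev = [HomologyMatch(ids[b], ids[a], 1e-9, 50) for a, b in reversed(edges)]
        c1 = build_clusters(fwd, iorfs)
        c2 = build_clusters(rev, iorfs)
        assert [(c.cluster_id, c.member_ids) for c in c1] == [
            (c.cluster_id, c.member_ids) for c in c2
        ]

    def test_components_equal_union_find_oracle(self):
        rng = np.random.default_rng(0)
        iorfs = self._iorfs(12)
        ids = [li.iorf_id for li in iorfs]
        for _ in range(30):
            k = int(rng.integers(0, 14))
            edges = [
                (ids[rng.integers(12)], ids[rng.integers(12)]) for _ in range(k)
            ]
            edges = [(a, b) for a, b in edges if a != b]
            matches = [HomologyMatch(a, b, 1e-9, 50) for a, b in edges]
            got = {frozenset(c.member_ids) for c in build_clusters(matches, iorfs)}
            assert got == oracle_components(ids, edges)

    def test_membership_partitions(self):
        genomes, iorfs, pylis, fam = planted_iorfs(n_members=4)
        matches = search_backend(pylis, sum(len(g) for g in genomes))
        clusters = build_clusters(matches, iorfs)
        seen = set()
        for c in clusters:
            assert c.n >= 2
            assert not (seen & set(c.member_ids))
            seen.update(c.member_ids)

    def test_strict_reciprocal_mode(self):
        iorfs = self._iorfs(2)
        ids = [li.iorf_id for li in iorfs]
        one_way = [HomologyMatch(ids[0], ids[1], 1e-9, 50)]
        assert build_clusters(one_way, iorfs, strict_reciprocal=False)
        assert not build_clusters(one_way, iorfs, strict_reciprocal=True)
        both = one_way + [HomologyMatch(ids[1], ids[0], 1e-9, 50)]
        assert build_clusters(both, iorfs, strict_reciprocal=True)


class TestPruning:
    def _cluster_with_member(self):
        genomes, iorfs, pylis, fam = planted_iorfs(n_members=2, sub_rate=0.0)
        matches = search_backend(pylis, sum(len(g) for g in genomes))
        clusters = build_clusters(matches, iorfs)
        target = [c for c in clusters if set(fam.member_ids) & set(c.member_ids)]
        assert target
        return genomes, target, fam

    @staticmethod
    def _pylis_interval(member, genomes):
        g = {x.genome_id: x for x in genomes}[member.genome_id]
        li = [x for x in find_iorfs(g) if x.iorf_id == member.iorf_id][0]
        return g, li

    def test_shadow_cds_different_frame_removes_cluster(self):
        genomes, clusters, fam = self._cluster_with_member()
        g, li = self._pylis_interval(fam.members[0], genomes)
        strand, phase = li.frame_class
        # same strand, frame shifted by +1, fully covering the PYLIS region
        start = li.pylis_fwd_start - 31
        if strand == "+":
            while start % 3 != (phase + 1) % 3:
                start += 1
            feat = AnnotatedFeature(start, li.pylis_fwd_end + 30, "+",
                                    "protein_coding", "transposase")
        else:
            end = li.pylis_fwd_end + 30
            while end % 3 != (phase + 1) % 3:
                end += 1
            feat = AnnotatedFeature(start, end, "-", "protein_coding", "transposase")
        assert feat.frame_class != li.frame_class
        pruned = prune_clusters(clusters, {g.genome_id: [feat]})
        assert all(fam.members[0].iorf_id not in c.member_ids for c in pruned)

    def test_opposite_strand_counts_as_different_frame(self):
        genomes, clusters, fam = self._cluster_with_member()
        g, li = self._pylis_interval(fam.members[0], genomes)
        other = "-" if li.orf.strand == "+" else "+"
        feat = AnnotatedFeature(max(0, li.pylis_fwd_start - 40), li.pylis_fwd_end + 40,
                                other, "protein_coding", "polymerase")
        pruned = prune_clusters(clusters, {g.genome_id: [feat]})
        assert all(fam.members[0].iorf_id not in c.member_ids for c in pruned)

    def test_same_frame_overlap_retained(self):
        genomes, clusters, fam = self._cluster_with_member()
        g, li = self._pylis_interval(fam.members[0], genomes)
        if li.orf.strand == "+":
            start = li.fwd_start
            feat = AnnotatedFeature(start, li.fwd_end, "+", "protein_coding", "kinase")
        else:
            feat = AnnotatedFeature(li.fwd_start, li.fwd_end, "-", "protein_coding", "kinase")
        assert feat.frame_class == li.frame_class
        pruned = prune_clusters(clusters, {g.genome_id: [feat]})
        assert clusters[0] in pruned

    def test_rna_overlap_removes_cluster(self):
        genomes, clusters, fam = self._cluster_with_member()
        g, li = self._pylis_interval(fam.members[0], genomes)
        rna = AnnotatedFeature(
            max(0, li.pylis_fwd_end - 5), li.pylis_fwd_end + 40, "+", "rna_gene", "tRNA-Lys"
        )
        pruned = prune_clusters(clusters, {g.genome_id: [rna]})
        assert all(fam.members[0].iorf_id not in c.member_ids for c in pruned)

    def test_unreliable_annotations_do_not_prune(self):
        genomes, clusters, fam = self._cluster_with_member()
        g, li = self._pylis_interval(fam.members[0], genomes)
        rna = AnnotatedFeature(
            max(0, li.pylis_fwd_end - 5), li.pylis_fwd_end + 40, "+", "rna_gene",
            "predicted RNA",
        )
        rna.is_confident = False
        assert prune_clusters(clusters, {g.genome_id: [rna]}) == clusters

    def test_pruning_monotone_in_annotations(self):
        genomes, clusters, fam = self._cluster_with_member()
        g, li = self._pylis_interval(fam.members[0], genomes)
        rna = AnnotatedFeature(
            max(0, li.pylis_fwd_end - 5), li.pylis_fwd_end + 40, "+", "rna_gene", "tRNA"
        )
        few = prune_clusters(clusters, {})
        more = prune_clusters(clusters, {g.genome_id: [rna]})
        assert {c.cluster_id for c in more} <= {c.cluster_id for c in few}


class TestBlastTabular:
    def test_reads_and_maps_hits(self, tmp_path):
        genomes, iorfs, pylis, fam = planted_iorfs(n_members=2, sub_rate=0.0)
        a, b = fam.members[:2]
        li_b = [x for g in genomes for x in find_iorfs(g) if x.iorf_id == b.iorf_id][0]
        row = "\t".join(
            [
                a.iorf_id, b.genome_id, "100.0", "33", "0", "0", "1", "33",
                str(li_b.fwd_start + 1), str(li_b.fwd_end), "1e-20", "120",
            ]
        )
        stray = "\t".join(
            [a.iorf_id, b.genome_id, "100.0", "33", "0", "0", "1", "33",
             "1", "5", "1e-20", "120"]
        )
        weak = row.replace("1e-20", "1e-3")
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join([row, stray, weak]) + "\n")
        matches = read_blast_hits(p, iorfs)
        pairs = {(m.query_id, m.subject_id) for m in matches}
        assert (a.iorf_id, b.iorf_id) in pairs  # the real hit is mapped
        # every mapped subject genuinely overlaps the strong hit's interval;
        # the stray (non-iORF) hit and the weak e-value hit produce nothing else
        by_id = {li.iorf_id: li for li in iorfs}
        for _q, s in pairs:
            li = by_id[s]
            assert li.fwd_start < li_b.fwd_end and li_b.fwd_start < li.fwd_end

    def test_rejects_short_rows(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\tc\n")
        with pytest.raises(ValueError):
            read_blast_hits(p, [])
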