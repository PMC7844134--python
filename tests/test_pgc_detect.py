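import pytest

from gemmapgc.family_search import FamilyAssignment
from gemmapgc.genome_io import AnnotatedGenome, Contig, GeneFeature
from gemmapgc.pgc_detect import (ChainingParams, detect_clusters,
                                 probe_continuity)
from gemmapgc.pipeline import run_scan
from gemmapgc.synthetic_data import (SimulationSpec, rotate_genome,
                                     simulate_genome)


def _toy_genome(gene_specs, contig_len=200_000, circular=False):
    """gene_specs: list of (start, length, family_or_None)."""
    feats, assignments = [], []
    for i, (start, length, family) in enumerate(gene_specs):
        locus = f"g{i:02d}"
        feats.append(GeneFeature("c1", start, start + length, "+", locus,
                                 protein="M" * 50))
        if family:
            assignments.append(FamilyAssignment(
                locus_tag=locus, family=family, bit_score=300, evalue=1e-40,
                coverage=0.95, identity=85))
    genome = AnnotatedGenome("toy", [Contig("c1", contig_len, circular)], feats)
    return genome, assignments


class TestChaining:
    def test_template_genome_yields_one_cluster_with_all_planted_genes(
            self, template_genome, template_scan):
        _, truth = template_genome
        assert len(template_scan.clusters) == 1
        expected = {g.locus_tag for g in truth.genes if g.kind == "cluster"}
        got = {f.locus_tag for f, _ in template_scan.clusters[0].members}
        assert got == expected

    def test_no_photosynthesis_assignments_no_clusters(self):
        genome, _ = _toy_genome([(100, 900, None), (1500, 900, None)])
        assert detect_clusters(genome, []) == []

    def test_large_insertion_splits_cluster_into_two(self):
        families = ["bchF", "bchN", "bchB", "bchH", "pufB", "pufA", "pufL",
                    "pufM"]
        specs = []
        pos = 1000
        for i, fam in enumerate(families):
            specs.append((pos, 900, fam))
            pos += 1100
            if i == 3:
                pos += 50_000  # non-photosynthesis insertion
        genome, assignments = _toy_genome(specs)
        clusters = detect_clusters(genome, assignments)
        assert len(clusters) == 2
        sets = [c.families for c in clusters]
        assert sets == [{"bchF", "bchN", "bchB", "bchH"},
                        {"pufB", "pufA", "pufL", "pufM"}]

    def test_intervening_gene_run_breaks_a_chain(self):
        specs = [(1000, 500, "bchF"), (1600, 500, "bchN"),
                 (2200, 500, "bchB"), (2800, 500, "bchH")]
        pos = 3400
        for _ in range(6):              # six consecutive hypotheticals
            specs.append((pos, 300, None))
            pos += 350
        specs += [(pos, 500, "pufB"), (pos + 550, 500, "pufA"),
                  (pos + 1100, 500, "pufL"), (pos + 1650, 500, "pufM")]
        genome, assignments = _toy_genome(specs)
        params = ChainingParams(max_gap=50_000, max_intervening=5)
        clusters = detect_clusters(genome, assignments, params)
        assert len(clusters) == 2
        loose = detect_clusters(genome, assignments,
                                ChainingParams(max_gap=50_000,
                                               max_intervening=6))
        assert len(loose) == 1

    def test_min_members_suppresses_scattered_genes(self):
        genome, assignments = _toy_genome(
            [(1000, 500, "crtF"), (2000, 500, "bchL"), (90_000, 500, "pufM")])
        assert detect_clusters(genome, assignments) == []

    def test_partition_property(self, template_scan):
        """Every assigned photosynthesis gene lands in at most one cluster."""
        seen = set()
        for cluster in template_scan.clusters:
            for feat, _ in cluster.members:
                assert feat.locus_tag not in seen
                seen.add(feat.locus_tag)

    @pytest.mark.parametrize("gap_pair", [(2000, 8000), (4000, 50_000)])
    def test_gap_monotonicity(self, gap_pair):
        small, large = gap_pair
        families = ["bchF", "bchN", "bchB", "bchH", "bchL", "bchM",
                    "pufB", "pufA", "pufL", "pufM"]
        specs = [(1000 + i * 4000, 900, fam) for i, fam in enumerate(families)]
        genome, assignments = _toy_genome(specs)
        # compare raw chain counts (min_members=1): merging chains under a
        # larger gap can only reduce, never increase, their number
        n_small = len(detect_clusters(
            genome, assignments, ChainingParams(max_gap=small, min_members=1)))
        n_large = len(detect_clusters(
            genome, assignments, ChainingParams(max_gap=large, min_members=1)))
        assert n_large <= n_small


class TestCircular:
    @pytest.mark.parametrize("cut_after", [5, 15, 25])
    def test_rotation_inside_cluster_preserves_member_set(self, cut_after):
        genome, truth = simulate_genome(
            SimulationSpec(seed=21, circular=True, n_background_genes=6))
        base = run_scan(genome)
        base_members = sorted(f.locus_tag for c in base.clusters
                              for f, _ in c.members)
        cluster_genes = sorted((g for g in truth.genes if g.kind == "cluster"),
                               key=lambda g: g.start)
        offset = (cluster_genes[cut_after].end
                  + cluster_genes[cut_after + 1].start) // 2
        rotated, _ = rotate_genome(genome, truth, offset)
        res = run_scan(rotated)
        members = sorted(f.locus_tag for c in res.clusters
                         for f, _ in c.members)
        assert members == base_members
        assert len(res.clusters) == 1


class TestContinuity:
    def test_all_three_anchors_in_one_cluster(self, template_scan):
        report = probe_continuity(template_scan.clusters,
                                  template_scan.assignments)
        assert report.continuous
        assert report.anchors_found == {"acsF", "bchO", "puhE"}
        assert report.split_flags == set()

    def test_missing_bchO_breaks_continuity(self):
        layout = [(1000 + i * 1100, 900, fam) for i, fam in enumerate(
            ["acsF", "lhaA", "puhA", "puhB", "puhC", "puhE", "pufB", "pufA"])]
        genome, assignments = _toy_genome(layout)
        clusters = detect_clusters(genome, assignments)
        report = probe_continuity(clusters)
        assert not report.continuous
        assert report.anchors_found == {"acsF", "puhE"}

    def test_split_acsF_in_one_cluster_flags_but_keeps_continuity(self):
        genome, truth = simulate_genome(
            SimulationSpec(seed=31, split_genes=frozenset({"acsF"})))
        res = run_scan(genome)
        report = res.report["continuity"]
        assert report["continuous"] is True
        assert report["split_flags"] == ["acsF"]
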