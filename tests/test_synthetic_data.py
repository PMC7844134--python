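import filecmp

import numpy as np
import pytest

from gemmapgc.genome_io import read_presence_matrix
from gemmapgc.pgc_compare import global_identity
from gemmapgc.pipeline import run_scan
from gemmapgc.references import load_references, reference_map
from gemmapgc.synthetic_data import (GEMMA_TEMPLATE, SimulationSpec,
                                     back_translate, fragment_to_mag,
                                     mutate_protein, package_fixtures,
                                     retained_gene_fraction, simulate_genome)
from gemmapgc.genome_io import write_annotated_genome


class TestMutation:
    def test_identity_one_reproduces_the_reference(self, rng):
        ref = reference_map()["bchH"].protein
        mutated, realized = mutate_protein(rng, ref, 1.0)
        assert mutated == ref and realized == 1.0

    @pytest.mark.parametrize("target", [0.95, 0.80, 0.60])
    def test_realized_identity_hits_the_target(self, rng, target):
        for family in ("acsF", "pufM", "bchL"):
            ref = reference_map()[family].protein
            mutated, realized = mutate_protein(rng, ref, target)
            assert abs(realized - target) <= 0.02
            identity, _ = global_identity(mutated, ref)
            assert identity == pytest.approx(100 * realized, abs=1e-9)

    def test_unsatisfiable_target_rejected(self):
        with pytest.raises(ValueError, match="0.2"):
            SimulationSpec(target_protein_identity=0.1)

    def test_back_translation_round_trips_through_table_11(self, rng):
        from Bio.Seq import Seq
        protein = reference_map()["puhA"].protein
        cds = back_translate(rng, protein)
        assert str(Seq(cds).translate(table=11, cds=False)) == protein + "*"


class TestSimulation:
    def test_genome_at_identity_one_plants_exact_references(self):
        genome, truth = simulate_genome(
            SimulationSpec(seed=7, target_protein_identity=1.0))
        refs = reference_map()
        planted = {g.locus_tag: g for g in truth.genes if g.kind == "cluster"}
        for feat in genome.features:
            gene = planted.get(feat.locus_tag)
            if gene and not gene.split:
                assert feat.protein == refs[gene.family].protein

    def test_mean_realized_identity_at_080(self):
        _, truth = simulate_genome(
            SimulationSpec(seed=8, target_protein_identity=0.80))
        realized = [g.realized_identity for g in truth.genes
                    if g.kind == "cluster" and not g.split]
        assert all(abs(r - 0.80) <= 0.02 for r in realized)
        assert 0.78 <= np.mean(realized) <= 0.82

    def test_same_spec_same_seed_byte_identical(self, tmp_path):
        spec = SimulationSpec(seed=9)
        for run in ("a", "b"):
            genome, truth = simulate_genome(spec)
            stem = tmp_path / run
            write_annotated_genome(genome, f"{stem}.gff3", f"{stem}.fna",
                                   f"{stem}.faa")
            truth.to_json(f"{stem}.truth.json")
        for ext in (".gff3", ".fna", ".faa", ".truth.json"):
            assert filecmp.cmp(tmp_path / f"a{ext}", tmp_path / f"b{ext}",
                               shallow=False)

    def test_template_architecture_is_planted_in_order(self):
        _, truth = simulate_genome(SimulationSpec(seed=10))
        planted = [g.family for g in truth.genes if g.kind == "cluster"]
        expected = [f for f, _ in GEMMA_TEMPLATE if f is not None]
        assert planted == expected

    def test_background_genes_are_never_assigned(self, template_genome,
                                                 template_scan):
        _, truth = template_genome
        background = {g.locus_tag for g in truth.genes
                      if g.kind in ("background", "hypothetical")}
        assigned = {a.locus_tag for a in template_scan.assignments}
        assert background.isdisjoint(assigned)


class TestEndToEndRecovery:
    def test_planted_families_recovered_and_markers_true(
            self, template_genome, template_scan):
        _, truth = template_genome
        assigned = {a.locus_tag: a.family for a in template_scan.assignments}
        planted = {g.locus_tag: g.family for g in truth.genes if g.family}
        recovered = sum(assigned.get(l) == f for l, f in planted.items())
        assert recovered / len(planted) >= 0.95
        assert len(template_scan.clusters) == 1
        sig = template_scan.signatures[0]
        assert sig.acsF_marker and sig.bchO_marker
        cls = template_scan.report["classification"]
        assert cls["cgb"] == "CGB"
        assert cls["oxygen"] == "aerobic-indicated"


class TestFragmentation:
    def test_full_completeness_single_contig_is_identity(self, template_genome):
        genome, truth = template_genome
        mag, mag_truth = fragment_to_mag(genome, truth, 1.0, 1, seed=1)
        assert len(mag.contigs) == 1
        assert mag.contigs[0].length == genome.contigs[0].length
        assert [(f.start, f.end, f.protein) for f in mag.features] == \
            [(f.start, f.end, f.protein) for f in genome.features]
        assert retained_gene_fraction(truth, mag_truth) == 1.0

    def test_retention_estimate_is_unbiased_at_080(self, template_genome):
        genome, truth = template_genome
        fractions = [
            retained_gene_fraction(
                truth, fragment_to_mag(genome, truth, 0.8, 12, seed=s)[1])
            for s in range(200)
        ]
        assert abs(np.mean(fractions) - 0.8) < 0.02

    def test_breakpoint_inside_acsF_reports_split(self, template_genome):
        genome, truth = template_genome
        # two-piece cut at full completeness: seek a replicate whose single
        # breakpoint falls inside acsF, splitting it across two contigs
        for seed in range(200):
            mag, mag_truth = fragment_to_mag(genome, truth, 1.0, 2, seed=seed)
            if any(g.family == "acsF" and g.split for g in mag_truth.genes):
                report = run_scan(mag).report
                assert "acsF" in report["continuity"]["split_flags"]
                return
        pytest.fail("no replicate produced a breakpoint inside acsF")


class TestPackagedFixtures:
    def test_fixture_files_written_and_parse(self, tmp_path):
        paths = package_fixtures(tmp_path)
        assert len(paths) == 3
        table3 = read_presence_matrix(tmp_path / "table3_key_genes.tsv")
        assert table3.genomes == ["ES-bin-14", "ES-bin-29", "ES-bin-51",
                                  "ES-bin-78", "LF-bin-215", "LF-bin-339"]

    def test_lf_bin_215_has_only_rhodopsin(self, table3_path):
        row = read_presence_matrix(table3_path).row("LF-bin-215")
        present = {m for m in row.index if row[m] == "present"}
        assert present == {"Rho-like"}

    def test_groenlandica_lacks_hemN_and_bchE(self, table2_path):
        row = read_presence_matrix(table2_path).row("G_groenlandica_TET16")
        assert row["hemN"] == "absent"
        assert row["bchE"] == "absent"
        assert row["BphP"] == "present" and row["BphO"] == "present"
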