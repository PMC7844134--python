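import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gemmapgc.architecture import (SUBCLUSTER_GENES, ArchitectureSignature,
                                   SubClusterBlock, compare_architectures,
                                   load_reference_architectures, marker_test,
                                   segment_families, segment_subclusters)
from gemmapgc.pgc_detect import PGCandidate

from oracles import breakpoint_distance, maximal_runs

_GENE_TO_BLOCK = {g: b for b, genes in SUBCLUSTER_GENES.items() for g in genes}


def _sig_from_blocks(order, orientations=None):
    """A signature with the given canonical block order (all forward unless
    orientations supplies strands)."""
    orientations = orientations or {}
    labelled = []
    for name in order:
        strand = orientations.get(name, "+")
        labelled.extend((gene, strand) for gene in SUBCLUSTER_GENES[name])
    return segment_families(labelled)


class TestSegmentation:
    def test_template_segments_into_six_canonical_blocks(self, template_scan):
        sig = template_scan.signatures[0]
        assert sig.canonical_block_count() == 6
        canonical = [b.name for b in sig.blocks if b.name in SUBCLUSTER_GENES]
        assert canonical == ["bchP2G", "bchFNBHLM", "lhaA-puhABC",
                             "pufBALMC", "crtF-bchCXYZ", "bchID"]
        singletons = [b.name for b in sig.blocks
                      if b.name not in SUBCLUSTER_GENES]
        assert set(singletons) == {"aerR", "ppsR", "acsF", "puhE", "bchO"}

    def test_empty_cluster_gives_empty_signature(self):
        cluster = PGCandidate(genome_id="g", members=[],
                              spans=[("c", 0, 0)], n_intervening=0)
        assert segment_subclusters(cluster).blocks == []

    def test_shuffled_families_match_maximal_run_oracle(self, rng):
        pool = [g for genes in SUBCLUSTER_GENES.values() for g in genes]
        for _ in range(25):
            families = list(rng.permutation(pool))[:int(rng.integers(5, 20))]
            sig = segment_families([(f, "+") for f in families])
            expected = maximal_runs([_GENE_TO_BLOCK[f] for f in families])
            got = [(b.name, len(b.members)) for b in sig.blocks]
            assert got == expected

    def test_strand_flip_and_reversal_leaves_signature_invariant(
            self, template_scan):
        cluster = template_scan.clusters[0]
        flipped = [(fam, "-" if feat.strand == "+" else "+")
                   for feat, fam in reversed(cluster.members)]
        sig_flipped = segment_families(flipped)
        sig = template_scan.signatures[0]
        assert [(b.name, b.orientation, b.members) for b in sig.blocks] == \
            [(b.name, b.orientation, b.members) for b in sig_flipped.blocks]

    def test_orientation_is_majority_strand(self):
        labelled = [("bchF", "+"), ("bchN", "+"), ("bchB", "-")]
        sig = segment_families(labelled)
        assert sig.blocks[0].orientation == "forward"


class TestMarkers:
    def test_template_has_both_markers(self, template_scan):
        result = marker_test(template_scan.signatures[0])
        assert (result.acsF_marker, result.bchO_marker) == (True, True)
        assert result.missing == set()

    def test_acsF_relocated_after_bchID_loses_its_marker(self):
        layout = [("aerR", "+"), ("ppsR", "+")]
        for block in ["bchP2G", "bchFNBHLM", "lhaA-puhABC"]:
            layout += [(g, "+") for g in SUBCLUSTER_GENES[block]]
        layout += [("puhE", "+")]
        layout += [(g, "+") for g in SUBCLUSTER_GENES["pufBALMC"]]
        layout += [("bchO", "+")]
        layout += [(g, "+") for g in SUBCLUSTER_GENES["crtF-bchCXYZ"]]
        layout += [(g, "+") for g in SUBCLUSTER_GENES["bchID"]]
        layout += [("acsF", "+")]
        result = marker_test(segment_families(layout))
        assert (result.acsF_marker, result.bchO_marker) == (False, True)

    def test_missing_acsF_reported(self):
        layout = []
        for block in ["bchFNBHLM", "lhaA-puhABC"]:
            layout += [(g, "+") for g in SUBCLUSTER_GENES[block]]
        result = marker_test(segment_families(layout))
        assert result.acsF_marker is False
        assert "acsF" in result.missing

    def test_intervening_canonical_block_defeats_the_marker(self):
        layout = [(g, "+") for g in SUBCLUSTER_GENES["bchFNBHLM"]]
        layout += [("acsF", "+")]
        layout += [(g, "+") for g in SUBCLUSTER_GENES["bchID"]]
        layout += [(g, "+") for g in SUBCLUSTER_GENES["lhaA-puhABC"]]
        result = marker_test(segment_families(layout))
        assert result.acsF_marker is False


class TestDistance:
    def test_identity(self, template_scan):
        sig = template_scan.signatures[0]
        assert compare_architectures(sig, sig) == 0

    def test_all_permutations_of_four_blocks_match_breakpoint_oracle(self):
        blocks = ["bchP2G", "bchFNBHLM", "lhaA-puhABC", "pufBALMC"]
        base = _sig_from_blocks(blocks)
        for perm in itertools.permutations(blocks):
            sig = _sig_from_blocks(list(perm))
            expected = breakpoint_distance(blocks, list(perm))
            assert compare_architectures(base, sig) == expected

    def test_adjacent_transposition_distance(self):
        base = _sig_from_blocks(["bchP2G", "bchFNBHLM", "lhaA-puhABC",
                                 "pufBALMC"])
        swapped = _sig_from_blocks(["bchP2G", "bchFNBHLM", "pufBALMC",
                                    "lhaA-puhABC"])
        oracle = breakpoint_distance(
            ["bchP2G", "bchFNBHLM", "lhaA-puhABC", "pufBALMC"],
            ["bchP2G", "bchFNBHLM", "pufBALMC", "lhaA-puhABC"])
        assert compare_architectures(base, swapped) == oracle

    def test_orientation_flip_counts_one(self):
        order = ["bchP2G", "bchFNBHLM", "lhaA-puhABC"]
        a = _sig_from_blocks(order)
        b = _sig_from_blocks(order, orientations={"bchP2G": "-"})
        assert compare_architectures(a, b) == 1

    def test_private_blocks_count(self):
        a = _sig_from_blocks(["bchP2G", "bchFNBHLM"])
        b = _sig_from_blocks(["bchP2G", "bchID"])
        assert compare_architectures(a, b) == 2

    @given(st.permutations(["bchP2G", "bchFNBHLM", "lhaA-puhABC",
                            "pufBALMC", "crtF-bchCXYZ"]))
    @settings(derandomize=True, deadline=None, max_examples=60)
    def test_symmetry(self, perm):
        base = _sig_from_blocks(["bchP2G", "bchFNBHLM", "lhaA-puhABC",
                                 "pufBALMC", "crtF-bchCXYZ"])
        other = _sig_from_blocks(list(perm))
        assert compare_architectures(base, other) == \
            compare_architectures(other, base)


class TestPackagedArchitectures:
    def test_gemma_template_markers(self):
        archs = load_reference_architectures()
        gemma = archs["gemma-template"]
        assert gemma.acsF_marker and gemma.bchO_marker
        assert gemma.canonical_block_count() == 6

    def test_every_proteobacterial_variant_is_distinct_from_the_template(self):
        archs = load_reference_architectures()
        gemma = archs.pop("gemma-template")
        assert archs, "packaged variants missing"
        for name, sig in archs.items():
            assert compare_architectures(gemma, sig) > 0, name
            assert not (sig.acsF_marker and sig.bchO_marker), name
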