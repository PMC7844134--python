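"""Stage orchestration: scan and compare pipelines with auditable reports.

``run_scan`` composes family assignment -> cluster chaining -> architecture
segmentation -> marker tests -> CGB / oxygen classification for one genome
and returns a JSON-serializable report that echoes every threshold used.
``run_compare`` relates two scanned genomes: per-family protein identities
with the >90% flag, nucleotide synteny blocks under both cutoff dialects,
and the architecture distance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .architecture import (ArchitectureSignature, compare_architectures,
                           marker_test, segment_subclusters)
from .classify import OxygenRuleSet, TaxonomyThresholds, classify_genome_row
from .family_search import SearchThresholds, assign_families, build_presence_matrix
from .genome_io import AnnotatedGenome
from .pgc_detect import ChainingParams, PGCandidate, detect_clusters, probe_continuity
from .pgc_compare import DIALECTS, pairwise_gene_identity, synteny_blocks
from .references import load_references, read_reference_fasta

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline in one structured object."""

    search: SearchThresholds = field(default_factory=SearchThresholds)
    chaining: ChainingParams = field(default_factory=ChainingParams)
    oxygen: OxygenRuleSet = field(default_factory=OxygenRuleSet)
    taxonomy: TaxonomyThresholds = field(default_factory=TaxonomyThresholds)
    reference_fasta: Optional[str] = None
    seed: int = 0

    _SECTIONS = {
        "search": SearchThresholds,
        "chaining": ChainingParams,
        "oxygen": OxygenRuleSet,
        "taxonomy": TaxonomyThresholds,
    }

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls._SECTIONS) | {"reference_fasta", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for section, klass in cls._SECTIONS.items():
            if section in raw:
                params = dict(raw[section])
                valid = {f.name for f in dataclasses.fields(klass)}
                bad = set(params) - valid
                if bad:
                    raise ValueError(f"unknown {section} keys: {sorted(bad)}")
                for key in ("require_absent", "require_present"):
                    if key in params:
                        params[key] = frozenset(params[key])
                kwargs[section] = klass(**params)
        if "reference_fasta" in raw:
            kwargs["reference_fasta"] = raw["reference_fasta"]
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)

    def thresholds_dict(self) -> dict:
        return {
            "search": _as_plain(self.search),
            "chaining": _as_plain(self.chaining),
            "oxygen": _as_plain(self.oxygen),
            "taxonomy": _as_plain(self.taxonomy),
        }

    def references(self):
        if self.reference_fasta:
            return read_reference_fasta(self.reference_fasta)
        return load_references()


def _as_plain(obj) -> dict:
    out = {}
    for f in dataclasses.fields(obj):
        value = getattr(obj, f.name)
        out[f.name] = sorted(value) if isinstance(value, frozenset) else value
    return out


@dataclass
class ScanResult:
    genome: AnnotatedGenome
    assignments: list
    clusters: list[PGCandidate]
    signatures: list[ArchitectureSignature]
    report: dict

    def best_cluster(self) -> Optional[PGCandidate]:
        return max(self.clusters, key=len) if self.clusters else None

    def best_signature(self) -> Optional[ArchitectureSignature]:
        if not self.clusters:
            return None
        best = max(range(len(self.clusters)), key=lambda i: len(self.clusters[i]))
        return self.signatures[best]


def run_scan(genome: AnnotatedGenome,
             config: PipelineConfig = None) -> ScanResult:
    """Scan one genome: assignments, clusters, architecture, classification."""
    config = config or PipelineConfig()
    refs = config.references()
    assignments = assign_families(genome, refs, config.search)
    matrix = build_presence_matrix({genome.genome_id: assignments})
    row = matrix.row(genome.genome_id)
    clusters = detect_clusters(genome, assignments, config.chaining)
    continuity = probe_continuity(clusters, assignments)
    signatures = []
    for cluster in clusters:
        sig = segment_subclusters(cluster)
        marker_test(sig)
        signatures.append(sig)
    classification = classify_genome_row(
        genome.genome_id, row, completeness=genome.completeness,
        rules=config.oxygen)

    report = {
        "genome_id": genome.genome_id,
        "thresholds": config.thresholds_dict(),
        "n_coding_features": len(genome.coding_features()),
        "assignments": [vars(a) for a in assignments],
        "presence": {m: row[m] for m in matrix.markers},
        "clusters": [{
            "spans": c.spans,
            "members": [[f.locus_tag, fam] for f, fam in c.members],
            "n_intervening": c.n_intervening,
            "continuous": c.continuous,
        } for c in clusters],
        "signatures": [s.to_dict() for s in signatures],
        "continuity": {
            "continuous": continuity.continuous,
            "anchors_found": sorted(continuity.anchors_found),
            "split_flags": sorted(continuity.split_flags),
        },
        "classification": classification.to_dict(),
    }
    return ScanResult(genome=genome, assignments=assignments,
                      clusters=clusters, signatures=signatures, report=report)


def run_compare(scan_a: ScanResult, scan_b: ScanResult,
                config: PipelineConfig = None) -> dict:
    """Compare two scanned genomes' best clusters."""
    config = config or PipelineConfig()
    cluster_a = scan_a.best_cluster()
    cluster_b = scan_b.best_cluster()
    report = {
        "genome_a": scan_a.genome.genome_id,
        "genome_b": scan_b.genome.genome_id,
        "thresholds": {**config.thresholds_dict(), "dialects": DIALECTS,
                       "high_identity_cutoff": 90.0},
    }
    if cluster_a is None or cluster_b is None:
        report["result"] = "no PGC"
        return report

    pairs, unpaired = pairwise_gene_identity(cluster_a, cluster_b)
    report["gene_identities"] = [vars(p) for p in pairs]
    report["unpaired_families"] = unpaired
    report["n_high_identity"] = sum(p.high_identity for p in pairs)

    sig_a, sig_b = scan_a.best_signature(), scan_b.best_signature()
    report["architecture_distance"] = compare_architectures(sig_a, sig_b)

    seq_a = _cluster_sequence(scan_a.genome, cluster_a)
    seq_b = _cluster_sequence(scan_b.genome, cluster_b)
    if seq_a and seq_b:
        report["synteny"] = {
            dialect: [vars(b) for b in synteny_blocks(seq_a, seq_b, dialect)]
            for dialect in DIALECTS
        }
    return report


def _cluster_sequence(genome: AnnotatedGenome,
                      cluster: PGCandidate) -> Optional[str]:
    parts = []
    for contig_id, start, end in cluster.spans:
        contig = genome.contig(contig_id)
        if contig.sequence is None:
            return None
        parts.append(contig.sequence[start:end])
    return "".join(parts)


def write_report(report: dict, json_path: Path | str,
                 tsv_path: Optional[Path | str] = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=1, default=str))
    if tsv_path and "assignments" in report:
        with open(tsv_path, "w") as fh:
            fh.write("locus_tag\tfamily\tbit_score\tevalue\tcoverage\t"
                     "identity\tsplit\n")
            for a in report["assignments"]:
                fh.write(f"{a['locus_tag']}\t{a['family']}\t"
                         f"{a['bit_score']:.1f}\t{a['evalue']:.3g}\t"
                         f"{a['coverage']:.3f}\t{a['identity']:.1f}\t"
                         f"{a['split']}\n")
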