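"""Chain photosynthesis-family genes into candidate gene clusters (PGCs).

Photosynthesis gene clusters are contiguous runs of bch/puf/puh/crt/
regulatory genes, typically ~42 kb in *Gemmatimonas*, interspersed with a
few hypothetical ORFs.  Two photosynthesis genes join the same cluster when
their genomic gap is at most ``max_gap`` and no more than
``max_intervening`` consecutive non-photosynthesis genes separate them.
Chaining wraps the origin on circular contigs.  In MAG mode clusters on
different contigs stay separate; the AcsF-BchO-PuhE continuity probe then
distinguishes complete, continuous clusters from fragmented ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome_io import AnnotatedGenome, GeneFeature
from .references import FAMILY_CATEGORY, PGC_CATEGORIES
from .family_search import FamilyAssignment

#: the three positionally flexible anchor genes used by the continuity probe
CONTINUITY_ANCHORS = frozenset({"acsF", "bchO", "puhE"})


@dataclass(frozen=True)
class ChainingParams:
    max_gap: int = 6000        # bp between consecutive photosynthesis genes
    max_intervening: int = 5   # consecutive non-photosynthesis genes tolerated
    min_members: int = 4       # smaller runs are background noise

    def __post_init__(self) -> None:
        if min(self.max_gap, self.max_intervening, self.min_members) <= 0:
            raise ValueError("chaining parameters must be positive")


@dataclass
class PGCandidate:
    """A candidate photosynthesis gene cluster on one contig."""

    genome_id: str
    members: list[tuple[GeneFeature, str]]   # (feature, family), in order
    spans: list[tuple[str, int, int]]        # (contig_id, start, end); 2 if wrapped
    n_intervening: int
    continuous: bool = False

    @property
    def contig_id(self) -> str:
        return self.spans[0][0]

    @property
    def families(self) -> set[str]:
        return {family for _, family in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ContinuityReport:
    continuous: bool
    anchors_found: set[str]
    split_flags: set[str]


def is_pgc_family(family: str) -> bool:
    return FAMILY_CATEGORY.get(family, "other") in PGC_CATEGORIES


def detect_clusters(
    genome: AnnotatedGenome,
    assignments: Sequence[FamilyAssignment],
    params: ChainingParams = ChainingParams(),
) -> list[PGCandidate]:
    """Chain assigned photosynthesis genes along each contig into clusters."""
    family_of = {a.locus_tag: a.family for a in assignments}
    unknown = set(family_of) - {f.locus_tag for f in genome.features}
    if unknown:
        raise ValueError(f"assignments reference unknown loci: {sorted(unknown)}")

    clusters: list[PGCandidate] = []
    for contig in genome.contigs:
        feats = genome.features_on(contig.id)
        photo_idx = [i for i, f in enumerate(feats)
                     if f.locus_tag in family_of
                     and is_pgc_family(family_of[f.locus_tag])]
        if not photo_idx:
            continue
        chains = _chain_linear(feats, photo_idx, params)
        if contig.circular and len(chains) >= 2:
            chains = _wrap_origin(feats, chains, contig.length, params)
        for chain in chains:
            if len(chain) < params.min_members:
                continue
            clusters.append(_make_candidate(genome.genome_id, contig.id,
                                            contig.length, feats, chain,
                                            family_of))
    return clusters


def _gap_and_intervening(feats: list[GeneFeature], i: int, j: int,
                         contig_len: int | None = None) -> tuple[int, int]:
    """Genomic gap (bp) and intervening gene count between feature i and j.

    When ``contig_len`` is given the path wraps from i over the origin to j.
    """
    if contig_len is None:
        gap = feats[j].start - feats[i].end
        intervening = j - i - 1
    else:
        gap = (contig_len - feats[i].end) + feats[j].start
        intervening = (len(feats) - i - 1) + j
    return max(gap, 0), intervening


def _chain_linear(feats: list[GeneFeature], photo_idx: list[int],
                  params: ChainingParams) -> list[list[int]]:
    chains: list[list[int]] = [[photo_idx[0]]]
    for prev, curr in zip(photo_idx, photo_idx[1:]):
        gap, intervening = _gap_and_intervening(feats, prev, curr)
        if gap <= params.max_gap and intervening <= params.max_intervening:
            chains[-1].append(curr)
        else:
            chains.append([curr])
    return chains


def _wrap_origin(feats: list[GeneFeature], chains: list[list[int]],
                 contig_len: int, params: ChainingParams) -> list[list[int]]:
    first, last = chains[0], chains[-1]
    gap, intervening = _gap_and_intervening(feats, last[-1], first[0],
                                            contig_len=contig_len)
    if gap <= params.max_gap and intervening <= params.max_intervening:
        chains = chains[1:-1] + [last + first]
    return chains


def _make_candidate(genome_id: str, contig_id: str, contig_len: int,
                    feats: list[GeneFeature], chain: list[int],
                    family_of: dict[str, str]) -> PGCandidate:
    members = [(feats[i], family_of[feats[i].locus_tag]) for i in chain]
    wrapped = any(b < a for a, b in zip(chain, chain[1:]))
    if wrapped:
        pivot = next(k for k in range(1, len(chain)) if chain[k] < chain[k - 1])
        head, tail = chain[:pivot], chain[pivot:]
        spans = [(contig_id, feats[head[0]].start, contig_len),
                 (contig_id, 0, feats[tail[-1]].end)]
        inside = set(range(chain[0], len(feats))) | set(range(0, chain[-1] + 1))
    else:
        spans = [(contig_id, feats[chain[0]].start, feats[chain[-1]].end)]
        inside = set(range(chain[0], chain[-1] + 1))
    n_intervening = len(inside) - len(chain)
    return PGCandidate(genome_id=genome_id, members=members, spans=spans,
                       n_intervening=n_intervening)


def probe_continuity(
    candidates: Sequence[PGCandidate],
    assignments: Sequence[FamilyAssignment] = (),
) -> ContinuityReport:
    """AcsF-BchO-PuhE continuity probe over one genome's candidates.

    A cluster set is *continuous* when a single candidate carries all three
    anchors; the anchors are the positionally flexible loci whose
    co-occurrence on one contig separates complete clusters from
    assembly-fragmented ones.  Split-gene merges (a gene recovered from two
    adjacent fragments) count as present and are reported in ``split_flags``.
    """
    anchors_found: set[str] = set()
    continuous = False
    for cand in candidates:
        present = cand.families & CONTINUITY_ANCHORS
        anchors_found |= present
        if present == CONTINUITY_ANCHORS:
            continuous = True
    split_flags = {a.family for a in assignments if a.split}
    for cand in candidates:
        cand.continuous = continuous and cand.families >= CONTINUITY_ANCHORS
    return ContinuityReport(continuous=continuous, anchors_found=anchors_found,
                            split_flags=split_flags)


def clusters_to_bed(clusters: Sequence[PGCandidate], path) -> None:
    """Export cluster spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for i, cand in enumerate(clusters):
            for contig_id, start, end in cand.spans:
                fh.write(f"{contig_id}\t{start}\t{end}\tPGC_{i + 1}\t"
                         f"{len(cand)}\t.\n")
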