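"""Assign query proteins to photosynthesis gene families.

The search is a Smith-Waterman local alignment against one representative
protein per family (BLOSUM62, gap open 11 / extend 1, i.e. a gap of length
k costs 11 + k) with BLAST-like significance semantics: the raw score is
converted to a bit score and an E-value with the Karlin-Altschul formula
using the standard gapped parameters, over a search space of query length x
total reference length.  A protein is assigned to a family only when

    E < E_max  (default 1e-5)   and   coverage > C_min  (default 0.40),

coverage being the fraction of the *reference* protein spanned by the
alignment — the rule screens for homolog completeness relative to the known
gene.  MAG assemblies frequently split genes across breakpoints, so two
same-family sub-threshold hits on one contig closer than ``split_gap`` whose
combined coverage clears ``C_min`` are merged and flagged ``split``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import (ABSENT, PRESENT, AnnotatedGenome, GeneFeature,
                        PresenceMatrix)
from .references import (CATEGORY_MARKERS, FAMILY_CATEGORY, MARKER_FAMILY,
                         FamilyReference)

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for gapped BLOSUM62, open 11 / extend 1
# (the values BLAST reports for protein searches with its defaults).
KA_LAMBDA = 0.267
KA_K = 0.041

GAP_OPEN = 11   # cost of opening a gap (first gapped residue costs open+extend)
GAP_EXTEND = 1

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
_MATRIX_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


@dataclass(frozen=True)
class SearchThresholds:
    """Significance and coverage cutoffs for family assignment."""

    E_max: float = 1e-5
    C_min: float = 0.40
    split_gap: int = 3000  # bp; max gap between fragments of a split gene

    def __post_init__(self) -> None:
        if self.E_max <= 0:
            raise ValueError("E_max must be positive")
        if not (0 < self.C_min < 1):
            raise ValueError("C_min must be in (0, 1)")


@dataclass
class FamilyAssignment:
    """Best-family call for one locus, with the evidence behind it."""

    locus_tag: str
    family: str
    bit_score: float
    evalue: float
    coverage: float
    identity: float
    split: bool = False

    @property
    def category(self) -> str:
        return FAMILY_CATEGORY.get(self.family, "other")


def make_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """A BLOSUM62 affine-gap aligner (gap of length k scores -(11 + k))."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def sanitize_protein(protein: str, locus_tag: str = "?") -> str:
    """Upper-case and map residues outside the scoring alphabet to X."""
    protein = protein.upper().rstrip("*")
    if not set(protein) <= _MATRIX_ALPHABET:
        bad = sorted(set(protein) - _MATRIX_ALPHABET)
        warnings.warn(
            f"{locus_tag}: non-standard residues {bad} treated as mismatch",
            stacklevel=2)
        protein = "".join(c if c in _MATRIX_ALPHABET else "X" for c in protein)
    return protein


def bit_score(raw_score: float) -> float:
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def evalue(raw_score: float, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * raw_score)


def alignment_stats(alignment: Align.Alignment) -> tuple[int, int, int, int, int]:
    """(matches, columns, ref_span_start, ref_span_end, query_span) of an alignment.

    Columns count aligned residue pairs plus internal gap columns; terminal
    gaps are outside the aligned blocks and therefore never counted.
    """
    query, ref = alignment.sequences
    blocks_q, blocks_r = alignment.aligned
    matches = 0
    columns = 0
    prev_q = prev_r = None
    for (qs, qe), (rs, re) in zip(blocks_q.tolist(), blocks_r.tolist()):
        if prev_q is not None:
            columns += (qs - prev_q) + (rs - prev_r)  # internal gap columns
        matches += sum(1 for a, b in zip(query[qs:qe], ref[rs:re]) if a == b)
        columns += qe - qs
        prev_q, prev_r = qe, re
    r_start = int(blocks_r[0][0]) if len(blocks_r) else 0
    r_end = int(blocks_r[-1][1]) if len(blocks_r) else 0
    q_span = (int(blocks_q[-1][1]) - int(blocks_q[0][0])) if len(blocks_q) else 0
    return matches, columns, r_start, r_end, q_span


def assign_families(
    genome: AnnotatedGenome,
    refs: Sequence[FamilyReference],
    thresholds: SearchThresholds = SearchThresholds(),
) -> list[FamilyAssignment]:
    """Assign each coding gene to at most one photosynthesis gene family.

    The best family per locus is chosen by bit score, ties broken by
    identity and then lexicographic family name; both the E-value and the
    coverage threshold must hold.  Sub-threshold coverage hits are then
    re-examined by the split-gene rule (see module docstring).
    """
    if not refs:
        raise ValueError("empty reference set")
    for ref in refs:
        if not ref.protein:
            raise ValueError(f"reference {ref.family} has an empty protein")

    aligner = make_aligner("local")
    db_len = sum(len(r.protein) for r in refs)
    clean_refs = [(r, sanitize_protein(r.protein, r.family)) for r in refs]

    accepted: list[FamilyAssignment] = []
    fragments: list[tuple[GeneFeature, FamilyAssignment]] = []
    features = {f.locus_tag: f for f in genome.features}

    for feat in genome.coding_features():
        query = sanitize_protein(feat.protein, feat.locus_tag)
        if not query:
            continue
        scores = [(float(aligner.score(query, ref_seq)), ref, ref_seq)
                  for ref, ref_seq in clean_refs]
        best_raw = max(s for s, _, _ in scores)
        if evalue(best_raw, len(query), db_len) >= thresholds.E_max:
            continue
        # full alignments only for top-scoring families (ties included)
        candidates = []
        for raw, ref, ref_seq in scores:
            if raw < best_raw:
                continue
            aln = aligner.align(query, ref_seq)[0]
            matches, columns, r_start, r_end, _ = alignment_stats(aln)
            identity = 100.0 * matches / columns if columns else 0.0
            coverage = (r_end - r_start) / len(ref_seq)
            candidates.append((-identity, ref.family, coverage, raw))
        candidates.sort()
        neg_ident, family, coverage, raw = candidates[0]
        assignment = FamilyAssignment(
            locus_tag=feat.locus_tag,
            family=family,
            bit_score=bit_score(raw),
            evalue=evalue(raw, len(query), db_len),
            coverage=coverage,
            identity=-neg_ident,
        )
        if coverage > thresholds.C_min:
            accepted.append(assignment)
        else:
            fragments.append((feat, assignment))

    merged, used = _merge_split_genes(fragments, thresholds)
    accepted.extend(merged)
    leftovers = [(feat, asn) for feat, asn in fragments
                 if asn.locus_tag not in used]
    accepted.extend(_merge_edge_fragments(genome, leftovers, accepted,
                                          thresholds))
    accepted.sort(key=lambda a: (features[a.locus_tag].contig_id,
                                 features[a.locus_tag].start, a.locus_tag))
    return accepted


def _merge_split_genes(
    fragments: list[tuple[GeneFeature, FamilyAssignment]],
    thresholds: SearchThresholds,
) -> tuple[list[FamilyAssignment], set[str]]:
    """Merge same-family sub-coverage hits within ``split_gap`` on one contig.

    Each merged fragment is emitted as its own assignment (its locus is a
    real feature) carrying the combined coverage and the ``split`` flag.
    """
    by_key: dict[tuple[str, str], list[tuple[GeneFeature, FamilyAssignment]]] = {}
    for feat, asn in fragments:
        by_key.setdefault((feat.contig_id, asn.family), []).append((feat, asn))

    merged: list[FamilyAssignment] = []
    for group in by_key.values():
        group.sort(key=lambda pair: pair[0].start)
        run: list[tuple[GeneFeature, FamilyAssignment]] = []
        for feat, asn in group:
            if run and feat.start - run[-1][0].end > thresholds.split_gap:
                merged.extend(_emit_run(run, thresholds))
                run = []
            run.append((feat, asn))
        merged.extend(_emit_run(run, thresholds))
    return merged, {a.locus_tag for a in merged}


def _merge_edge_fragments(
    genome: AnnotatedGenome,
    leftovers: list[tuple[GeneFeature, FamilyAssignment]],
    accepted: list[FamilyAssignment],
    thresholds: SearchThresholds,
) -> list[FamilyAssignment]:
    """Merge same-family gene fragments stranded at different contig ends.

    Assembly breakpoints in MAGs cut genes across contig boundaries; the
    pieces appear as truncated same-family hits adjacent to a contig
    terminus.  Such pieces on at least two contigs are merged (combined
    coverage must still clear ``C_min``) and flagged ``split``.  Circular
    contigs have no termini and are exempt.
    """
    contig_len = {c.id: c.length for c in genome.contigs if not c.circular}
    feat_of = {f.locus_tag: f for f in genome.features}

    def at_edge(feat: GeneFeature) -> bool:
        length = contig_len.get(feat.contig_id)
        if length is None:
            return False
        return (feat.start < thresholds.split_gap
                or feat.end > length - thresholds.split_gap)

    pool: dict[str, list[tuple[FamilyAssignment, bool]]] = {}
    for feat, asn in leftovers:
        if at_edge(feat):
            pool.setdefault(asn.family, []).append((asn, True))
    for asn in accepted:
        if asn.coverage < 0.9 and not asn.split and at_edge(feat_of[asn.locus_tag]):
            pool.setdefault(asn.family, []).append((asn, False))

    new: list[FamilyAssignment] = []
    for family, items in sorted(pool.items()):
        contigs = {feat_of[asn.locus_tag].contig_id for asn, _ in items}
        if len(items) < 2 or len(contigs) < 2:
            continue
        combined = min(1.0, sum(asn.coverage for asn, _ in items))
        if combined <= thresholds.C_min:
            continue
        for asn, is_new in items:
            asn.split = True
            asn.coverage = combined
            if is_new:
                new.append(asn)
        logger.info("edge split-gene merge: %s across contigs %s", family,
                    sorted(contigs))
    return new


def _emit_run(run: list[tuple[GeneFeature, FamilyAssignment]],
              thresholds: SearchThresholds) -> list[FamilyAssignment]:
    if len(run) < 2:
        return []
    combined = min(1.0, sum(asn.coverage for _, asn in run))
    if combined <= thresholds.C_min:
        return []
    out = []
    for _, asn in run:
        out.append(FamilyAssignment(
            locus_tag=asn.locus_tag, family=asn.family,
            bit_score=asn.bit_score, evalue=asn.evalue,
            coverage=combined, identity=asn.identity, split=True))
    logger.info("split-gene merge: %s over loci %s (combined coverage %.2f)",
                out[0].family, [a.locus_tag for a in out], combined)
    return out


def build_presence_matrix(
    assignments_by_genome: dict[str, list[FamilyAssignment]],
    marker_set: Sequence[str] = None,
) -> PresenceMatrix:
    """Summarize per-genome family assignments into a presence matrix.

    Category markers (puf/puh/bch/crt) are satisfied by any family of that
    category; named markers by their family.  Scanned genomes never yield
    ``unknown`` — a marker without a qualifying assignment is ``absent``.
    """
    from .references import DEFAULT_MARKERS
    markers = list(marker_set) if marker_set else list(DEFAULT_MARKERS)
    if not markers:
        raise ValueError("marker_set must be non-empty")
    rows = {}
    for genome_id, assignments in assignments_by_genome.items():
        families = {a.family for a in assignments}
        categories = {a.category for a in assignments}
        row = {}
        for marker in markers:
            if marker in CATEGORY_MARKERS:
                hit = marker in categories
            else:
                hit = MARKER_FAMILY.get(marker, marker) in families
            row[marker] = PRESENT if hit else ABSENT
        rows[genome_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index", columns=markers)
    df.index.name = "genome_id"
    return PresenceMatrix(df)


def assignments_to_tsv(assignments: Sequence[FamilyAssignment], path) -> None:
    df = pd.DataFrame([vars(a) for a in assignments])
    df.to_csv(path, sep="\t", index=False)
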