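"""Pairwise comparison of photosynthesis gene clusters and genome regions.

Two layers of comparison:

* protein level — per-family global alignment identity between the gene
  complements of two clusters, with the strict ``>90%`` high-identity flag
  used when relating Gemmatimonadetes clusters to each other;
* nucleotide level — conserved synteny blocks between two sequences under
  two cutoff dialects: the cluster-scale dialect (identity > 70%, length
  > 500 bp) and the genome-scale dialect (identity > 80%, length > 2 kb).

Identity uses alignment columns (internal gaps included, terminal gaps
trimmed) as the denominator, matching common BLAST-style reporting.  Block
finding is exact k-mer anchoring (k = 11) on both strands, diagonal-wise
chaining, and per-block identity from a banded edit-distance alignment of
the paired spans — deterministic and desk-scale without an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import edlib

from .family_search import alignment_stats, make_aligner, sanitize_protein
from .pgc_detect import PGCandidate

HIGH_IDENTITY_CUTOFF = 90.0  # percent, strict

DIALECTS = {
    "pgc": {"min_identity": 70.0, "min_length": 500},
    "genome": {"min_identity": 80.0, "min_length": 2000},
}

_KMER = 11
_CHAIN_GAP = 300     # bp between anchors chained into one block
_DIAG_BAND = 30      # diagonal drift tolerated within a chain

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenePairIdentity:
    family: str
    identity: float          # percent
    aligned_length: int      # alignment columns, terminal gaps trimmed
    high_identity: bool

    def __post_init__(self) -> None:
        assert self.high_identity == (self.identity > HIGH_IDENTITY_CUTOFF)


@dataclass
class SyntenyBlock:
    a_span: tuple[int, int]
    b_span: tuple[int, int]
    identity: float          # percent
    length: int              # bp on sequence a
    orientation: str         # "same" | "inverted"


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Percent identity of a global protein alignment, terminal gaps trimmed.

    Returns (identity %, alignment columns).
    """
    aligner = make_aligner("global")
    aln = aligner.align(sanitize_protein(a), sanitize_protein(b))[0]
    matches, columns, _, _, _ = alignment_stats(aln)
    return (100.0 * matches / columns if columns else 0.0), columns


def pairwise_gene_identity(
    pgc_a: PGCandidate, pgc_b: PGCandidate
) -> tuple[list[GenePairIdentity], list[str]]:
    """Per-family protein identity between two clusters.

    Families present in both clusters are aligned globally (the longest
    protein per family represents split fragments); families present in
    only one are returned as the unpaired list.
    """
    prot_a = _best_protein_per_family(pgc_a)
    prot_b = _best_protein_per_family(pgc_b)
    shared = sorted(set(prot_a) & set(prot_b))
    unpaired = sorted(set(prot_a) ^ set(prot_b))
    pairs = []
    for family in shared:
        identity, columns = global_identity(prot_a[family], prot_b[family])
        pairs.append(GenePairIdentity(
            family=family, identity=identity, aligned_length=columns,
            high_identity=identity > HIGH_IDENTITY_CUTOFF))
    return pairs, unpaired


def _best_protein_per_family(pgc: PGCandidate) -> dict[str, str]:
    out: dict[str, str] = {}
    for feat, family in pgc.members:
        if feat.protein and len(feat.protein) > len(out.get(family, "")):
            out[family] = feat.protein
    return out


# --- nucleotide synteny blocks ----------------------------------------------

def synteny_blocks(seq_a: str, seq_b: str, dialect: str = "pgc") -> list[SyntenyBlock]:
    """Conserved blocks between two nucleotide sequences under a dialect.

    Blocks are maximal chains of exact k-mer anchors on a consistent
    diagonal; identity is recomputed over each chained span pair.  Blocks
    must clear the dialect's strict identity and length cutoffs and are
    greedily made non-overlapping on ``seq_a`` (longest first).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {list(DIALECTS)}")
    params = DIALECTS[dialect]
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a or not seq_b:
        return []

    candidates = []
    for chain in _chain_anchors(seq_a, seq_b):
        block = _evaluate_chain(seq_a, seq_b, chain, "same", len(seq_b))
        if block:
            candidates.append(block)
    rc_b = revcomp(seq_b)
    for chain in _chain_anchors(seq_a, rc_b):
        block = _evaluate_chain(seq_a, rc_b, chain, "inverted", len(seq_b))
        if block:
            candidates.append(block)

    passing = [b for b in candidates
               if b.identity > params["min_identity"]
               and b.length > params["min_length"]]
    return _non_overlapping_on_a(passing)


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if "N" not in kmer:
            index.setdefault(kmer, []).append(i)
    return index


def _chain_anchors(seq_a: str, seq_b: str) -> list[list[tuple[int, int]]]:
    """Group exact k-mer anchors into chains of consistent diagonal."""
    index_b = _kmer_index(seq_b, _KMER)
    anchors: list[tuple[int, int, int]] = []   # (diag, a_pos, b_pos)
    for i in range(len(seq_a) - _KMER + 1):
        kmer = seq_a[i:i + _KMER]
        if "N" in kmer:
            continue
        for j in index_b.get(kmer, ()):
            anchors.append((i - j, i, j))
    if not anchors:
        return []
    anchors.sort()

    chains: list[list[tuple[int, int]]] = []
    # bucket by diagonal band, then split on large positional gaps
    current: list[tuple[int, int, int]] = []
    for anchor in anchors:
        if current and (anchor[0] - current[0][0] > _DIAG_BAND):
            chains.extend(_split_on_gaps(current))
            current = []
        current.append(anchor)
    chains.extend(_split_on_gaps(current))
    return chains


def _split_on_gaps(bucket: list[tuple[int, int, int]]) -> list[list[tuple[int, int]]]:
    if not bucket:
        return []
    ordered = sorted((a, b) for _, a, b in bucket)
    chains: list[list[tuple[int, int]]] = [[ordered[0]]]
    for a_pos, b_pos in ordered[1:]:
        prev_a, prev_b = chains[-1][-1]
        if a_pos - prev_a <= _CHAIN_GAP and b_pos > prev_b - _KMER:
            chains[-1].append((a_pos, b_pos))
        else:
            chains.append([(a_pos, b_pos)])
    return chains


_XDROP = 12          # ungapped extension stops when score falls this far
_MATCH, _MISMATCH = 1, -2


def _extend_left(seq_a: str, seq_b: str, a: int, b: int) -> tuple[int, int]:
    best = score = 0
    best_off = 0
    off = 0
    while a - off > 0 and b - off > 0:
        off += 1
        score += _MATCH if seq_a[a - off] == seq_b[b - off] else _MISMATCH
        if score > best:
            best, best_off = score, off
        elif best - score > _XDROP:
            break
    return a - best_off, b - best_off


def _extend_right(seq_a: str, seq_b: str, a: int, b: int) -> tuple[int, int]:
    best = score = 0
    best_off = 0
    off = 0
    while a + off < len(seq_a) and b + off < len(seq_b):
        score += _MATCH if seq_a[a + off] == seq_b[b + off] else _MISMATCH
        off += 1
        if score > best:
            best, best_off = score, off
        elif best - score > _XDROP:
            break
    return a + best_off, b + best_off


def _evaluate_chain(seq_a: str, seq_b: str, chain: list[tuple[int, int]],
                    orientation: str, b_len: int) -> Optional[SyntenyBlock]:
    if not chain:
        return None
    a_start, b_start = _extend_left(seq_a, seq_b, chain[0][0], chain[0][1])
    a_end, b_end = _extend_right(seq_a, seq_b, chain[-1][0] + _KMER,
                                 chain[-1][1] + _KMER)
    if a_end - a_start < _KMER or b_end <= b_start:
        return None
    sub_a = seq_a[a_start:a_end]
    sub_b = seq_b[b_start:b_end]
    result = edlib.align(sub_a, sub_b, task="distance", mode="NW")
    columns = max(len(sub_a), len(sub_b))
    identity = 100.0 * (columns - result["editDistance"]) / columns
    if orientation == "inverted":
        # map coordinates on revcomp(b) back to the original b
        b_span = (b_len - b_end, b_len - b_start)
    else:
        b_span = (b_start, b_end)
    return SyntenyBlock(a_span=(a_start, a_end), b_span=b_span,
                        identity=identity, length=a_end - a_start,
                        orientation=orientation)


def _non_overlapping_on_a(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    blocks = sorted(blocks, key=lambda b: (-b.length, b.a_span, b.b_span))
    kept: list[SyntenyBlock] = []
    for block in blocks:
        if all(block.a_span[1] <= other.a_span[0]
               or block.a_span[0] >= other.a_span[1] for other in kept):
            kept.append(block)
    kept.sort(key=lambda b: b.a_span)
    return kept


def blocks_to_tsv(blocks: Sequence[SyntenyBlock], path) -> None:
    with open(path, "w") as fh:
        fh.write("a_start\ta_end\tb_start\tb_end\tidentity\tlength\torientation\n")
        for b in blocks:
            fh.write(f"{b.a_span[0]}\t{b.a_span[1]}\t{b.b_span[0]}\t"
                     f"{b.b_span[1]}\t{b.identity:.2f}\t{b.length}\t"
                     f"{b.orientation}\n")
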