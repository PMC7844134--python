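"""Sub-cluster architecture of photosynthesis gene clusters.

A PGC decomposes into six canonical multi-gene sub-clusters — bchP2G,
bchFNBHLM, lhaA-puhABC, pufBALMC, crtF-bchCXYZ and bchID — plus positionally
flexible singleton genes (acsF, bchO, puhE, and the ppsR/aerR regulators).
The *Gemmatimonas*-type architecture carries two diagnostic placement
markers: acsF sits between the bchFNBHLM and lhaA-puhABC sub-clusters, and
bchO between pufBALMC and crtF-bchCXYZ.  No known proteobacterial PGC shows
both placements together with the same sub-cluster order and orientations,
which makes the fingerprint usable for recognizing Gemmatimonadetes-type
clusters on metagenomic contigs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .pgc_detect import PGCandidate

#: canonical sub-cluster membership (single source of truth, configurable)
SUBCLUSTER_GENES: dict[str, tuple[str, ...]] = {
    "bchP2G": ("bchP", "idi", "bchG"),
    "bchFNBHLM": ("bchF", "bchN", "bchB", "bchH", "bchL", "bchM"),
    "lhaA-puhABC": ("lhaA", "puhA", "puhB", "puhC"),
    "pufBALMC": ("pufB", "pufA", "pufL", "pufM", "pufC"),
    "crtF-bchCXYZ": ("crtF", "bchC", "bchX", "bchY", "bchZ"),
    "bchID": ("bchI", "bchD"),
}

CANONICAL_BLOCKS = tuple(SUBCLUSTER_GENES)

#: singleton genes tracked by name; anything else non-canonical becomes "other"
SINGLETON_FAMILIES = ("acsF", "bchO", "ppsR", "aerR", "puhE")

_GENE_TO_BLOCK = {gene: block
                  for block, genes in SUBCLUSTER_GENES.items()
                  for gene in genes}


@dataclass
class SubClusterBlock:
    name: str                 # canonical block name, singleton family, or "other"
    orientation: str          # "forward" | "reverse"
    members: list[str]        # locus tags or family names, in genomic order

    def flipped(self) -> "SubClusterBlock":
        orient = "reverse" if self.orientation == "forward" else "forward"
        return SubClusterBlock(self.name, orient, list(reversed(self.members)))


@dataclass
class ArchitectureSignature:
    """Ordered, oriented sub-cluster blocks plus singleton placements."""

    blocks: list[SubClusterBlock] = field(default_factory=list)
    acsF_marker: bool = False
    bchO_marker: bool = False
    missing: set[str] = field(default_factory=set)

    @property
    def block_names(self) -> list[str]:
        return [b.name for b in self.blocks]

    def canonical_block_count(self) -> int:
        return sum(1 for b in self.blocks if b.name in SUBCLUSTER_GENES)

    def to_dict(self) -> dict:
        return {
            "blocks": [{"name": b.name, "orientation": b.orientation,
                        "members": b.members} for b in self.blocks],
            "acsF_marker": self.acsF_marker,
            "bchO_marker": self.bchO_marker,
            "missing": sorted(self.missing),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ArchitectureSignature":
        return cls(
            blocks=[SubClusterBlock(b["name"], b["orientation"],
                                    list(b["members"]))
                    for b in data["blocks"]],
            acsF_marker=data.get("acsF_marker", False),
            bchO_marker=data.get("bchO_marker", False),
            missing=set(data.get("missing", ())),
        )


def segment_subclusters(cluster: PGCandidate) -> ArchitectureSignature:
    """Segment a cluster's labelled genes into canonical blocks and singletons.

    Maximal runs of consecutive genes belonging to the same canonical
    sub-cluster form one block.  Genes outside every canonical sub-cluster
    become singleton blocks.  Hypothetical ORFs carry no family label, never
    appear among cluster members, and are therefore transparent.  The
    signature is canonicalized to the strand most genes point along, so a
    uniform strand flip plus coordinate reversal of the whole cluster leaves
    it unchanged.
    """
    labelled = [(family, feat.strand)
                for feat, family in cluster.members] if cluster else []
    return _segment(labelled)


def segment_families(families_strands: Sequence[tuple[str, str]]) -> ArchitectureSignature:
    """Segment a bare (family, strand) sequence; used by oracles and fixtures."""
    return _segment(list(families_strands))


def _segment(labelled: list[tuple[str, str]]) -> ArchitectureSignature:
    blocks: list[SubClusterBlock] = []
    run_block: str | None = None
    run: list[tuple[str, str]] = []

    def close_run() -> None:
        nonlocal run, run_block
        if run:
            blocks.append(_finish_block(run_block, run))
        run, run_block = [], None

    for family, strand in labelled:
        block = _GENE_TO_BLOCK.get(family)
        if block is None:
            close_run()
            name = family if family in SINGLETON_FAMILIES else "other"
            blocks.append(_finish_block(name, [(family, strand)]))
        elif block == run_block:
            run.append((family, strand))
        else:
            close_run()
            run_block = block
            run = [(family, strand)]
    close_run()

    sig = ArchitectureSignature(blocks=blocks)
    return _canonicalize(sig)


def _finish_block(name: str, members: list[tuple[str, str]]) -> SubClusterBlock:
    plus = sum(1 for _, strand in members if strand == "+")
    minus = len(members) - plus
    if plus > minus:
        orientation = "forward"
    elif minus > plus:
        orientation = "reverse"
    else:
        orientation = "forward" if members[0][1] == "+" else "reverse"
    return SubClusterBlock(name=name, orientation=orientation,
                           members=[fam for fam, _ in members])


def _canonicalize(sig: ArchitectureSignature) -> ArchitectureSignature:
    """Read the cluster along its majority strand."""
    forward = sum(len(b.members) for b in sig.blocks if b.orientation == "forward")
    reverse = sum(len(b.members) for b in sig.blocks if b.orientation == "reverse")
    if reverse > forward:
        sig.blocks = [b.flipped() for b in reversed(sig.blocks)]
    return sig


@dataclass
class MarkerResult:
    acsF_marker: bool
    bchO_marker: bool
    missing: set[str] = field(default_factory=set)

    def __iter__(self):
        return iter((self.acsF_marker, self.bchO_marker))


def marker_test(sig: ArchitectureSignature) -> MarkerResult:
    """Test the two Gemmatimonadetes-specific singleton placements.

    ``acsF_marker`` is true iff the acsF singleton lies between the
    bchFNBHLM and lhaA-puhABC blocks (in either reading direction) with no
    other canonical sub-cluster in between; ``bchO_marker`` analogously for
    pufBALMC / crtF-bchCXYZ.  A missing singleton or flanking block makes
    the marker false and is recorded in ``missing``.
    """
    missing: set[str] = set()
    acsF = _between(sig, "acsF", "bchFNBHLM", "lhaA-puhABC", missing)
    bchO = _between(sig, "bchO", "pufBALMC", "crtF-bchCXYZ", missing)
    sig.acsF_marker, sig.bchO_marker, sig.missing = acsF, bchO, missing
    return MarkerResult(acsF_marker=acsF, bchO_marker=bchO, missing=missing)


def _between(sig: ArchitectureSignature, singleton: str, left: str, right: str,
             missing: set[str]) -> bool:
    names = sig.block_names
    for required in (singleton, left, right):
        if required not in names:
            missing.add(required)
    if missing & {singleton, left, right}:
        return False
    i, j, k = (names.index(left), names.index(singleton), names.index(right))
    lo, hi = min(i, k), max(i, k)
    if not (lo < j < hi):
        return False
    between = names[lo + 1:hi]
    return all(n not in SUBCLUSTER_GENES or n == singleton for n in between
               if n != singleton)


def compare_architectures(a: ArchitectureSignature,
                          b: ArchitectureSignature) -> int:
    """Architecture distance between two signatures.

    distance = breakpoints between the shared-block orders
             + shared blocks whose orientation differs
             + blocks present in exactly one signature.

    Symmetric; zero iff the signatures agree in content, order and
    orientation.  The triangle inequality is not guaranteed.
    """
    order_a = _unique_block_order(a)
    order_b = _unique_block_order(b)
    shared = set(order_a) & set(order_b)
    only_one = len(set(order_a) ^ set(order_b))

    sa = [n for n in order_a if n in shared]
    sb = [n for n in order_b if n in shared]
    adjacency_b = {frozenset(pair) for pair in zip(sb, sb[1:])}
    breakpoints = sum(1 for pair in zip(sa, sa[1:])
                      if frozenset(pair) not in adjacency_b)

    orient_a = _orientations(a)
    orient_b = _orientations(b)
    flips = sum(1 for n in shared if orient_a[n] != orient_b[n])
    return breakpoints + flips + only_one


def _unique_block_order(sig: ArchitectureSignature) -> list[str]:
    seen: list[str] = []
    for name in sig.block_names:
        if name != "other" and name not in seen:
            seen.append(name)
    return seen


def _orientations(sig: ArchitectureSignature) -> dict[str, str]:
    out: dict[str, str] = {}
    for block in sig.blocks:
        out.setdefault(block.name, block.orientation)
    return out


# --- packaged reference architectures ---------------------------------------

def load_reference_architectures() -> dict[str, ArchitectureSignature]:
    """Packaged architectures: the Gemmatimonadetes template plus synthetic
    proteobacterial-style variants (plausible per-class permutations, not
    transcriptions of any particular genome)."""
    text = (resources.files("gemmapgc.data") / "reference_architectures.json"
            ).read_text()
    data = json.loads(text)
    return {name: _signature_from_layout(layout)
            for name, layout in data["architectures"].items()}


def _signature_from_layout(layout: list[list[str]]) -> ArchitectureSignature:
    """Build a signature from [[block_or_singleton, "+"|"-"], ...]."""
    labelled: list[tuple[str, str]] = []
    for name, strand in layout:
        if name in SUBCLUSTER_GENES:
            labelled.extend((gene, strand) for gene in SUBCLUSTER_GENES[name])
        else:
            labelled.append((name, strand))
    sig = segment_families(labelled)
    marker_test(sig)
    return sig
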