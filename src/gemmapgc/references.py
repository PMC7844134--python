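"""Packaged photosynthesis gene family reference set.

One representative protein per family.  The sequences shipped here are
*synthetic stand-ins*: deterministic pseudo-random proteins with realistic
lengths and amino-acid composition, generated once from a fixed internal
seed.  They play the role that curated reference proteins (e.g. from the
deposited *Gemmatimonas* annotations) would play in a production deployment:
every downstream test and simulation derives its planted proteins from this
same set, so family recovery, identity targeting and threshold behaviour are
exercised exactly as they would be with real references, without any
download.

Categories drive the aggregate presence columns (``puf``/``puh``/``bch``/
``crt``) and decide which families count as photosynthesis genes during
cluster chaining.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

# categories: bch, puf, puh, crt, regulatory, oxygen-marker, other
#
# acsF/bchE are the aerobic/anaerobic Mg-protoporphyrin IX monomethyl ester
# cyclases and both belong to the bacteriochlorophyll pathway; lhaA (LH1
# assembly) is grouped with the reaction-center assembly (puh) genes; idi
# sits in the bchP2G sub-cluster and is counted with the bch genes.
_FAMILY_TABLE: list[tuple[str, str, int]] = [
    # family, category, reference protein length (aa)
    ("bchP", "bch", 395),
    ("idi", "bch", 176),
    ("bchG", "bch", 304),
    ("bchF", "bch", 168),
    ("bchN", "bch", 430),
    ("bchB", "bch", 508),
    ("bchH", "bch", 590),
    ("bchL", "bch", 271),
    ("bchM", "bch", 228),
    ("acsF", "bch", 344),
    ("bchE", "bch", 555),
    ("bchO", "bch", 285),
    ("bchC", "bch", 315),
    ("bchX", "bch", 334),
    ("bchY", "bch", 486),
    ("bchZ", "bch", 470),
    ("bchI", "bch", 337),
    ("bchD", "bch", 580),
    ("lhaA", "puh", 388),
    ("puhA", "puh", 258),
    ("puhB", "puh", 214),
    ("puhC", "puh", 160),
    ("puhE", "puh", 245),
    ("pufB", "puf", 152),
    ("pufA", "puf", 160),
    ("pufL", "puf", 276),
    ("pufM", "puf", 307),
    ("pufC", "puf", 352),
    ("crtF", "crt", 287),
    ("ppsR", "regulatory", 462),
    ("aerR", "regulatory", 190),
    ("BphP", "oxygen-marker", 590),
    ("BphO", "oxygen-marker", 221),
    ("hemF", "other", 302),
    ("hemN", "other", 457),
    ("hemJ", "other", 168),
    ("hemG", "other", 181),
    ("RubisCO-like", "other", 432),
    ("rhodopsin-like", "other", 249),
]

FAMILY_CATEGORY: dict[str, str] = {fam: cat for fam, cat, _ in _FAMILY_TABLE}

#: categories whose members are chained into photosynthesis gene clusters
PGC_CATEGORIES = frozenset({"bch", "puf", "puh", "crt", "regulatory"})

#: marker columns of the default genome presence matrix
DEFAULT_MARKERS = ["puf", "puh", "bch", "acsF", "bchE", "hemF", "hemN",
                   "hemJ", "hemG", "BphP", "BphO", "RubisCO", "Rho-like"]

#: marker name -> family whose presence satisfies it (non-category markers)
MARKER_FAMILY = {
    "acsF": "acsF", "bchE": "bchE", "hemF": "hemF", "hemN": "hemN",
    "hemJ": "hemJ", "hemG": "hemG", "BphP": "BphP", "BphO": "BphO",
    "RubisCO": "RubisCO-like", "Rho-like": "rhodopsin-like",
}

CATEGORY_MARKERS = frozenset({"puf", "puh", "bch", "crt"})

_AA = "ACDEFGHIKLMNPQRSTVWY"
# Typical bacterial proteome amino-acid frequencies (rounded).
_AA_FREQ = np.array([
    0.089, 0.012, 0.054, 0.059, 0.040, 0.074, 0.022, 0.057, 0.046, 0.102,
    0.024, 0.041, 0.047, 0.039, 0.057, 0.060, 0.055, 0.070, 0.013, 0.032,
])
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_REFERENCE_SEED = 20210115  # fixed: the packaged set must never change


@dataclass(frozen=True)
class FamilyReference:
    """A reference protein for one photosynthesis-related gene family."""

    family: str
    category: str
    protein: str
    source: str = "synthetic"


def random_protein(rng: np.random.Generator, length: int) -> str:
    """A pseudo-random protein with typical amino-acid composition."""
    return "".join(rng.choice(list(_AA), size=length, p=_AA_FREQ))


def load_references() -> list[FamilyReference]:
    """The packaged reference set (synthetic stand-ins, deterministic)."""
    rng = np.random.default_rng(_REFERENCE_SEED)
    refs = []
    for family, category, length in _FAMILY_TABLE:
        refs.append(FamilyReference(
            family=family, category=category,
            protein=random_protein(rng, length), source="synthetic"))
    return refs


def reference_map() -> dict[str, FamilyReference]:
    return {r.family: r for r in load_references()}


def write_reference_fasta(path: Path | str) -> None:
    """Write the packaged set as protein FASTA with ``>family|source`` headers."""
    with open(path, "w") as fh:
        for ref in load_references():
            fh.write(f">{ref.family}|{ref.source}\n{ref.protein}\n")


def read_reference_fasta(path: Path | str) -> list[FamilyReference]:
    """Read a reference set from FASTA (``>family|source`` headers)."""
    refs = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    refs.append(_ref_from(header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        refs.append(_ref_from(header, "".join(chunks)))
    return refs


def _ref_from(header: str, protein: str) -> FamilyReference:
    family, _, source = header.partition("|")
    category = FAMILY_CATEGORY.get(family, "other")
    return FamilyReference(family=family, category=category,
                           protein=protein, source=source or "unknown")
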