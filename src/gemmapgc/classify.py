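"""Decision rules: CGB membership, oxygen lifestyle, taxonomic delimitation.

A genome belongs to the chlorophototrophic Gemmatimonadetes bacteria (CGB)
when it carries at least one puf gene, one puh gene and one bch gene.  The
oxygen-lifestyle rule exploits the aerobic/anaerobic enzyme dichotomy of the
bacteriochlorophyll pathway: absence of bchE (the anaerobic cyclase)
together with presence of the bacteriophytochrome pair BphP/BphO indicates
an aerobic anoxygenic phototroph, whereas bchE presence indicates a
microaerophilic lifestyle.  These are *indications*, not physiological
claims — the result classes are named accordingly, and absence-based calls
are downgraded to indeterminate for badly incomplete MAGs, where a missing
gene is weak evidence.

Taxonomic delimitation consumes pre-computed identity values: ANI with the
conventional 95-96% species band, and 16S rRNA identity with the 98.7%
species and 95% genus thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .genome_io import ABSENT, PRESENT, UNKNOWN

CGB = "CGB"
NON_CGB = "non-CGB"

AEROBIC = "aerobic-indicated"
MICROAEROPHILIC = "microaerophilic-indicated"
INDETERMINATE = "indeterminate"

SAME_SPECIES = "same species"
NEW_SPECIES_SAME_GENUS = "new species same genus"
NEW_GENUS = "new genus candidate"
CONFLICTING = "conflicting evidence"


@dataclass(frozen=True)
class OxygenRuleSet:
    require_absent: frozenset = frozenset({"bchE"})
    require_present: frozenset = frozenset({"BphP", "BphO"})
    completeness_floor: float = 75.0

    def __post_init__(self) -> None:
        if self.require_absent & self.require_present:
            raise ValueError("require_absent and require_present overlap")


@dataclass(frozen=True)
class TaxonomyThresholds:
    ani_species_low: float = 95.0
    ani_species_high: float = 96.0
    ssu_genus: float = 95.0
    ssu_species: float = 98.7

    def __post_init__(self) -> None:
        if self.ani_species_low > self.ani_species_high:
            raise ValueError("ANI band inverted")
        if self.ssu_genus >= self.ssu_species:
            raise ValueError("16S genus threshold must be below species threshold")


@dataclass
class ClassificationResult:
    genome_id: str
    cgb: str
    oxygen: str
    taxon: Optional[str] = None
    evidence: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"genome_id": self.genome_id, "cgb": self.cgb,
                "oxygen": self.oxygen, "taxon": self.taxon,
                "evidence": [list(pair) for pair in self.evidence]}


def _get(row, marker: str) -> str:
    if isinstance(row, pd.Series):
        if marker not in row.index:
            raise KeyError(f"missing marker column: {marker}")
        return row[marker]
    if marker not in row:
        raise KeyError(f"missing marker column: {marker}")
    return row[marker]


def classify_cgb(row) -> str:
    """CGB iff puf, puh and bch markers are all present (unknown counts as
    absent: conservative inclusion)."""
    states = {m: _get(row, m) for m in ("puf", "puh", "bch")}
    return CGB if all(s == PRESENT for s in states.values()) else NON_CGB


def classify_oxygen(row, completeness: Optional[float] = None,
                    rules: OxygenRuleSet = OxygenRuleSet()) -> str:
    """Oxygen-lifestyle indication from the bchE / BphP / BphO markers.

    aerobic-indicated   : every required-absent marker absent and every
                          required-present marker present;
    microaerophilic-indicated : any required-absent marker present;
    indeterminate       : anything else, and any absence-dependent call on a
                          genome below the completeness floor.
    """
    absent_states = {m: _get(row, m) for m in sorted(rules.require_absent)}
    present_states = {m: _get(row, m) for m in sorted(rules.require_present)}

    if any(s == PRESENT for s in absent_states.values()):
        return MICROAEROPHILIC

    all_absent = all(s == ABSENT for s in absent_states.values())
    all_present = all(s == PRESENT for s in present_states.values())
    if all_absent and all_present:
        # the call leans on an absence: weak evidence in an incomplete MAG
        if completeness is not None and completeness < rules.completeness_floor:
            return INDETERMINATE
        return AEROBIC
    return INDETERMINATE


def classify_genome_row(genome_id: str, row, completeness: Optional[float] = None,
                        rules: OxygenRuleSet = OxygenRuleSet()) -> ClassificationResult:
    """CGB + oxygen calls for one presence-matrix row, with an evidence trail."""
    consulted = ["puf", "puh", "bch", *sorted(rules.require_absent),
                 *sorted(rules.require_present)]
    evidence = [(m, _get(row, m)) for m in consulted]
    if completeness is not None:
        evidence.append(("completeness", f"{completeness:g}"))
    return ClassificationResult(
        genome_id=genome_id,
        cgb=classify_cgb(row),
        oxygen=classify_oxygen(row, completeness=completeness, rules=rules),
        evidence=evidence,
    )


def delimit_taxon(ani: Optional[float] = None,
                  ssu_identity: Optional[float] = None,
                  thresholds: TaxonomyThresholds = TaxonomyThresholds()) -> str:
    """Threshold-based rank call from ANI and/or 16S identity.

    ANI at or above the species band means same species; below the band,
    the 16S identity decides the genus question (above the genus threshold:
    new species in the same genus; at or below: new genus candidate; no 16S
    value: the genus is retained, as a new genus cannot be proposed without
    16S evidence).  ANI inside the band is ambiguous and resolves to
    "conflicting evidence" unless the 16S value corroborates one side.
    """
    t = thresholds
    if ani is None and ssu_identity is None:
        raise ValueError("at least one of ani, ssu_identity is required")

    if ani is not None:
        if ani >= t.ani_species_high:
            return SAME_SPECIES
        if ani < t.ani_species_low:
            return _genus_call(ssu_identity, t)
        # ANI inside the ambiguous band
        if ssu_identity is not None:
            if ssu_identity >= t.ssu_species:
                return SAME_SPECIES
            if ssu_identity > t.ssu_genus:
                return NEW_SPECIES_SAME_GENUS
        return CONFLICTING

    if ssu_identity >= t.ssu_species:
        return SAME_SPECIES
    return _genus_call(ssu_identity, t)


def _genus_call(ssu_identity: Optional[float], t: TaxonomyThresholds) -> str:
    if ssu_identity is None or ssu_identity > t.ssu_genus:
        return NEW_SPECIES_SAME_GENUS
    return NEW_GENUS
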