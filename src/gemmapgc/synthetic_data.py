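"""Synthetic annotated genomes with known ground truth.

The generator plants a *Gemmatimonas*-type photosynthesis gene cluster —
the canonical six sub-clusters, the diagnostic acsF/bchO singleton
placements, regulators, and intervening hypothetical ORFs — into a
background of non-photosynthesis genes, then emits GFF3/FASTA exactly as
the readers expect.  Planted proteins are the packaged reference proteins
mutated by BLOSUM62-positive substitution sampling to a controlled target
identity; coding sequences are back-translated with the bacterial codon
table (uniform synonymous choice).  MAG-like inputs are produced by cutting
a genome at random breakpoints and dropping pieces to a target
completeness, with genes cut by a breakpoint annotated as split fragments.

Everything is deterministic given the seed, and every emitted genome comes
with a :class:`GroundTruth` record naming the planted genes, architecture
and realized identities, so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .family_search import SearchThresholds, assign_families, evalue as _evalue, make_aligner, sanitize_protein
from .genome_io import AnnotatedGenome, Contig, GeneFeature
from .references import FamilyReference, load_references, random_protein

#: gene-level layout of the Gemmatimonadetes-type cluster (family, strand);
#: ``None`` marks a hypothetical ORF slot (here: between the puh and puf operons)
GEMMA_TEMPLATE: tuple[tuple[Optional[str], str], ...] = (
    ("aerR", "-"), ("ppsR", "-"),
    ("bchP", "+"), ("idi", "+"), ("bchG", "+"),
    ("bchF", "+"), ("bchN", "+"), ("bchB", "+"), ("bchH", "+"),
    ("bchL", "+"), ("bchM", "+"),
    ("acsF", "+"),
    ("lhaA", "+"), ("puhA", "+"), ("puhB", "+"), ("puhC", "+"),
    ("puhE", "+"),
    (None, "+"), (None, "-"), (None, "+"),
    ("pufB", "+"), ("pufA", "+"), ("pufL", "+"), ("pufM", "+"), ("pufC", "+"),
    ("bchO", "+"),
    ("crtF", "-"), ("bchC", "-"), ("bchX", "-"), ("bchY", "-"), ("bchZ", "-"),
    ("bchI", "-"), ("bchD", "-"),
)

_BACKGROUND_LEN_RANGE = (200, 1500)   # codons
_HYP_LEN_RANGE = (80, 200)            # codons
_MIN_FRAGMENT_AA = 15
_GC = 0.65
_NT = np.array(list("ACGT"))
_NT_P = np.array([(1 - _GC) / 2, _GC / 2, _GC / 2, (1 - _GC) / 2])


@dataclass
class SimulationSpec:
    """Controls for one simulated genome."""

    seed: int = 0
    architecture: Sequence[tuple[Optional[str], str]] = GEMMA_TEMPLATE
    target_protein_identity: float = 0.75
    intergenic_gap_range: tuple[int, int] = (50, 500)
    n_background_genes: int = 10
    #: marker genes planted outside the cluster; the default emulates an
    #: aerobic chlorophototroph (bacteriophytochrome pair present, no bchE)
    extra_families: tuple[str, ...] = ("BphP", "BphO")
    circular: bool = False
    split_genes: frozenset = frozenset()   # families planted as 2 partial CDS
    fragmentation: Optional[tuple[float, int]] = None  # (completeness, n_contigs)
    genome_id: str = "sim"

    def __post_init__(self) -> None:
        if not (0 <= self.target_protein_identity <= 1):
            raise ValueError("target_protein_identity outside [0, 1]")
        if self.target_protein_identity < 0.2:
            raise ValueError("identity target < 0.2 is unsatisfiable for "
                             "substitution-only mutation")
        lo, hi = self.intergenic_gap_range
        if not (0 < lo <= hi):
            raise ValueError("intergenic gap range must be positive")


@dataclass
class PlantedGene:
    locus_tag: str
    family: Optional[str]     # None for hypothetical/background ORFs
    kind: str                 # "cluster" | "hypothetical" | "background"
    contig_id: str
    start: int
    end: int
    strand: str
    realized_identity: Optional[float] = None
    split: bool = False


@dataclass
class GroundTruth:
    genome_id: str
    genes: list[PlantedGene] = field(default_factory=list)
    architecture: list[tuple[Optional[str], str]] = field(default_factory=list)
    target_identity: float = 1.0
    completeness: float = 100.0
    retained_families: set[str] = field(default_factory=set)

    @property
    def cluster_families(self) -> set[str]:
        return {g.family for g in self.genes if g.kind == "cluster" and g.family}

    def to_json(self, path: Path | str) -> None:
        data = {
            "genome_id": self.genome_id,
            "target_identity": self.target_identity,
            "completeness": self.completeness,
            "architecture": [[f, s] for f, s in self.architecture],
            "retained_families": sorted(self.retained_families),
            "genes": [vars(g) for g in self.genes],
        }
        Path(path).write_text(json.dumps(data, indent=1))


# --- protein mutation and back-translation ----------------------------------

def _positive_exchanges() -> dict[str, str]:
    """For each residue, the residues it exchanges with at positive BLOSUM62
    score (excluding itself)."""
    matrix = substitution_matrices.load("BLOSUM62")
    aa = "ACDEFGHIKLMNPQRSTVWY"
    out = {}
    for a in aa:
        partners = [b for b in aa if b != a and matrix[a][b] > 0]
        out[a] = "".join(partners) if partners else aa.replace(a, "")
    return out


_POSITIVE = _positive_exchanges()


def mutate_protein(rng: np.random.Generator, protein: str,
                   target_identity: float) -> tuple[str, float]:
    """Substitute residues (BLOSUM62-positive exchanges) down to the target
    global identity; substitution-only, so realized identity is exact."""
    length = len(protein)
    n_mut = int(round((1 - target_identity) * length))
    n_mut = min(n_mut, length)
    positions = rng.choice(length, size=n_mut, replace=False)
    residues = list(protein)
    for pos in positions:
        choices = _POSITIVE.get(residues[pos], "A")
        residues[pos] = choices[rng.integers(len(choices))]
    realized = 1 - n_mut / length
    return "".join(residues), realized


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    out["*"] = sorted(table.stop_codons)
    return out


_CODONS = _codon_map()


def back_translate(rng: np.random.Generator, protein: str) -> str:
    """Protein -> CDS with stop codon, uniform synonymous codon choice."""
    parts = []
    for aa in protein + "*":
        codons = _CODONS[aa]
        parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length, p=_NT_P))


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _nonsignificant_protein(rng: np.random.Generator, length: int,
                            refs: Sequence[FamilyReference],
                            thresholds: SearchThresholds) -> str:
    """Rejection-sample a random ORF with no significant hit to any reference."""
    aligner = make_aligner("local")
    db_len = sum(len(r.protein) for r in refs)
    for _ in range(50):
        candidate = random_protein(rng, length)
        best = max(float(aligner.score(candidate, sanitize_protein(r.protein)))
                   for r in refs)
        if _evalue(best, length, db_len) >= thresholds.E_max:
            return candidate
    raise RuntimeError("could not sample a non-significant background ORF")


# --- genome assembly ---------------------------------------------------------

def simulate_genome(
    spec: SimulationSpec,
    refs: Optional[Sequence[FamilyReference]] = None,
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Emit one annotated genome with a planted cluster and ground truth."""
    rng = np.random.default_rng(spec.seed)
    refs = list(refs) if refs is not None else load_references()
    ref_by_family = {r.family: r for r in refs}
    thresholds = SearchThresholds()

    n_bg = spec.n_background_genes
    n_before = n_bg // 2
    contig_id = f"{spec.genome_id}_ctg1"

    chunks: list[str] = []
    features: list[GeneFeature] = []
    planted: list[PlantedGene] = []
    cursor = 0
    counter = {"bg": 0, "hyp": 0}

    def gap() -> None:
        nonlocal cursor
        lo, hi = spec.intergenic_gap_range
        length = int(rng.integers(lo, hi + 1))
        chunks.append(_random_dna(rng, length))
        cursor += length

    def place(protein: str, strand: str, locus: str,
              family: Optional[str], kind: str, symbol: Optional[str],
              realized: Optional[float], split: bool = False) -> None:
        nonlocal cursor
        cds = back_translate(rng, protein)
        genomic = cds.translate(_REVCOMP)[::-1] if strand == "-" else cds
        start, end = cursor, cursor + len(genomic)
        chunks.append(genomic)
        cursor = end
        features.append(GeneFeature(contig_id=contig_id, start=start, end=end,
                                    strand=strand, locus_tag=locus,
                                    declared_symbol=symbol, protein=protein))
        planted.append(PlantedGene(locus_tag=locus, family=family, kind=kind,
                                   contig_id=contig_id, start=start, end=end,
                                   strand=strand, realized_identity=realized,
                                   split=split))

    def place_background() -> None:
        counter["bg"] += 1
        length = int(rng.integers(*_BACKGROUND_LEN_RANGE))
        protein = _nonsignificant_protein(rng, length, refs, thresholds)
        strand = "+" if rng.integers(2) else "-"
        gap()
        place(protein, strand, f"bg_{counter['bg']:03d}", None, "background",
              None, None)

    for _ in range(n_before):
        place_background()

    cluster_index = 0
    for family, strand in spec.architecture:
        gap()
        if family is None:
            counter["hyp"] += 1
            length = int(rng.integers(*_HYP_LEN_RANGE))
            protein = _nonsignificant_protein(rng, length, refs, thresholds)
            place(protein, strand, f"hyp_{counter['hyp']:02d}", None,
                  "hypothetical", None, None)
            continue
        cluster_index += 1
        reference = ref_by_family[family]
        mutated, realized = mutate_protein(rng, reference.protein,
                                           spec.target_protein_identity)
        locus = f"pgc_{cluster_index:03d}_{family}"
        if family in spec.split_genes:
            # annotation-level split: two partial CDS, each below the
            # coverage threshold alone, jointly above it
            length = len(mutated)
            cut = int(0.38 * length)
            halves = [mutated[:cut], mutated[-cut:]]
            for i, half in enumerate(halves, start=1):
                if i > 1:
                    gap()
                place(half, strand, f"{locus}_f{i}", family, "cluster",
                      family, realized, split=True)
        else:
            place(mutated, strand, locus, family, "cluster", family, realized)

    for i, family in enumerate(spec.extra_families, start=1):
        gap()
        reference = ref_by_family[family]
        mutated, realized = mutate_protein(rng, reference.protein,
                                           spec.target_protein_identity)
        strand = "+" if rng.integers(2) else "-"
        place(mutated, strand, f"mk_{i:02d}_{family}", family, "marker",
              family, realized)

    for _ in range(n_bg - n_before):
        place_background()
    gap()

    sequence = "".join(chunks)
    genome = AnnotatedGenome(
        genome_id=spec.genome_id,
        contigs=[Contig(id=contig_id, length=len(sequence),
                        circular=spec.circular, sequence=sequence)],
        features=features,
        completeness=100.0,
    )
    truth = GroundTruth(
        genome_id=spec.genome_id,
        genes=planted,
        architecture=list(spec.architecture),
        target_identity=spec.target_protein_identity,
        completeness=100.0,
        retained_families={g.family for g in planted if g.family},
    )
    if spec.fragmentation is not None:
        completeness, n_contigs = spec.fragmentation
        genome, truth = fragment_to_mag(genome, truth, completeness,
                                        n_contigs, seed=spec.seed + 1)
    return genome, truth


def rotate_genome(genome: AnnotatedGenome, truth: GroundTruth,
                  offset: int) -> tuple[AnnotatedGenome, GroundTruth]:
    """Rotate a single circular contig's origin by ``offset`` bp.

    Features crossing the new origin are dropped (a rotation point inside a
    gene would need a wrapped feature representation); callers rotate at
    intergenic positions to keep the full gene complement.
    """
    (contig,) = genome.contigs
    length = contig.length
    offset %= length
    sequence = (contig.sequence[offset:] + contig.sequence[:offset]
                if contig.sequence else None)
    features = []
    truth_genes = []
    for feat, gene in zip(genome.features, truth.genes):
        start = (feat.start - offset) % length
        end = start + feat.length
        if end > length:
            continue
        features.append(replace(feat, start=start, end=end))
        truth_genes.append(replace(gene, start=start, end=end))
    rotated = AnnotatedGenome(
        genome_id=genome.genome_id,
        contigs=[Contig(id=contig.id, length=length, circular=contig.circular,
                        sequence=sequence)],
        features=features,
        completeness=genome.completeness,
    )
    new_truth = replace(truth, genes=truth_genes)
    return rotated, new_truth


# --- MAG-style fragmentation -------------------------------------------------

def fragment_to_mag(
    genome: AnnotatedGenome,
    truth: GroundTruth,
    completeness: float,
    n_contigs: int,
    seed: int,
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Cut a genome into pieces and drop pieces to a target completeness.

    Breakpoints are uniform over the genome; pieces are retained in random
    order until the retained length is as close as possible to
    ``completeness`` x genome length.  Genes cut by a breakpoint are kept as
    annotated split fragments on both sides (same family, ``_f1``/``_f2``
    locus suffixes) when the in-frame remainder is long enough.
    """
    if not (0 < completeness <= 1):
        raise ValueError("completeness must be in (0, 1]")
    rng = np.random.default_rng(seed)
    total = sum(c.length for c in genome.contigs)

    # global breakpoints -> per-contig cut positions
    n_breaks = max(n_contigs - 1, 0)
    breaks = sorted(rng.choice(np.arange(1, total), size=n_breaks,
                               replace=False)) if n_breaks else []
    pieces: list[tuple[str, int, int]] = []
    offset = 0
    for contig in genome.contigs:
        local = [b - offset for b in breaks if offset < b < offset + contig.length]
        bounds = [0, *local, contig.length]
        for lo, hi in zip(bounds, bounds[1:]):
            pieces.append((contig.id, lo, hi))
        offset += contig.length

    order = rng.permutation(len(pieces))
    lengths = np.array([pieces[i][2] - pieces[i][1] for i in order])
    cumulative = np.cumsum(lengths)
    target = completeness * total
    k = int(np.argmin(np.abs(cumulative - target))) + 1
    kept_idx = sorted(order[:k], )
    kept = [pieces[i] for i in kept_idx]
    retained_len = int(cumulative[k - 1])

    contig_seq = {c.id: c.sequence for c in genome.contigs}
    new_contigs: list[Contig] = []
    new_features: list[GeneFeature] = []
    new_genes: list[PlantedGene] = []
    gene_by_locus = {g.locus_tag: g for g in truth.genes}

    for piece_no, (cid, lo, hi) in enumerate(kept, start=1):
        new_cid = f"{genome.genome_id}_mag_{piece_no:03d}"
        seq = contig_seq[cid][lo:hi] if contig_seq[cid] else None
        new_contigs.append(Contig(id=new_cid, length=hi - lo, circular=False,
                                  sequence=seq))
        for feat in genome.features_on(cid):
            if feat.end <= lo or feat.start >= hi:
                continue
            clipped = _clip_feature(feat, lo, hi, new_cid)
            if clipped is None:
                continue
            new_feat, was_cut = clipped
            new_features.append(new_feat)
            old = gene_by_locus.get(feat.locus_tag)
            if old is not None:
                new_genes.append(replace(
                    old, locus_tag=new_feat.locus_tag, contig_id=new_cid,
                    start=new_feat.start, end=new_feat.end,
                    split=old.split or was_cut))

    retained_families = {g.family for g in new_genes if g.family}
    mag = AnnotatedGenome(
        genome_id=f"{genome.genome_id}_mag",
        contigs=new_contigs,
        features=new_features,
        completeness=100.0 * retained_len / total,
    )
    new_truth = GroundTruth(
        genome_id=mag.genome_id,
        genes=new_genes,
        architecture=truth.architecture,
        target_identity=truth.target_identity,
        completeness=100.0 * retained_len / total,
        retained_families=retained_families,
    )
    return mag, new_truth


def _clip_feature(feat: GeneFeature, lo: int, hi: int,
                  new_cid: str) -> Optional[tuple[GeneFeature, bool]]:
    start = max(feat.start, lo)
    end = min(feat.end, hi)
    left_cut = start - feat.start
    right_cut = feat.end - end
    was_cut = left_cut > 0 or right_cut > 0
    locus = feat.locus_tag
    protein = feat.protein
    if was_cut and protein:
        if feat.strand == "+":
            head_nt, tail_nt = left_cut, right_cut
        else:
            head_nt, tail_nt = right_cut, left_cut
        aa_start = (head_nt + 2) // 3
        coding_nt = 3 * (len(protein) + 1)
        aa_end = min((coding_nt - tail_nt) // 3, len(protein))
        if aa_end - aa_start < _MIN_FRAGMENT_AA:
            return None
        protein = protein[aa_start:aa_end]
        locus = f"{locus}_f1" if left_cut else f"{locus}_f2"
    elif was_cut:
        return None
    return GeneFeature(contig_id=new_cid, start=start - lo, end=end - lo,
                       strand=feat.strand, locus_tag=locus,
                       declared_symbol=feat.declared_symbol,
                       protein=protein), was_cut


# --- retention scoring -------------------------------------------------------

def retained_gene_fraction(original: GroundTruth, mag: GroundTruth) -> float:
    """Fraction of originally planted genes retained (>= half their length)."""
    kept_len: dict[str, int] = {}
    for gene in mag.genes:
        base = gene.locus_tag.rsplit("_f", 1)[0] if gene.split else gene.locus_tag
        kept_len[base] = kept_len.get(base, 0) + (gene.end - gene.start)
    n_kept = sum(1 for g in original.genes
                 if kept_len.get(g.locus_tag, 0) >= (g.end - g.start) / 2)
    return n_kept / len(original.genes)


# --- published-table fixtures -------------------------------------------------

def fixture_path(name: str) -> Path:
    return Path(str(resources.files("gemmapgc.data") / name))


def package_fixtures(out_dir: Path | str) -> list[Path]:
    """Copy the packaged table fixtures (gene presence/absence per genome)
    into ``out_dir``; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in ("table3_key_genes.tsv", "table3_genome_stats.tsv",
                 "table2_gene_presence.tsv"):
        text = (resources.files("gemmapgc.data") / name).read_text()
        target = out_dir / name
        target.write_text(text)
        written.append(target)
    return written
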