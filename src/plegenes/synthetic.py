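"""Synthetic PLE-like gene clusters, BAC clone sets and pooled-library layouts.

Every downstream stage of the pipeline (spliced annotation, inverted-repeat
detection, clone ordering, isoform classification, screening simulation) is
tested against loci generated here, where the ground truth is known exactly.

The generator emulates the published architecture of the pig liver esterase
(PLE) locus:

* genes of 14 exons / 13 introns with the bundled per-gene exon and intron
  sizes; every intron starts ``GT`` and ends ``AG``;
* a 6,000-bp upstream regulatory region per gene carrying a planted pair of
  720-bp reverse-complement (inverted repeat) copies at promoter positions
  -5132..-4413 and -802..-83 (+1 is the A of the start codon; there is no
  position 0);
* ~22-kb random intergenic spacers between genes;
* coding sequences realizing the bundled diagnostic-residue profile of each
  isoenzyme, a shared 18-residue signal peptide and a C-terminal HAEL
  ER-retention signal;
* screening primer-pair binding-site cassettes planted inside introns so
  that in-silico PCR yields the expected product sizes;
* BAC clones cut from the locus with a vector stand-in prepended, and
  384-well library plates whose non-positive wells are guaranteed free of
  primer binding sites.

Base composition is uniform i.i.d. ACGT except at forced motifs. All output
is a deterministic function of the spec and its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from . import tables
from ._util import (
    CODONS_FOR_AA,
    codons_for,
    complement,
    random_dna,
    random_protein,
    revcomp,
    stable_rng,
    translate,
)
from .errors import InvalidSpecError
from .models import GeneModel

DEFAULT_SEED = 1063

#: fixed 18-residue signal peptide shared by all generated isoforms
SIGNAL_PEPTIDE = "MWLRAFILATLSASHAQE"

#: C-terminal ER retention signal
ER_RETENTION = "HAEL"

_STOPS = ("TAA", "TAG", "TGA")


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatPlantSpec:
    """Where and how the inverted-repeat pair is planted in each promoter.

    Coordinates are signed promoter positions (+1 = A of ATG, no position 0).
    ``copy1_start``/``copy2_start`` are the 5'-most bases of the two copies;
    both copies have the same ``length`` and copy1 is the exact reverse
    complement of copy2 at planting time.
    """

    length: int = 720
    copy1_start: int = -5132
    copy2_start: int = -802
    max_mismatches: int = 0

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        c1 = (self.copy1_start, self.copy1_start + self.length - 1)
        c2 = (self.copy2_start, self.copy2_start + self.length - 1)
        return c1, c2

    def validate(self, promoter_len: int) -> None:
        if self.length < 1:
            raise InvalidSpecError("repeat length must be >= 1")
        if self.max_mismatches < 0:
            raise InvalidSpecError("max_mismatches must be >= 0")
        (s1, e1), (s2, e2) = self.intervals()
        for s, e in ((s1, e1), (s2, e2)):
            if s < -promoter_len or e > -1:
                raise InvalidSpecError(
                    f"repeat copy ({s}..{e}) outside promoter [-{promoter_len}, -1]"
                )
        if e1 >= s2:
            raise InvalidSpecError("repeat copies must not overlap (copy1 before copy2)")


@dataclass(frozen=True)
class PrimerPlantSpec:
    """Which primer-pair cassettes are planted inside each gene's introns.

    ``products`` maps primer-pair id to the product size(s) to realize; pairs
    printed with two product sizes alternate between them along the gene
    order, which is what makes pooled PCR see two band sizes. Cassettes are
    placed greedily into the first intron with room, never touching the
    GT/AG dinucleotides.
    """

    products: Mapping[int, tuple[int, ...]] = field(
        default_factory=lambda: {
            1: (208,),
            2: (534,),
            4: (2327, 3811),
            5: (1540, 3558),
            6: (1869, 1213),
        }
    )

    def product_for(self, pair_id: int, gene_index: int) -> int:
        sizes = self.products[pair_id]
        return sizes[gene_index % len(sizes)]


@dataclass(frozen=True)
class SyntheticClusterSpec:
    """Full parameterization of a generated PLE-like locus."""

    gene_order: tuple[str, ...] = ("PLE-G2", "PLE-1", "PLE-B9")
    exon_sizes: tuple[int, ...] = field(default_factory=tables.exon_sizes)
    intron_sizes: Mapping[str, tuple[int, ...]] | None = None
    intergenic_len: int = 22000
    promoter_len: int = 6000
    downstream_len: int = 200
    repeat_plant: RepeatPlantSpec = field(default_factory=RepeatPlantSpec)
    primer_plant: PrimerPlantSpec = field(default_factory=PrimerPlantSpec)
    strands: Mapping[str, str] = field(default_factory=dict)
    point_mutation_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def introns_for(self, gene_id: str) -> tuple[int, ...]:
        if self.intron_sizes and gene_id in self.intron_sizes:
            return tuple(self.intron_sizes[gene_id])
        return tables.intron_sizes(gene_id)

    def strand_for(self, gene_id: str) -> str:
        return self.strands.get(gene_id, "+")

    def validate(self) -> None:
        if not self.gene_order:
            raise InvalidSpecError("gene_order must contain at least one gene")
        if len(set(self.gene_order)) != len(self.gene_order):
            raise InvalidSpecError("gene_order contains duplicates")
        if any(s < 1 for s in self.exon_sizes):
            raise InvalidSpecError("exon sizes must be >= 1")
        for gid in self.gene_order:
            introns = self.introns_for(gid)
            if len(self.exon_sizes) != len(introns) + 1:
                raise InvalidSpecError(
                    f"{gid}: need len(exon_sizes) == len(intron_sizes) + 1"
                )
            if any(i < 4 for i in introns):
                raise InvalidSpecError(f"{gid}: introns must be >= 4 nt to hold GT..AG")
        if not (0.0 <= self.point_mutation_rate <= 0.05):
            raise InvalidSpecError("point_mutation_rate must be in [0, 0.05]")
        if self.promoter_len < 0 or self.intergenic_len < 0 or self.downstream_len < 0:
            raise InvalidSpecError("lengths must be non-negative")
        if self.promoter_len:
            self.repeat_plant.validate(self.promoter_len)
        for gid, s in dict(self.strands).items():
            if s not in "+-":
                raise InvalidSpecError(f"{gid}: strand must be '+' or '-'")


@dataclass(frozen=True)
class LibraryLayoutSpec:
    """Geometry of the pooled BAC library (plates x 16 rows x 24 columns)."""

    n_plates: int = 500
    rows: int = 16
    cols: int = 24
    positives: tuple[tuple[int, int, int, str], ...] = ()
    decoy_insert_len: int = 1000

    def validate(self) -> None:
        if self.n_plates < 1 or self.rows < 1 or self.cols < 1:
            raise InvalidSpecError("library geometry must be positive")
        seen = set()
        for plate, row, col, _key in self.positives:
            if not (1 <= plate <= self.n_plates and 1 <= row <= self.rows and 1 <= col <= self.cols):
                raise InvalidSpecError(f"positive well ({plate},{row},{col}) outside layout")
            if (plate, row, col) in seen:
                raise InvalidSpecError(f"duplicate positive well ({plate},{row},{col})")
            seen.add((plate, row, col))

    @property
    def wells_per_plate(self) -> int:
        return self.rows * self.cols


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerSiteTruth:
    pair_id: int
    start: int  # contig coords, 1-based inclusive, whole cassette
    end: int
    product_len: int


@dataclass(frozen=True)
class GeneTruth:
    """Everything the generator knows about one planted gene.

    Intervals are 1-based inclusive contig coordinates; ``cdna`` is the
    pre-mutation reference coding sequence (the annotation reference), while
    ``cds`` is the realized, possibly mutated, genomic coding sequence read
    on the gene strand.
    """

    gene_id: str
    strand: str
    unit_span: tuple[int, int]
    promoter: tuple[int, int] | None
    exons: tuple[tuple[int, int], ...]
    introns: tuple[tuple[int, int], ...]
    repeat_copies: tuple[tuple[int, int], tuple[int, int]] | None
    repeat_promoter_coords: tuple[tuple[int, int], tuple[int, int]] | None
    primer_sites: tuple[PrimerSiteTruth, ...]
    cdna: str
    cds: str

    @property
    def protein(self) -> str:
        return translate(self.cds).rstrip("*")

    def exon_sizes(self) -> tuple[int, ...]:
        sizes = tuple(e - s + 1 for s, e in self.exons)
        return sizes if self.strand == "+" else sizes[::-1]

    def intron_sizes(self) -> tuple[int, ...]:
        sizes = tuple(e - s + 1 for s, e in self.introns)
        return sizes if self.strand == "+" else sizes[::-1]

    def shifted(self, offset: int) -> "GeneTruth":
        def sh(iv):
            return (iv[0] + offset, iv[1] + offset)

        return replace(
            self,
            unit_span=sh(self.unit_span),
            promoter=sh(self.promoter) if self.promoter else None,
            exons=tuple(sh(iv) for iv in self.exons),
            introns=tuple(sh(iv) for iv in self.introns),
            repeat_copies=(
                tuple(sh(iv) for iv in self.repeat_copies) if self.repeat_copies else None
            ),
            primer_sites=tuple(
                replace(p, start=p.start + offset, end=p.end + offset)
                for p in self.primer_sites
            ),
        )

    def flipped(self) -> "GeneTruth":
        """Mirror all coordinates for a gene placed on the minus strand."""
        length = self.unit_span[1] - self.unit_span[0] + 1

        def fl(iv):
            return (length - iv[1] + 1, length - iv[0] + 1)

        return replace(
            self,
            strand="-" if self.strand == "+" else "+",
            unit_span=(1, length),
            promoter=fl(self.promoter) if self.promoter else None,
            exons=tuple(sorted(fl(iv) for iv in self.exons)),
            introns=tuple(sorted(fl(iv) for iv in self.introns)),
            repeat_copies=(
                tuple(sorted(fl(iv) for iv in self.repeat_copies))
                if self.repeat_copies
                else None
            ),
            primer_sites=tuple(
                replace(p, start=length - p.end + 1, end=length - p.start + 1)
                for p in self.primer_sites
            ),
        )

    def to_model(self, contig_id: str = "locus") -> GeneModel:
        return GeneModel(
            contig_id=contig_id,
            strand=self.strand,
            exons=self.exons,
            cdna_id=f"{self.gene_id}_cdna",
            alignment_score=0,
            mismatch_count=0,
            cds_sequence=self.cds,
            name=self.gene_id,
        )


@dataclass(frozen=True)
class ClusterTruth:
    spec: SyntheticClusterSpec
    locus_len: int
    genes: tuple[GeneTruth, ...]

    @property
    def gene_order(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in sorted(self.genes, key=lambda g: g.exons[0][0]))

    def gene(self, gene_id: str) -> GeneTruth:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass(frozen=True)
class CloneTruth:
    name: str
    window: tuple[int, int]  # locus coords of insert, 1-based inclusive
    vector_len: int
    insert_len: int


@dataclass(frozen=True)
class CloneSetTruth:
    clones: tuple[CloneTruth, ...]

    def overlap(self, name_a: str, name_b: str) -> int:
        """Intersection length of two clone windows on the master locus."""
        a = next(c for c in self.clones if c.name == name_a)
        b = next(c for c in self.clones if c.name == name_b)
        lo = max(a.window[0], b.window[0])
        hi = min(a.window[1], b.window[1])
        return max(0, hi - lo + 1)


@dataclass
class Library:
    """A pooled 384-well library: well -> template sequence, plus truth."""

    layout: LibraryLayoutSpec
    wells: dict
    positives: tuple[tuple[int, int, int, str], ...]

    def plate_wells(self, plate: int):
        return [
            (plate, r, c)
            for r in range(1, self.layout.rows + 1)
            for c in range(1, self.layout.cols + 1)
        ]


# ---------------------------------------------------------------------------
# cDNA generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CdnaResult:
    seq: str
    exon_boundaries: tuple[tuple[int, int], ...]  # 1-based inclusive within the cDNA

    def __len__(self) -> int:
        return len(self.seq)


def _exon_boundaries(exon_sizes: Sequence[int]) -> tuple[tuple[int, int], ...]:
    out, pos = [], 1
    for size in exon_sizes:
        out.append((pos, pos + size - 1))
        pos += size
    return tuple(out)


def generate_cdna(
    exon_sizes: Sequence[int],
    seed: int = DEFAULT_SEED,
    *,
    profile: Mapping[int, str] | None = None,
    signal_peptide: str | None = None,
    c_terminal: str | None = None,
) -> CdnaResult:
    """Random-composition CDS (ATG .. stop, no internal stops) cut into exons.

    Optional overlays: a fixed N-terminal signal peptide, a C-terminal
    tetrapeptide, and a diagnostic-residue profile in mature-peptide
    numbering (position p sits at full-length residue p + 18). Overlays are
    applied only when the protein is long enough to hold them.
    """
    exon_sizes = tuple(int(s) for s in exon_sizes)
    if any(s < 1 for s in exon_sizes):
        raise InvalidSpecError("exon sizes must be >= 1")
    total = sum(exon_sizes)
    if total % 3 != 0:
        raise InvalidSpecError(f"exon sizes sum to {total}, not a multiple of 3")
    if total < 6:
        raise InvalidSpecError("need at least 6 nt (start + stop codon)")

    rng = stable_rng(seed, "cdna")
    n_aa = total // 3 - 1
    prot = list(random_protein(rng, n_aa))
    prot[0] = "M"
    if signal_peptide and n_aa >= len(signal_peptide) + 4:
        prot[: len(signal_peptide)] = list(signal_peptide)
    if c_terminal and n_aa >= 22:
        prot[-len(c_terminal):] = list(c_terminal)
    if profile and n_aa >= 18 + max(profile):
        for pos, aa in profile.items():
            prot[18 + pos - 1] = aa
    cds = codons_for("".join(prot), rng) + _STOPS[rng.integers(0, len(_STOPS))]
    assert len(cds) == total
    return CdnaResult(seq=cds, exon_boundaries=_exon_boundaries(exon_sizes))


def apply_diagnostic_profile(cds: str, profile: Mapping[int, str]) -> str:
    """Swap codons so the translated mature peptide realizes ``profile``.

    Positions whose residue already matches are left untouched, so two
    isoforms sharing a column stay nucleotide-identical outside the profile.
    """
    prot = translate(cds)
    out = list(cds)
    for pos, aa in profile.items():
        idx = 18 + pos - 1
        if idx >= len(prot) - 1:
            continue
        if prot[idx] != aa:
            out[idx * 3 : idx * 3 + 3] = CODONS_FOR_AA[aa][0]
    return "".join(out)


# ---------------------------------------------------------------------------
# gene / cluster generation
# ---------------------------------------------------------------------------


def _plant_repeat(promoter: list, plant: RepeatPlantSpec, promoter_len: int) -> tuple:
    """Write copy1 = revcomp(copy2) at the spec'd promoter positions.

    Flanking bases are adjusted so the planted pair is not extendable by
    chance, keeping the detected repeat length exactly ``plant.length``.
    Returns the two copies as 0-based index intervals.
    """
    (s1, e1), (s2, e2) = plant.intervals()
    b1, b2 = promoter_len + s1, promoter_len + s2
    f1, f2 = promoter_len + e1, promoter_len + e2
    copy2 = "".join(promoter[b2 : f2 + 1])
    promoter[b1 : f1 + 1] = revcomp(copy2)
    # break lock-step extension: left of copy1 pairs with right of copy2 ...
    if b1 - 1 >= 0 and f2 + 1 < promoter_len:
        partner = complement(promoter[f2 + 1])
        if promoter[b1 - 1] == partner:
            promoter[b1 - 1] = next(b for b in "ACGT" if b != partner)
    # ... and right of copy1 pairs with left of copy2
    if f1 + 1 < promoter_len and b2 - 1 >= 0 and f1 + 1 != b2 - 1:
        partner = complement(promoter[b2 - 1])
        if promoter[f1 + 1] == partner:
            promoter[f1 + 1] = next(b for b in "ACGT" if b != partner)
    return (b1, f1), (b2, f2)


def _plant_primer_cassettes(
    intron_seqs: list,
    plant: PrimerPlantSpec,
    gene_index: int,
    rng: np.random.Generator,
) -> list:
    """Place primer cassettes (fwd + filler + revcomp(rev)) inside introns.

    Greedy: each cassette goes into the first intron with enough room,
    leaving the GT/AG dinucleotides plus a 2-nt margin intact. Returns
    (pair_id, intron_index, rel_start, rel_end, product, protected_rel) tuples;
    positions are 0-based relative to the intron start.
    """
    panel = {p.id: p for p in tables.primer_panel()}
    cursors = [2 for _ in intron_seqs]  # first writable position after "GT"
    placed = []
    for pair_id in sorted(plant.products):
        pair = panel[pair_id]
        product = plant.product_for(pair_id, gene_index)
        filler = product - len(pair.forward) - len(pair.reverse)
        if filler < 0:
            raise InvalidSpecError(
                f"primer pair {pair_id}: product {product} shorter than the primers"
            )
        cassette = pair.forward + random_dna(rng, filler) + revcomp(pair.reverse)
        for i, intron in enumerate(intron_seqs):
            if cursors[i] + product <= len(intron) - 2:
                start = cursors[i]
                intron_seqs[i] = (
                    intron[:start] + cassette + intron[start + product :]
                )
                cursors[i] = start + product + 2
                # protect the 3'-terminal 5 nt of both primer binding sites
                fwd_3p = range(start + len(pair.forward) - 5, start + len(pair.forward))
                rev_3p = range(start + product - len(pair.reverse),
                               start + product - len(pair.reverse) + 5)
                placed.append(
                    (pair_id, i, start, start + product - 1, product,
                     tuple(fwd_3p) + tuple(rev_3p))
                )
                break
    return placed


def _mutate(
    seq: list,
    rate: float,
    protected: set,
    exon_frames: dict,
    rng: np.random.Generator,
) -> None:
    """Apply i.i.d. substitutions, skipping protected positions.

    Substitutions inside exons avoid creating in-frame stop codons so the
    planted coding sequence always translates. ``exon_frames`` maps a unit
    position (0-based) to its in-frame codon start within the CDS string.
    """
    if rate <= 0:
        return
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    for pos in hits:
        pos = int(pos)
        if pos in protected:
            continue
        current = seq[pos]
        options = [b for b in "ACGT" if b != current]
        order = rng.permutation(len(options))
        if pos in exon_frames:
            cds_idx, codon = exon_frames[pos]
            within = cds_idx % 3
            chosen = None
            for k in order:
                cand = options[k]
                new_codon = codon[:within] + cand + codon[within + 1 :]
                if new_codon not in _STOPS:
                    chosen = cand
                    break
            if chosen is None:
                continue
            seq[pos] = chosen
        else:
            seq[pos] = options[int(order[0])]


def generate_gene(
    spec: SyntheticClusterSpec,
    gene_id: str,
    *,
    gene_index: int | None = None,
) -> tuple[str, GeneTruth]:
    """Generate one gene unit: promoter + exons/introns + downstream tail.

    Coordinates in the returned :class:`GeneTruth` are 1-based within the
    unit (promoter base 1 = position 1); :func:`generate_cluster` shifts
    them onto the master locus. The plus strand is always generated; strand
    placement happens at cluster level.
    """
    spec.validate()
    if gene_index is None:
        gene_index = (
            spec.gene_order.index(gene_id) if gene_id in spec.gene_order else 0
        )
    profiles = tables.diagnostic_profiles()
    base_profile = profiles.get("gamma-PLE")
    gene_profile = profiles.get(gene_id, base_profile)

    base = generate_cdna(
        spec.exon_sizes,
        spec.seed,
        profile=base_profile,
        signal_peptide=SIGNAL_PEPTIDE,
        c_terminal=ER_RETENTION,
    )
    cdna = apply_diagnostic_profile(base.seq, gene_profile) if gene_profile else base.seq

    rng = stable_rng(spec.seed, "gene", gene_id)
    intron_sizes = spec.introns_for(gene_id)

    # promoter with planted inverted repeat
    promoter = list(random_dna(rng, spec.promoter_len))
    repeat_idx = None
    if spec.promoter_len:
        repeat_idx = _plant_repeat(promoter, spec.repeat_plant, spec.promoter_len)

    # introns with GT..AG and primer cassettes
    introns = ["GT" + random_dna(rng, size - 4) + "AG" for size in intron_sizes]
    cassettes = _plant_primer_cassettes(introns, spec.primer_plant, gene_index, rng)

    # interleave exons and introns
    parts = []
    exon_iv, intron_iv = [], []
    pos = spec.promoter_len  # 0-based cursor
    exon_frames: dict[int, tuple[int, str]] = {}
    cds_cursor = 0
    for i, (bs, be) in enumerate(base.exon_boundaries):
        exon_seq = cdna[bs - 1 : be]
        exon_iv.append((pos + 1, pos + len(exon_seq)))
        for k in range(len(exon_seq)):
            # codon context is attached after assembly, once the CDS is known
            exon_frames[pos + k] = (cds_cursor + k, "")
        cds_cursor += len(exon_seq)
        parts.append(exon_seq)
        pos += len(exon_seq)
        if i < len(introns):
            intron_iv.append((pos + 1, pos + len(introns[i])))
            parts.append(introns[i])
            pos += len(introns[i])

    downstream = random_dna(rng, spec.downstream_len)
    unit = list("".join(promoter) + "".join(parts) + downstream)
    unit_len = len(unit)

    # protected positions: GT/AG, start & stop codons, primer 3' ends
    protected: set[int] = set()
    for s, e in intron_iv:
        protected.update((s - 1, s, e - 2, e - 1))
    first_exon, last_exon = exon_iv[0], exon_iv[-1]
    protected.update(range(first_exon[0] - 1, first_exon[0] + 2))  # ATG
    protected.update(range(last_exon[1] - 3, last_exon[1]))  # stop codon
    primer_sites = []
    for pair_id, intron_i, rel_s, rel_e, product, prot_rel in cassettes:
        intron_start = intron_iv[intron_i][0] - 1  # 0-based
        primer_sites.append(
            PrimerSiteTruth(
                pair_id=pair_id,
                start=intron_start + rel_s + 1,
                end=intron_start + rel_e + 1,
                product_len=product,
            )
        )
        protected.update(intron_start + r for r in prot_rel)

    # codon context for stop-avoiding exon mutations
    cds_concat = "".join(cdna[bs - 1 : be] for bs, be in base.exon_boundaries)
    for unit_pos, (cds_idx, _) in list(exon_frames.items()):
        codon_start = (cds_idx // 3) * 3
        exon_frames[unit_pos] = (cds_idx, cds_concat[codon_start : codon_start + 3])

    _mutate(unit, spec.point_mutation_rate, protected, exon_frames, rng)
    seq = "".join(unit)

    realized_cds = "".join(seq[s - 1 : e] for s, e in exon_iv)
    plant = spec.repeat_plant
    truth = GeneTruth(
        gene_id=gene_id,
        strand="+",
        unit_span=(1, unit_len),
        promoter=(1, spec.promoter_len) if spec.promoter_len else None,
        exons=tuple(exon_iv),
        introns=tuple(intron_iv),
        repeat_copies=(
            ((repeat_idx[0][0] + 1, repeat_idx[0][1] + 1),
             (repeat_idx[1][0] + 1, repeat_idx[1][1] + 1))
            if repeat_idx
            else None
        ),
        repeat_promoter_coords=plant.intervals() if repeat_idx else None,
        primer_sites=tuple(primer_sites),
        cdna=cdna,
        cds=realized_cds,
    )
    return seq, truth


def generate_cluster(spec: SyntheticClusterSpec) -> tuple[str, ClusterTruth]:
    """Concatenate the spec'd genes with random intergenic spacers."""
    spec.validate()
    parts: list[str] = []
    truths: list[GeneTruth] = []
    offset = 0
    for idx, gid in enumerate(spec.gene_order):
        seq, truth = generate_gene(spec, gid, gene_index=idx)
        if spec.strand_for(gid) == "-":
            seq = revcomp(seq)
            truth = truth.flipped()
        truths.append(truth.shifted(offset))
        parts.append(seq)
        offset += len(seq)
        if idx < len(spec.gene_order) - 1:
            spacer = random_dna(stable_rng(spec.seed, "intergenic", idx), spec.intergenic_len)
            parts.append(spacer)
            offset += len(spacer)
    locus = "".join(parts)
    return locus, ClusterTruth(spec=spec, locus_len=len(locus), genes=tuple(truths))


# ---------------------------------------------------------------------------
# clones and library
# ---------------------------------------------------------------------------


def bundled_vector() -> str:
    """The bundled vector stand-in (synthetic, fixed-seed, 8128 nt).

    The true cloning vector sequence is not part of the bundled data; this
    is a synthetic placeholder of the published length. Users may substitute
    the real vector FASTA anywhere a vector sequence is accepted.
    """
    ref = resources.files("plegenes.data").joinpath("pcc1bac_synthetic.fasta")
    with ref.open("r") as fh:
        lines = [l.strip() for l in fh if not l.startswith(">")]
    return "".join(lines)


def generate_bac_clones(
    locus: str,
    windows: Sequence[tuple[int, int]],
    vector_seq: str | None = None,
    names: Sequence[str] | None = None,
) -> tuple[list[tuple[str, str]], CloneSetTruth]:
    """Cut clone inserts out of the locus and prepend the vector.

    ``windows`` are 1-based inclusive locus intervals (may overlap). Returns
    ``[(name, sequence), ...]`` plus truth with window offsets; pairwise
    window intersection lengths are available via ``CloneSetTruth.overlap``.
    """
    if vector_seq is None:
        vector_seq = bundled_vector()
    n = len(locus)
    records, truths = [], []
    for i, (s, e) in enumerate(windows):
        if not (1 <= s <= e <= n):
            raise InvalidSpecError(f"clone window ({s}, {e}) outside locus of length {n}")
        name = names[i] if names else f"clone-{i + 1}"
        insert = locus[s - 1 : e]
        records.append((name, vector_seq + insert))
        truths.append(
            CloneTruth(name=name, window=(s, e), vector_len=len(vector_seq), insert_len=len(insert))
        )
    return records, CloneSetTruth(clones=tuple(truths))


def _contaminated(seq: str, patterns: tuple[str, ...]) -> bool:
    return any(p in seq for p in patterns)


def generate_library(
    layout: LibraryLayoutSpec,
    positive_clone_seqs: Mapping[str, str],
    seed: int = DEFAULT_SEED,
) -> Library:
    """Populate the well grid: positives where the layout says, decoys elsewhere.

    Decoy inserts are random sequences re-drawn (in the astronomically
    unlikely case) until they contain no occurrence of any bundled primer or
    its reverse complement, so a decoy can never amplify.
    """
    layout.validate()
    for _, _, _, key in layout.positives:
        if key not in positive_clone_seqs:
            raise InvalidSpecError(f"no clone sequence supplied for positive '{key}'")
    patterns = []
    for pair in tables.primer_panel():
        patterns += [pair.forward, revcomp(pair.forward), pair.reverse, revcomp(pair.reverse)]
    patterns = tuple(dict.fromkeys(patterns))

    rng = stable_rng(seed, "library")
    wells: dict = {}
    for plate in range(1, layout.n_plates + 1):
        for row in range(1, layout.rows + 1):
            for col in range(1, layout.cols + 1):
                s = random_dna(rng, layout.decoy_insert_len)
                while _contaminated(s, patterns):
                    s = random_dna(rng, layout.decoy_insert_len)
                wells[(plate, row, col)] = s
    for plate, row, col, key in layout.positives:
        wells[(plate, row, col)] = positive_clone_seqs[key]
    return Library(layout=layout, wells=wells, positives=tuple(layout.positives))


@dataclass(frozen=True)
class CloneSetLayout:
    """A generated multi-clone layout with everything tests need."""

    clones: tuple  # (name, sequence) with vector prepended
    clone_windows: dict  # name -> (locus_key, (start, end))
    clone_genes: dict  # name -> [(gene_id, gene-body start position on insert)]
    insert_lengths: dict
    loci: dict  # locus_key -> (sequence, ClusterTruth)
    vector: str


def generate_reference_clone_set(seed: int = DEFAULT_SEED) -> CloneSetLayout:
    """Five overlapping clones over two gene clusters.

    Emulates the published clone architecture: one cluster carrying
    PLE-G2, PLE-1 and PLE-B9 covered by four clones chained by large end
    overlaps (one clone holding G2 only, one G2+PLE-1, one PLE-1+B9, one B9
    only), and a separate single-clone cluster carrying PLE-C4 next to a
    long stretch of unrelated sequence.
    """
    vector = bundled_vector()
    spec1 = SyntheticClusterSpec(seed=seed)
    locus1, truth1 = generate_cluster(spec1)
    spec2 = SyntheticClusterSpec(gene_order=("PLE-C4",), seed=seed)
    locus2, truth2 = generate_cluster(spec2)
    locus2 = locus2 + random_dna(stable_rng(seed, "unknown-tail"), 60000)
    truth2 = replace(truth2, locus_len=len(locus2))

    n1 = len(locus1)
    windows1 = {
        "BAC-10": (1, 40000),
        "BAC-206": (5001, 105000),
        "BAC-70": (60001, n1),
        "BAC-75": (115001, n1),
    }
    windows2 = {"BAC-119": (1, min(len(locus2), 110000))}

    clones = []
    clone_windows: dict = {}
    clone_genes: dict = {}
    insert_lengths: dict = {}
    for key, locus, truth, windows in (
        ("cluster1", locus1, truth1, windows1),
        ("cluster2", locus2, truth2, windows2),
    ):
        for name, (s, e) in windows.items():
            records, _ = generate_bac_clones(locus, [(s, e)], vector_seq=vector, names=[name])
            clones.append(records[0])
            clone_windows[name] = (key, (s, e))
            insert_lengths[name] = e - s + 1
            genes = []
            for g in truth.genes:
                body = (g.exons[0][0], g.exons[-1][1])
                if s <= body[0] and body[1] <= e:
                    genes.append((g.gene_id, body[0] - s + 1))
            clone_genes[name] = genes
    return CloneSetLayout(
        clones=tuple(clones),
        clone_windows=clone_windows,
        clone_genes=clone_genes,
        insert_lengths=insert_lengths,
        loci={"cluster1": (locus1, truth1), "cluster2": (locus2, truth2)},
        vector=vector,
    )


# ---------------------------------------------------------------------------
# output plumbing
# ---------------------------------------------------------------------------


def truth_to_json(truth: ClusterTruth) -> dict:
    """JSON-serializable sidecar with repeat / primer / gene truth."""
    return {
        "locus_len": truth.locus_len,
        "gene_order": list(truth.gene_order),
        "genes": [
            {
                "gene_id": g.gene_id,
                "strand": g.strand,
                "unit_span": list(g.unit_span),
                "exons": [list(iv) for iv in g.exons],
                "introns": [list(iv) for iv in g.introns],
                "repeat_copies": (
                    [list(iv) for iv in g.repeat_copies] if g.repeat_copies else None
                ),
                "repeat_promoter_coords": (
                    [list(iv) for iv in g.repeat_promoter_coords]
                    if g.repeat_promoter_coords
                    else None
                ),
                "primer_sites": [dataclasses.asdict(p) for p in g.primer_sites],
            }
            for g in truth.genes
        ],
    }


def write_fasta(path, records) -> None:
    """records: iterable of (name, sequence)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    seqio_write(recs, str(path), "fasta")


def write_cluster_outputs(outdir, locus: str, truth: ClusterTruth) -> None:
    """Write locus FASTA, per-gene cDNA FASTA, truth GFF3 and JSON sidecar."""
    import pathlib

    from .gff import write_gff3

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "locus.fasta", [("locus", locus)])
    write_fasta(
        outdir / "cdna.fasta",
        [(f"{g.gene_id}_cdna", g.cdna) for g in truth.genes],
    )
    write_gff3([g.to_model("locus") for g in truth.genes], outdir / "truth.gff3")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_to_json(truth), fh, indent=2)
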