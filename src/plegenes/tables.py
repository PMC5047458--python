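"""Bundled reference tables for the PLE gene family.

Four small fixtures travel with the package:

* exon sizes of the four PLE genes (14 exons, identical across genes) plus
  their amino-acid homology to gamma-PLE,
* intron sizes of the four PLE genes (13 introns each; PLE-B9 appears twice,
  once per source clone),
* the 25 diagnostic amino-acid positions distinguishing eleven PLE
  isoenzymes (mature-peptide numbering, i.e. after removal of the 18-residue
  signal peptide),
* the eight primer pairs used to screen the BAC library, with annealing
  temperature and expected product sizes.

All loaders return plain pandas DataFrames / dicts of the printed values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

GENE_NAMES = ("PLE-1", "PLE-B9", "PLE-C4", "PLE-G2")

#: default intron-size row used for each gene (PLE-B9 defaults to its BAC-75 copy)
INTRON_ROW_FOR_GENE = {
    "PLE-1": "PLE-1",
    "PLE-B9": "PLE-B9(75)",
    "PLE-C4": "PLE-C4",
    "PLE-G2": "PLE-G2",
}


def _read_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("plegenes.data").joinpath(name)
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


@lru_cache(maxsize=None)
def exon_sizes_table() -> pd.DataFrame:
    """Exon sizes (bp) per gene, indexed by gene name."""
    return _read_tsv("table1_exons.tsv").set_index("gene")


@lru_cache(maxsize=None)
def intron_sizes_table() -> pd.DataFrame:
    """Intron sizes (bp) per gene, indexed by gene name."""
    return _read_tsv("table2_introns.tsv").set_index("gene")


@lru_cache(maxsize=None)
def diagnostic_table() -> pd.DataFrame:
    """25 diagnostic residues x 11 isoenzymes, indexed by mature position."""
    return _read_tsv("table3_diagnostic.tsv").set_index("position")


def exon_sizes(gene: str = "PLE-1") -> tuple[int, ...]:
    row = exon_sizes_table().loc[gene]
    return tuple(int(row[f"exon_{i}"]) for i in range(1, 15))


def intron_sizes(gene: str = "PLE-1") -> tuple[int, ...]:
    key = INTRON_ROW_FOR_GENE.get(gene, gene)
    tab = intron_sizes_table()
    if key not in tab.index:
        key = "PLE-1"
    row = tab.loc[key]
    return tuple(int(row[f"intron_{i}"]) for i in range(1, 14))


DIAGNOSTIC_POSITIONS = (
    73, 75, 76, 77, 80, 87, 92, 93, 129, 133, 134, 138, 139,
    234, 236, 237, 285, 286, 287, 290, 294, 302, 459, 461, 463,
)


def diagnostic_profiles() -> dict[str, dict[int, str]]:
    """Mapping isoenzyme name -> {mature position: residue} for all 11 columns."""
    tab = diagnostic_table()
    return {name: {int(p): str(v) for p, v in tab[name].items()} for name in tab.columns}


@dataclass(frozen=True)
class PrimerPair:
    """One screening primer pair with its expected product size(s)."""

    id: int
    forward: str
    reverse: str
    annealing_temp: float
    expected_products: tuple[int, ...]

    def __post_init__(self):
        if len(self.forward) < 15 or len(self.reverse) < 15:
            raise ValueError(f"primer pair {self.id}: primers must be >= 15 nt")
        if not self.expected_products:
            raise ValueError(f"primer pair {self.id}: expected_products is empty")


@lru_cache(maxsize=None)
def primer_panel() -> tuple[PrimerPair, ...]:
    """All eight bundled primer pairs, in id order."""
    df = _read_tsv("table5_primers.tsv")
    pairs = []
    for _, row in df.iterrows():
        products = tuple(int(x) for x in str(row["products"]).split("/"))
        pairs.append(
            PrimerPair(
                id=int(row["id"]),
                forward=str(row["forward"]),
                reverse=str(row["reverse"]),
                annealing_temp=float(row["annealing_c"]),
                expected_products=products,
            )
        )
    return tuple(pairs)


def screening_panel() -> tuple[PrimerPair, ...]:
    """The five pairs retained for library screening (1, 2, 4, 5 and 6)."""
    keep = {1, 2, 4, 5, 6}
    return tuple(p for p in primer_panel() if p.id in keep)


def load_fixture_tables() -> dict:
    """Return all bundled tables at once (exons, introns, diagnostics, primers)."""
    return {
        "exon_sizes": exon_sizes_table(),
        "intron_sizes": intron_sizes_table(),
        "diagnostic": diagnostic_table(),
        "primers": primer_panel(),
    }
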