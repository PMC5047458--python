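"""Small shared helpers: complements, random sequence synthesis, codon tables."""

from __future__ import annotations

import zlib

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))

# amino acid -> sorted list of codons (standard genetic code)
CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    CODONS_FOR_AA.setdefault(_aa, []).append(_codon)

AMINO_ACIDS = "".join(sorted(CODONS_FOR_AA))  # 20 standard letters


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform i.i.d. ACGT string of length ``n``."""
    if n <= 0:
        return ""
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def random_protein(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    idx = rng.integers(0, len(AMINO_ACIDS), size=n)
    return "".join(AMINO_ACIDS[i] for i in idx)


def codons_for(protein: str, rng: np.random.Generator) -> str:
    """Back-translate a protein, drawing uniformly among synonymous codons."""
    parts = []
    for aa in protein:
        options = CODONS_FOR_AA[aa]
        parts.append(options[rng.integers(0, len(options))])
    return "".join(parts)


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


def stable_rng(seed: int, *labels) -> np.random.Generator:
    """Deterministic RNG derived from an integer seed plus string/int labels.

    The labels keep independent parts of a simulation (per-gene, per-spacer,
    per-well ...) decoupled so that changing one does not reshuffle the rest.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, int):
            entropy.append(lab & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(lab).encode()))
    return np.random.default_rng(entropy)
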