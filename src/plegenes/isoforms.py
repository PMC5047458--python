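"""Translation, protein features, and diagnostic-position isoform typing.

The carboxylesterase isoforms of the PLE family differ at 25 diagnostic
amino-acid positions (numbered on the mature peptide, i.e. after removing
the 18-residue N-terminal signal peptide). Reading those positions from a
translated coding sequence and comparing against the bundled isoenzyme
profiles assigns a gene product to a known isoform or calls it novel.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._util import translate
from .errors import TranslationError
from .spliced import pairwise_identity
from .tables import DIAGNOSTIC_POSITIONS, diagnostic_profiles

SIGNAL_PEPTIDE_LEN = 18


@dataclass(frozen=True)
class ProteinFeatures:
    length: int  # aa, stop excluded
    signal_peptide: str  # first 18 residues
    c_terminal_4: str
    third_from_bottom: str
    starts_with_met: bool


@dataclass(frozen=True)
class IsoformProfile:
    """Residues at the 25 diagnostic positions (mature-peptide numbering)."""

    name: str
    residues: dict

    def __post_init__(self):
        if tuple(sorted(self.residues)) != DIAGNOSTIC_POSITIONS:
            raise ValueError("profile must cover exactly the 25 diagnostic positions")

    def mismatches(self, other: "IsoformProfile") -> int:
        return sum(1 for p in DIAGNOSTIC_POSITIONS if self.residues[p] != other.residues[p])


@dataclass(frozen=True)
class Classification:
    best_match: str
    best_mismatches: int
    is_novel: bool
    mismatch_table: dict  # reference name -> mismatch count


def translate_cds(cds: str) -> tuple[str, ProteinFeatures]:
    """Standard-code translation plus N/C-terminal features.

    The CDS must be a whole number of codons with a single terminal stop;
    an internal stop raises :class:`TranslationError` naming the codon. A
    non-ATG start is tolerated but flagged via ``starts_with_met``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(f"CDS length {len(cds)} is not a multiple of 3")
    if len(cds) < 6:
        raise TranslationError("CDS must hold at least a start and a stop codon")
    prot = translate(cds)
    if not prot.endswith("*"):
        raise TranslationError("CDS does not end with a stop codon")
    body = prot[:-1]
    if "*" in body:
        raise TranslationError(f"internal stop codon at codon {body.index('*') + 1}")
    feats = ProteinFeatures(
        length=len(body),
        signal_peptide=body[:SIGNAL_PEPTIDE_LEN],
        c_terminal_4=body[-4:],
        third_from_bottom=body[-3] if len(body) >= 3 else "",
        starts_with_met=cds.startswith("ATG"),
    )
    return body, feats


def diagnostic_profile(protein: str, name: str = "query") -> IsoformProfile:
    """Strip the signal peptide and read the 25 diagnostic positions."""
    protein = protein.rstrip("*")
    needed = SIGNAL_PEPTIDE_LEN + max(DIAGNOSTIC_POSITIONS)
    if len(protein) < needed:
        raise ValueError(
            f"protein of {len(protein)} aa too short; need >= {needed} to cover "
            "all diagnostic positions"
        )
    mature = protein[SIGNAL_PEPTIDE_LEN:]
    residues = {p: mature[p - 1] for p in DIAGNOSTIC_POSITIONS}
    return IsoformProfile(name=name, residues=residues)


def reference_profiles() -> dict[str, IsoformProfile]:
    """The bundled isoenzyme columns as :class:`IsoformProfile` objects."""
    return {
        name: IsoformProfile(name=name, residues=res)
        for name, res in diagnostic_profiles().items()
    }


def classify_isoform(
    profile: IsoformProfile,
    references: dict[str, IsoformProfile] | None = None,
) -> Classification:
    """Nearest reference by diagnostic-position mismatches; novel if none is exact.

    Ambiguous nucleotides translate to ``X`` upstream and count as
    mismatches here, so unknowns never fake an identity.
    """
    refs = references or reference_profiles()
    table = {name: profile.mismatches(ref) for name, ref in refs.items()}
    best = min(table, key=lambda n: (table[n], list(refs).index(n)))
    return Classification(
        best_match=best,
        best_mismatches=table[best],
        is_novel=table[best] > 0,
        mismatch_table=table,
    )


def variable_positions(profiles: dict[str, IsoformProfile] | None = None) -> list[int]:
    """Diagnostic positions at which the given profiles are not unanimous."""
    refs = profiles or reference_profiles()
    out = []
    for p in DIAGNOSTIC_POSITIONS:
        values = {prof.residues[p] for prof in refs.values()}
        if len(values) > 1:
            out.append(p)
    return out


def identity_matrix(proteins: dict[str, str]) -> "pd.DataFrame":
    """Symmetric pairwise percent-identity table over protein sequences."""
    import pandas as pd

    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    names = list(proteins)
    mat = pd.DataFrame(100.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pct = pairwise_identity(proteins[a], proteins[b], alphabet="aa").percent
            mat.loc[a, b] = pct
            mat.loc[b, a] = pct
    return mat
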