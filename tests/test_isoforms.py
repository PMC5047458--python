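"""Translation, protein features, and diagnostic-position classification."""

import itertools

import pytest

from plegenes import synthetic as syn
from plegenes import tables
from plegenes.errors import TranslationError
from plegenes.isoforms import (
    IsoformProfile,
    classify_isoform,
    diagnostic_profile,
    identity_matrix,
    reference_profiles,
    translate_cds,
    variable_positions,
)


def test_table_sized_cds_translates_to_565_aa():
    cds = syn.generate_cdna(tables.exon_sizes()).seq
    prot, feats = translate_cds(cds)
    assert feats.length == 565
    assert len(prot) == 565


def test_hand_translation_and_cterm():
    prot, feats = translate_cds("ATGGCGGAGCTTTAA")
    assert prot == "MAEL"
    assert feats.c_terminal_4 == "MAEL"
    assert feats.starts_with_met


def test_generated_gene_has_planted_features(ple1_gene):
    _, truth = ple1_gene
    prot, feats = translate_cds(truth.cds)
    assert feats.signal_peptide == syn.SIGNAL_PEPTIDE
    assert feats.c_terminal_4 == "HAEL"
    assert feats.third_from_bottom == "A"


def test_translation_errors():
    with pytest.raises(TranslationError, match="multiple of 3"):
        translate_cds("ATGAA")
    with pytest.raises(TranslationError, match="codon 2"):
        translate_cds("ATGTAAGGGTAA")
    with pytest.raises(TranslationError, match="stop"):
        translate_cds("ATGGCGGAGCTT")
    prot, feats = translate_cds("TTGGCGGAGCTTTAA")  # non-ATG start: flagged only
    assert not feats.starts_with_met


@pytest.mark.parametrize("gene", ["PLE-1", "PLE-B9", "PLE-C4", "PLE-G2"])
def test_planted_profiles_classify_back_to_their_column(gene):
    spec = syn.SyntheticClusterSpec(seed=51)
    _, truth = syn.generate_gene(spec, gene)
    prof = diagnostic_profile(truth.protein, gene)
    result = classify_isoform(prof)
    # PLE-1's column is identical to gamma-PLE's, which sits first in the table
    expected = "gamma-PLE" if gene == "PLE-1" else gene
    assert result.best_match == expected
    assert result.best_mismatches == 0
    assert not result.is_novel
    assert result.mismatch_table[gene] == 0


def test_all_eleven_reference_columns_round_trip():
    refs = reference_profiles()
    for name, prof in refs.items():
        res = classify_isoform(prof)
        # PLE-1 and gamma-PLE share a column; either label is a 0-mismatch hit
        assert res.best_mismatches == 0
        assert prof.mismatches(refs[res.best_match]) == 0


def test_ple1_column_matches_gamma_ple_exactly():
    refs = reference_profiles()
    assert refs["PLE-1"].mismatches(refs["gamma-PLE"]) == 0
    res = classify_isoform(refs["PLE-1"])
    assert res.best_match == "gamma-PLE"
    assert res.best_mismatches == 0


def test_novel_profile_detected():
    refs = reference_profiles()
    residues = dict(refs["gamma-PLE"].residues)
    residues[73] = "W"  # no column carries W at 73
    novel = IsoformProfile(name="q", residues=residues)
    res = classify_isoform(novel)
    assert res.is_novel
    assert res.best_mismatches == 1


def test_all_25_positions_are_variable_across_columns():
    assert len(variable_positions()) == 25


def test_all_alanine_profile():
    prot = "A" * 500
    prof = diagnostic_profile(prot)
    assert set(prof.residues.values()) == {"A"}


def test_profile_too_short_errors():
    with pytest.raises(ValueError, match="too short"):
        diagnostic_profile("M" * 100)


def test_mismatch_counts_are_a_metric():
    refs = list(reference_profiles().values())
    for a, b in itertools.combinations(refs, 2):
        assert a.mismatches(b) == b.mismatches(a)
        assert (a.mismatches(b) == 0) == (a.residues == b.residues)
    for a in refs:
        assert a.mismatches(a) == 0


def test_translation_invariant_to_exon_partition():
    """The same CDS split into different exon layouts gives one protein."""
    total = sum(tables.exon_sizes())
    a = syn.generate_cdna(tables.exon_sizes(), seed=33)
    b = syn.generate_cdna([total // 2, total - total // 2], seed=33)
    assert a.seq == b.seq  # partition does not affect the coding sequence
    assert translate_cds(a.seq)[0] == translate_cds(b.seq)[0]


def test_identity_matrix_symmetric():
    spec = syn.SyntheticClusterSpec(seed=61)
    prots = {}
    for gene in ("PLE-1", "PLE-G2"):
        _, truth = syn.generate_gene(spec, gene)
        prots[gene] = truth.protein
    prots["copy"] = prots["PLE-1"]
    mat = identity_matrix(prots)
    assert mat.loc["PLE-1", "copy"] == 100.0
    assert mat.loc["PLE-1", "PLE-G2"] == mat.loc["PLE-G2", "PLE-1"]
    assert mat.loc["PLE-1", "PLE-G2"] > 90.0  # isoforms differ at few positions
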