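"""In-silico PCR and the three-step pooled screen."""

import pytest

from plegenes import synthetic as syn
from plegenes import tables
from plegenes._util import random_dna, revcomp, stable_rng
from plegenes.screening import (
    insilico_pcr,
    pool,
    pool_is_positive,
    run_three_step_screen,
    template_is_positive,
    verify_primer_panel,
)

PANEL = tables.primer_panel()
PAIR = {p.id: p for p in PANEL}


@pytest.fixture(scope="module")
def positive_clone(ple1_gene):
    seq, _ = ple1_gene
    return syn.bundled_vector() + seq


def test_pair1_amplifies_208_on_positive_clone(positive_clone):
    amps = insilico_pcr(positive_clone, PAIR[1])
    assert [a.length for a in amps] == [208]
    a = amps[0]
    assert a.end - a.start + 1 == 208
    assert positive_clone[a.start - 1 :].startswith(PAIR[1].forward)


def test_constructed_template_arithmetic():
    fwd, rev = PAIR[1].forward, PAIR[1].reverse
    template = fwd + "N" * 10 + revcomp(rev)
    amps = insilico_pcr(template, PAIR[1])
    assert len(amps) == 1
    assert amps[0].length == len(fwd) + 10 + len(rev)
    assert amps[0].start == 1 and amps[0].end == len(template)


def test_reverse_orientation_template():
    fwd, rev = PAIR[1].forward, PAIR[1].reverse
    template = revcomp(fwd + "ACGT" * 20 + revcomp(rev))
    amps = insilico_pcr(template, PAIR[1])
    assert len(amps) == 1
    assert amps[0].strand == "-"


def test_decoy_template_is_silent():
    decoy = random_dna(stable_rng(17, "decoy"), 5000)
    for pair in PANEL:
        assert insilico_pcr(decoy, pair) == []


def test_max_product_filter(positive_clone):
    # pair 4's cassette realizes 2327 in the first-indexed gene
    amps = insilico_pcr(positive_clone, PAIR[4], max_product=10000)
    assert amps and amps[0].length in (2327, 3811)
    assert insilico_pcr(positive_clone, PAIR[4], max_product=1000) == []


def test_mismatch_tolerance_requires_exact_three_prime(positive_clone):
    fwd = PAIR[1].forward
    # corrupt one base in the middle of the forward site
    site = positive_clone.find(fwd)
    mutated = list(positive_clone)
    mid = site + 10
    mutated[mid] = "A" if mutated[mid] != "A" else "C"
    mutated = "".join(mutated)
    assert insilico_pcr(mutated, PAIR[1], max_mismatch=0) == []
    assert [a.length for a in insilico_pcr(mutated, PAIR[1], max_mismatch=1)] == [208]
    # a 3'-terminal corruption is never tolerated
    mutated3 = list(positive_clone)
    tail = site + len(fwd) - 1
    mutated3[tail] = "A" if mutated3[tail] != "A" else "C"
    assert insilico_pcr("".join(mutated3), PAIR[1], max_mismatch=2) == []


def test_pool_positivity_is_or_over_members(positive_clone):
    decoys = [random_dna(stable_rng(s, "pool"), 800) for s in range(6)]
    panel = tables.screening_panel()
    assert not pool_is_positive(pool(decoys), panel)
    for k in range(len(decoys) + 1):
        members = decoys[:k] + [positive_clone] + decoys[k:]
        assert pool_is_positive(pool(members), panel)
    # monotone: adding members never turns a pool negative
    assert pool_is_positive(pool(decoys + [positive_clone] + decoys), panel)


def test_three_step_screen_recovers_planted_positives(clone_layout):
    clone_seqs = dict(clone_layout.clones)
    positions = (
        (3, 2, 11, "BAC-10"),
        (7, 5, 4, "BAC-70"),
        (9, 16, 24, "BAC-75"),
        (14, 1, 1, "BAC-119"),
        (18, 8, 17, "BAC-206"),
    )
    layout = syn.LibraryLayoutSpec(n_plates=20, positives=positions, decoy_insert_len=1000)
    library = syn.generate_library(layout, clone_seqs, seed=101)
    result = run_three_step_screen(library)
    assert sorted(result.step3_positive_wells) == sorted((p, r, c) for p, r, c, _ in positions)
    assert result.step1_positive_plates == [3, 7, 9, 14, 18]
    # pooling economy: far fewer reactions than one per well
    n_plates, n_pools = 5, 5
    assert result.pcr_count == 20 + 24 * n_plates + 16 * n_pools
    assert result.pcr_count < 384 * 20


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_no_false_positives_on_decoy_libraries(seed):
    layout = syn.LibraryLayoutSpec(n_plates=4, positives=(), decoy_insert_len=800)
    library = syn.generate_library(layout, {}, seed=seed)
    result = run_three_step_screen(library)
    assert result.step1_positive_plates == []
    assert result.step3_positive_wells == []
    assert result.pcr_count == 4


def test_verify_primer_panel_mirrors_pair_selection():
    # two genes so that double-product pairs realize both printed sizes
    spec = syn.SyntheticClusterSpec(gene_order=("PLE-G2", "PLE-1"), seed=71)
    g2 = syn.generate_gene(spec, "PLE-G2", gene_index=0)[0]
    p1 = syn.generate_gene(spec, "PLE-1", gene_index=1)[0]
    decoys = [random_dna(stable_rng(s, "vd"), 3000) for s in range(3)]
    verdicts = {v.pair_id: v for v in verify_primer_panel(PANEL, [g2, p1], decoys)}
    assert [pid for pid, v in sorted(verdicts.items()) if v.status == "usable"] == [1, 2, 4, 5, 6]
    assert verdicts[3].status == "rejected_no_product"
    assert verdicts[7].status == "rejected_no_product"
    assert verdicts[8].status == "rejected_no_product"
    assert verdicts[4].product_sizes_on_positives == (2327, 3811)
    assert verdicts[5].product_sizes_on_positives == (1540, 3558)
    assert verdicts[6].product_sizes_on_positives == (1213, 1869)
    assert all(v.products_on_decoys == () for v in verdicts.values())


def test_positive_well_calling_uses_size_window(positive_clone):
    panel = tables.screening_panel()
    assert template_is_positive(positive_clone, panel)
    decoy = random_dna(stable_rng(5, "neg"), 2000)
    assert not template_is_positive(decoy, panel)
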