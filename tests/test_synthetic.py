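"""Generator invariants: determinism, forced motifs, bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plegenes import synthetic as syn
from plegenes import tables
from plegenes._util import revcomp, translate
from plegenes.errors import InvalidSpecError


def test_generate_cdna_table_sizes():
    res = syn.generate_cdna(tables.exon_sizes())
    assert len(res.seq) == 1698
    assert res.seq.startswith("ATG")
    assert res.seq[-3:] in ("TAA", "TAG", "TGA")
    prot = translate(res.seq)
    assert "*" not in prot[:-1] and prot.endswith("*")
    assert len(res.exon_boundaries) == 14
    assert res.exon_boundaries[0] == (1, 52)
    assert res.exon_boundaries[-1] == (1518, 1698)


def test_generate_cdna_minimal_and_errors():
    res = syn.generate_cdna([3, 3])
    assert len(res.seq) == 6
    assert res.seq.startswith("ATG")
    assert len(res.exon_boundaries) == 2
    with pytest.raises(InvalidSpecError):
        syn.generate_cdna([4, 3])


def test_cdna_deterministic():
    a = syn.generate_cdna(tables.exon_sizes(), seed=99)
    b = syn.generate_cdna(tables.exon_sizes(), seed=99)
    c = syn.generate_cdna(tables.exon_sizes(), seed=100)
    assert a.seq == b.seq
    assert a.seq != c.seq


def test_gene_determinism_and_layout(default_spec, ple1_gene):
    seq, truth = ple1_gene
    seq2, truth2 = syn.generate_gene(default_spec, "PLE-1")
    assert seq == seq2 and truth == truth2
    # promoter + body + downstream
    assert len(seq) == 6000 + (1698 + sum(tables.intron_sizes("PLE-1"))) + 200
    body = truth.exons[-1][1] - truth.exons[0][0] + 1
    assert body == 1698 + 32069
    assert truth.exon_sizes() == tables.exon_sizes("PLE-1")
    assert truth.intron_sizes() == tables.intron_sizes("PLE-1")


def test_gene_gt_ag_and_planted_repeat(ple1_gene):
    seq, truth = ple1_gene
    for s, e in truth.introns:
        assert seq[s - 1 : s + 1] == "GT"
        assert seq[e - 2 : e] == "AG"
    (c1s, c1e), (c2s, c2e) = truth.repeat_copies
    assert c1e - c1s + 1 == 720 and c2e - c2s + 1 == 720
    assert seq[c1s - 1 : c1e] == revcomp(seq[c2s - 1 : c2e])
    assert truth.repeat_promoter_coords == ((-5132, -4413), (-802, -83))


def test_mutations_keep_motifs_and_cds_translatable():
    spec = syn.SyntheticClusterSpec(point_mutation_rate=0.02, seed=5)
    seq, truth = syn.generate_gene(spec, "PLE-1")
    for s, e in truth.introns:
        assert seq[s - 1 : s + 1] == "GT" and seq[e - 2 : e] == "AG"
    assert truth.cds.startswith("ATG")
    prot = translate(truth.cds)
    assert prot.endswith("*") and "*" not in prot[:-1]
    # mutations actually happened
    assert truth.cds != truth.cdna


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    n_exons=st.integers(2, 5),
    rate=st.sampled_from([0.0, 0.01, 0.05]),
)
def test_gt_ag_and_no_internal_stop_property(seed, n_exons, rate):
    rng = np.random.default_rng(seed)
    exons = [int(rng.integers(10, 90)) for _ in range(n_exons)]
    exons[-1] += (3 - sum(exons) % 3) % 3
    introns = tuple(int(rng.integers(45, 400)) for _ in range(n_exons - 1))
    spec = syn.SyntheticClusterSpec(
        gene_order=("PLE-1",),
        exon_sizes=tuple(exons),
        intron_sizes={"PLE-1": introns},
        promoter_len=300,
        downstream_len=50,
        repeat_plant=syn.RepeatPlantSpec(length=30, copy1_start=-280, copy2_start=-60),
        primer_plant=syn.PrimerPlantSpec(products={}),
        point_mutation_rate=rate,
        seed=seed,
    )
    seq, truth = syn.generate_gene(spec, "PLE-1")
    for s, e in truth.introns:
        assert seq[s - 1 : s + 1] == "GT" and seq[e - 2 : e] == "AG"
    prot = translate(truth.cds)
    assert "*" not in prot[:-1]
    # determinism: same spec, same bytes
    assert syn.generate_gene(spec, "PLE-1")[0] == seq


def test_spec_validation_errors():
    with pytest.raises(InvalidSpecError):
        syn.SyntheticClusterSpec(point_mutation_rate=0.2).validate()
    with pytest.raises(InvalidSpecError):
        syn.SyntheticClusterSpec(
            gene_order=("PLE-1",), intron_sizes={"PLE-1": (3,) * 13}
        ).validate()
    with pytest.raises(InvalidSpecError):
        syn.RepeatPlantSpec(copy1_start=-700, copy2_start=-400, length=400).validate(6000)
    with pytest.raises(InvalidSpecError):
        syn.RepeatPlantSpec(copy1_start=-7000).validate(6000)


def test_cluster_arithmetic_and_order():
    spec = syn.SyntheticClusterSpec(seed=3)
    locus, truth = syn.generate_cluster(spec)
    unit_lens = []
    for gid in spec.gene_order:
        unit_lens.append(6000 + 1698 + sum(tables.intron_sizes(gid)) + 200)
    assert len(locus) == sum(unit_lens) + 2 * 22000
    assert truth.gene_order == ("PLE-G2", "PLE-1", "PLE-B9")
    assert truth.locus_len == len(locus)


def test_single_gene_cluster_matches_generate_gene():
    spec = syn.SyntheticClusterSpec(gene_order=("PLE-1",))
    locus, truth = syn.generate_cluster(spec)
    seq, gtruth = syn.generate_gene(spec, "PLE-1")
    assert locus == seq
    assert truth.genes[0].exons == gtruth.exons


def test_custom_gene_order_respected():
    spec = syn.SyntheticClusterSpec(gene_order=("PLE-G2", "PLE-1", "PLE-B9"), seed=8)
    _, truth = syn.generate_cluster(spec)
    assert truth.gene_order == ("PLE-G2", "PLE-1", "PLE-B9")


def test_bac_clone_windows_and_overlap_truth():
    locus = "A" * 0 + syn.generate_cluster(syn.SyntheticClusterSpec(gene_order=("PLE-1",)))[0]
    vec = syn.bundled_vector()
    records, truth = syn.generate_bac_clones(
        locus, [(1, 10000), (3919, 16000)], vector_seq=vec, names=["a", "b"]
    )
    assert truth.overlap("a", "b") == 6082
    assert all(len(seq) == 8128 + t.insert_len for (_, seq), t in zip(records, truth.clones))
    records2, truth2 = syn.generate_bac_clones(locus, [(1, 5000), (20000, 30000)], vec)
    assert truth2.overlap("clone-1", "clone-2") == 0
    with pytest.raises(InvalidSpecError):
        syn.generate_bac_clones(locus, [(0, 100)], vec)
    with pytest.raises(InvalidSpecError):
        syn.generate_bac_clones(locus, [(1, len(locus) + 1)], vec)


def test_library_truth_and_errors():
    lay = syn.LibraryLayoutSpec(
        n_plates=2, positives=((1, 1, 1, "x"), (2, 16, 24, "x")), decoy_insert_len=200
    )
    lib = syn.generate_library(lay, {"x": "ACGT" * 100}, seed=1)
    assert len(lib.positives) == 2
    assert lib.wells[(1, 1, 1)] == "ACGT" * 100
    assert len(lib.wells) == 2 * 384
    with pytest.raises(InvalidSpecError):
        syn.LibraryLayoutSpec(
            n_plates=1, positives=((1, 1, 1, "x"), (1, 1, 1, "y"))
        ).validate()
    with pytest.raises(InvalidSpecError):
        syn.generate_library(lay, {}, seed=1)


def test_library_determinism():
    lay = syn.LibraryLayoutSpec(n_plates=1, positives=(), decoy_insert_len=150)
    a = syn.generate_library(lay, {}, seed=42)
    b = syn.generate_library(lay, {}, seed=42)
    assert a.wells == b.wells
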