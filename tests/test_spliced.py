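"""Spliced alignment: exactness, oracle equivalence, strand symmetry."""

import numpy as np
import pytest

from plegenes import synthetic as syn
from plegenes import tables
from plegenes._util import random_dna, revcomp, stable_rng
from plegenes.spliced import (
    AlignParams,
    annotate_contig,
    extract_regions,
    pairwise_identity,
    spliced_align,
)


def _toy_spec(seed, exons, introns, rate=0.0):
    return syn.SyntheticClusterSpec(
        gene_order=("PLE-1",),
        exon_sizes=tuple(exons),
        intron_sizes={"PLE-1": tuple(introns)},
        promoter_len=120,
        downstream_len=80,
        repeat_plant=syn.RepeatPlantSpec(length=20, copy1_start=-110, copy2_start=-40),
        primer_plant=syn.PrimerPlantSpec(products={}),
        point_mutation_rate=rate,
        seed=seed,
    )


def test_identity_alignment_single_exon():
    cdna = syn.generate_cdna([30, 30]).seq
    model = spliced_align(cdna, cdna)
    assert model.strand == "+"
    assert model.exons == ((1, 60),)
    assert model.introns == ()
    assert model.mismatch_count == 0
    assert model.alignment_score == 120


def test_toy_intron_anchored_equals_full_dp():
    # ~60-nt coding region interrupted by one 45-nt GT..AG intron
    spec = _toy_spec(17, [30, 30], [45])
    g, truth = syn.generate_gene(spec, "PLE-1")
    models = {
        mode: spliced_align(g, truth.cdna, AlignParams(mode=mode))
        for mode in ("anchored", "full_dp")
    }
    assert models["anchored"].exons == models["full_dp"].exons == truth.exons
    assert models["anchored"].alignment_score == models["full_dp"].alignment_score


@pytest.mark.parametrize("gene", ["PLE-1", "PLE-B9", "PLE-C4", "PLE-G2"])
def test_round_trip_recovery_all_genes(gene):
    spec = syn.SyntheticClusterSpec(seed=2024)
    g, truth = syn.generate_gene(spec, gene)
    model = spliced_align(g, truth.cdna)
    assert model.exons == truth.exons
    assert model.exon_sizes() == tables.exon_sizes(gene)
    assert model.intron_sizes() == tables.intron_sizes(gene)
    assert model.mismatch_count == 0
    model.validate(g)


def test_oracle_equivalence_on_random_toys():
    """Anchored mode reproduces the full-DP optimum on small planted genes."""
    mismatches = 0
    for seed in range(25):
        rng = np.random.default_rng(seed)
        n_ex = int(rng.integers(2, 5))
        exons = [int(rng.integers(18, 70)) for _ in range(n_ex)]
        exons[-1] += (3 - sum(exons) % 3) % 3
        introns = [int(rng.integers(45, 250)) for _ in range(n_ex - 1)]
        rate = 0.0 if seed % 2 else 0.005
        g, truth = syn.generate_gene(_toy_spec(seed, exons, introns, rate), "PLE-1")
        assert len(g) <= 3000
        a = spliced_align(g, truth.cdna, AlignParams(mode="anchored"))
        f = spliced_align(g, truth.cdna, AlignParams(mode="full_dp"))
        if (a.alignment_score, a.exons, a.strand) != (f.alignment_score, f.exons, f.strand):
            mismatches += 1
    assert mismatches == 0


def test_strand_symmetry(ple1_gene):
    g, truth = ple1_gene
    fwd = spliced_align(g, truth.cdna)
    rev = spliced_align(revcomp(g), truth.cdna)
    n = len(g)
    assert fwd.strand == "+" and rev.strand == "-"
    assert rev.exons == tuple(sorted((n - e + 1, n - s + 1) for s, e in fwd.exons))
    assert rev.alignment_score == fwd.alignment_score
    assert rev.cds_sequence == fwd.cds_sequence


def test_boundary_recovery_under_point_mutations():
    """Exon boundaries survive 0.5% substitution noise in nearly all genes.

    20 simulated genes (4 isoforms x 5 seeds, fixed); at least 19 must be
    recovered exactly, a deterministic stand-in for a >=95% recovery rate.
    """
    exact = total = 0
    for seed in (11, 22, 33, 44, 55):
        spec = syn.SyntheticClusterSpec(point_mutation_rate=0.005, seed=seed)
        for gene in ("PLE-1", "PLE-B9", "PLE-C4", "PLE-G2"):
            g, truth = syn.generate_gene(spec, gene)
            model = spliced_align(g, truth.cdna)
            total += 1
            exact += model.exons == truth.exons
    assert total == 20
    assert exact >= 19


def test_concatenated_exons_differ_by_mismatch_count():
    spec = syn.SyntheticClusterSpec(point_mutation_rate=0.005, seed=77)
    g, truth = syn.generate_gene(spec, "PLE-1")
    model = spliced_align(g, truth.cdna)
    assert model.exons == truth.exons
    cds = model.cds_sequence
    assert len(cds) == len(truth.cdna)
    subs = sum(1 for a, b in zip(cds, truth.cdna) if a != b)
    assert subs == model.mismatch_count > 0


def test_annotate_two_gene_cluster():
    spec = syn.SyntheticClusterSpec(gene_order=("PLE-1", "PLE-B9"), seed=6)
    locus, truth = syn.generate_cluster(spec)
    models = annotate_contig(locus, truth.genes[0].cdna, contig_id="locus")
    assert len(models) == 2
    for model, g in zip(models, truth.genes):
        assert model.exons == g.exons
        assert model.strand == g.strand


def test_annotate_minus_strand_gene():
    spec = syn.SyntheticClusterSpec(
        gene_order=("PLE-G2", "PLE-1", "PLE-B9"), strands={"PLE-1": "-"}, seed=9
    )
    locus, truth = syn.generate_cluster(spec)
    models = annotate_contig(locus, truth.genes[0].cdna, contig_id="locus")
    assert [m.strand for m in models] == [g.strand for g in truth.genes] == ["+", "-", "+"]
    for model, g in zip(models, truth.genes):
        assert model.exons == g.exons


def test_annotate_decoy_contig_is_empty():
    decoy = random_dna(stable_rng(123, "decoy"), 30000)
    cdna = syn.generate_cdna(tables.exon_sizes()).seq
    assert annotate_contig(decoy, cdna) == []


def test_no_gene_found_returns_empty_model():
    decoy = random_dna(stable_rng(5, "d"), 3000)
    cdna = syn.generate_cdna([30, 30]).seq
    model = spliced_align(decoy, cdna)
    assert model.is_empty and model.alignment_score == 0


def test_extract_regions_upstream_and_introns():
    spec = syn.SyntheticClusterSpec(seed=14)
    g, truth = syn.generate_gene(spec, "PLE-G2")
    model = spliced_align(g, truth.cdna)
    regions = extract_regions(model, g, upstream_len=6000)
    assert len(regions.upstream.seq) == 6000
    assert not regions.upstream.truncated
    assert regions.upstream.start_coord == -6000
    assert regions.upstream.seq == g[model.start - 6001 : model.start - 1]
    assert len(regions.introns) == 13
    assert len(regions.introns[1]) == 2195  # second intron of PLE-G2
    assert regions.cds == truth.cds


def test_extract_regions_truncates_at_contig_start():
    spec = _toy_spec(4, [30, 30], [60])
    g, truth = syn.generate_gene(spec, "PLE-1")
    model = spliced_align(g, truth.cdna)
    regions = extract_regions(model, g, upstream_len=5000)
    assert regions.upstream.truncated
    assert len(regions.upstream.seq) == model.start - 1


def test_pairwise_identity_examples():
    assert pairwise_identity("ACGTACGT", "ACGTACGT").percent == 100.0
    res = pairwise_identity("ACGT", "ACGA")
    assert res.percent == 75.0 and res.gaps == 0
    prot = "MWLRAFILATLSASHAQE" * 4
    assert pairwise_identity(prot, prot, alphabet="aa").percent == 100.0
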