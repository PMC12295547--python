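"""Region calling, consensus intervals, gene annotation and effect calls."""

import numpy as np
import pytest

from bsamap.bsa_statistics import smooth_track
from bsamap.qtl_mapping import (
    GeneModel,
    SignificantRegion,
    call_regions,
    candidate_filter,
    classify_effect,
    consensus_intervals,
    genes_in_interval,
    genotype_concordance,
    read_gene_models,
    region_to_bed_fields,
    spliced_cds,
    translate_cds,
    variants_in_genes,
)
from bsamap.variant_io import HOM_ALT, HOM_REF
from tests.test_variant_io import _rec


def _raw_track(pos, values, chrom="s1"):
    # bandwidth tiny so values pass through unsmoothed
    return smooth_track([chrom] * len(pos), pos, values, bandwidth=1e-3)


def _region(chrom, start, end, method="delta_snp_index"):
    return SignificantRegion(
        chrom=chrom, start=start, end=end, method=method,
        peak_pos=start, peak_value=1.0, n_sites=1,
    )


# ---------------------------------------------------------------------------
# region calling
# ---------------------------------------------------------------------------


def test_call_regions_empty_when_all_below_threshold():
    t = _raw_track([10, 20, 30], [0.1, 0.2, 0.1])
    assert call_regions(t, threshold=0.5) == []


def test_call_regions_isolated_site():
    t = _raw_track([10, 5000, 9000], [0.1, 0.9, 0.1])
    (region,) = call_regions(t, threshold=0.5, max_gap=100)
    assert (region.start, region.end, region.peak_pos) == (5000, 5000, 5000)
    assert region.n_sites == 1


def test_call_regions_threshold_tie_counts_as_significant():
    t = _raw_track([10], [0.5])
    assert len(call_regions(t, threshold=0.5)) == 1


def test_call_regions_merges_runs_within_max_gap():
    pos = [1000, 2000, 7000, 8000]
    values = [0.9, 0.9, 0.9, 0.9]
    t = _raw_track(pos, np.array([0.9, 0.2, 0.9, 0.9]))
    two = call_regions(t, threshold=0.5, max_gap=3000)
    assert len(two) == 2
    merged = call_regions(t, threshold=0.5, max_gap=10_000)
    assert len(merged) == 1
    assert (merged[0].start, merged[0].end) == (1000, 8000)
    assert merged[0].n_sites == 3  # the sub-threshold site is not a member
    t2 = _raw_track(pos, values)
    (single,) = call_regions(t2, threshold=0.5, max_gap=10_000)
    assert single.n_sites == 4


def test_call_regions_does_not_merge_across_scaffolds():
    t = smooth_track(["s1", "s2"], [100, 150], [0.9, 0.9], bandwidth=1e-3)
    assert len(call_regions(t, threshold=0.5, max_gap=10_000)) == 2


# ---------------------------------------------------------------------------
# consensus intervals
# ---------------------------------------------------------------------------


def test_consensus_four_way_intersection():
    regions = {
        "delta_snp_index": [_region("s19", 40_000, 56_000)],
        "ed": [_region("s19", 45_000, 60_000, "ed")],
        "g": [_region("s19", 44_000, 55_000, "g")],
        "fisher": [_region("s19", 45_000, 58_000, "fisher")],
    }
    (qtl,) = consensus_intervals(regions)
    assert (qtl.chrom, qtl.start, qtl.end) == ("s19", 45_000, 55_000)
    assert qtl.supporting_methods == frozenset(regions)


def test_consensus_empty_when_one_method_empty():
    regions = {
        "delta_snp_index": [_region("s1", 10, 20)],
        "ed": [_region("s1", 10, 20, "ed")],
        "g": [_region("s1", 10, 20, "g")],
        "fisher": [],
    }
    assert consensus_intervals(regions) == []
    assert len(consensus_intervals(regions, consensus_level=3)) == 1


def test_consensus_identical_regions_idempotent():
    regions = {m: [_region("s1", 100, 200, m)] for m in ("a", "b", "c", "d")}
    (qtl,) = consensus_intervals(regions)
    assert (qtl.start, qtl.end) == (100, 200)


def test_consensus_level_validation():
    with pytest.raises(ValueError):
        consensus_intervals({"a": []}, consensus_level=2)


def brute_force_consensus(regions_by_method, level, span=3000):
    coverage = np.zeros((len(regions_by_method), span + 2), dtype=bool)
    for i, regs in enumerate(regions_by_method.values()):
        for r in regs:
            coverage[i, r.start : r.end + 1] = True
    ok = coverage.sum(axis=0) >= level
    out = []
    start = None
    for pos in range(span + 2):
        if ok[pos] and start is None:
            start = pos
        elif not ok[pos] and start is not None:
            out.append((start, pos - 1))
            start = None
    return out


def test_consensus_matches_per_base_oracle():
    rng = np.random.default_rng(12)
    for trial in range(30):
        regions = {}
        for m in ("a", "b", "c", "d"):
            regs = []
            for _ in range(rng.integers(0, 4)):
                s = int(rng.integers(1, 2800))
                e = s + int(rng.integers(0, 400))
                regs.append(_region("s1", s, min(e, 3000), m))
            regions[m] = regs
        for level in (1, 2, 3, 4):
            got = [
                (q.start, q.end) for q in consensus_intervals(regions, level)
            ]
            assert got == brute_force_consensus(regions, level), (trial, level)


def test_bed_conversion():
    assert region_to_bed_fields("s1", 45_000, 55_000) == ("s1", 44_999, 55_000)
    with pytest.raises(ValueError):
        region_to_bed_fields("s1", 10, 5)


# ---------------------------------------------------------------------------
# genes in intervals
# ---------------------------------------------------------------------------


def test_five_genes_tile_the_causal_interval(small_sim):
    chrom, pos = small_sim.config.causal_locus
    hits = genes_in_interval(small_sim.genes, (chrom, pos - 2000, pos + 8000))
    assert len(hits) == 5
    assert [g.start for g in hits] == sorted(g.start for g in hits)


def test_gene_desert_and_edge_overlap(small_sim):
    chrom, pos = small_sim.config.causal_locus
    assert genes_in_interval(small_sim.genes, ("scaffold2", 1, 300_000)) == []
    causal_gene = small_sim.causal_gene
    # interval ending exactly at the gene start still overlaps by 1 bp
    hits = genes_in_interval(small_sim.genes, (chrom, 1, causal_gene.start))
    assert causal_gene.gene_id in {g.gene_id for g in hits}
    with pytest.raises(ValueError, match="unknown scaffold"):
        genes_in_interval(small_sim.genes, ("nope", 1, 10), known_chroms=["scaffold1"])


def test_read_gene_models_roundtrip(dataset_paths, small_sim):
    genes = read_gene_models(dataset_paths["gff"])
    assert len(genes) == len(small_sim.genes)
    by_id = {g.gene_id: g for g in genes}
    for g in small_sim.genes:
        got = by_id[g.gene_id]
        assert (got.chrom, got.start, got.end, got.strand) == (
            g.chrom, g.start, g.end, g.strand,
        )
        assert got.exons == g.exons
        assert got.cds == g.cds


# ---------------------------------------------------------------------------
# variant-to-feature assignment
# ---------------------------------------------------------------------------


def test_variants_in_genes_feature_labels(small_sim):
    gene = small_sim.causal_gene
    cds_pos = gene.cds[0][0]  # first CDS base
    intron_pos = gene.cds[0][1] + 1  # first intron base
    past_end = gene.end + 1
    variants = [
        _rec(chrom=gene.chrom, pos=cds_pos),
        _rec(chrom=gene.chrom, pos=intron_pos),
        _rec(chrom=gene.chrom, pos=past_end),
    ]
    got = variants_in_genes(variants, [gene])
    assert got[0].feature == "CDS" and got[0].cds_pos == 1
    assert got[1].feature == "intron" and got[1].gene_id == gene.gene_id
    # 1 bp past the gene end may fall in the next gene but not in this one
    assert got[2].feature == "intergenic" or got[2].gene_id != gene.gene_id


def test_variants_in_genes_warns_on_ragged_cds(small_sim):
    gene = small_sim.causal_gene
    bad = GeneModel(
        gene_id="bad", chrom=gene.chrom, start=gene.start, end=gene.end,
        strand="+", exons=gene.exons, cds=((gene.start, gene.start + 3, 0),),
    )
    with pytest.warns(UserWarning, match="divisible by 3"):
        variants_in_genes([], [bad])


# ---------------------------------------------------------------------------
# translation and effect classification
# ---------------------------------------------------------------------------


def test_translate_cds_basics(small_sim):
    cds = spliced_cds(small_sim.causal_gene, small_sim.genome)
    assert len(cds) == 1710
    assert len(translate_cds(cds)) == 569
    assert translate_cds("ATGTGA") == "M"
    assert translate_cds("ATGGCTTAA") == "MA"  # second residue alanine
    with pytest.raises(ValueError, match="divisible"):
        translate_cds("ATGT")
    with pytest.raises(ValueError, match="internal stop"):
        translate_cds("ATGTAATGA")
    with pytest.warns(UserWarning, match="ATG"):
        translate_cds("CTGTGA")


def test_causal_variant_is_codon41_ser_to_ala(small_sim):
    chrom, pos = small_sim.config.causal_locus
    variant = _rec(chrom=chrom, pos=pos, ref="T", alt="G")
    effect = classify_effect(variant, small_sim.causal_gene, small_sim.genome)
    assert effect.cds_pos == 121
    assert effect.codon_number == 41
    assert (effect.ref_aa, effect.alt_aa) == ("S", "A")
    assert effect.effect == "missense"


def test_third_position_wobble_is_synonymous(small_sim):
    chrom, pos = small_sim.config.causal_locus
    variant = _rec(chrom=chrom, pos=pos + 2, ref="T", alt="A")  # TCT -> TCA
    effect = classify_effect(variant, small_sim.causal_gene, small_sim.genome)
    assert effect.effect == "synonymous"
    assert effect.ref_aa == effect.alt_aa == "S"


def test_nonsense_and_ref_mismatch():
    genome = {"chr": "XX" + "ATGTACCCCTAA" + "XX"}  # gene at 3..14
    gene = GeneModel(
        gene_id="g", chrom="chr", start=3, end=14, strand="+",
        exons=((3, 14),), cds=((3, 14, 0),),
    )
    variant = _rec(chrom="chr", pos=8, ref="C", alt="A")  # TAC -> TAA
    effect = classify_effect(variant, gene, genome)
    assert effect.effect == "nonsense" and effect.codon_number == 2
    with pytest.raises(ValueError, match="REF mismatch"):
        classify_effect(_rec(chrom="chr", pos=8, ref="G", alt="A"), gene, genome)
    with pytest.raises(ValueError, match="outside the CDS"):
        classify_effect(_rec(chrom="chr", pos=1, ref="X", alt="A"), gene, genome)


def test_classify_effect_agrees_with_full_cds_translation(small_sim):
    """For CDS variants on both strands, the codon-level call must match
    re-translating the whole mutated CDS."""
    from Bio.Seq import Seq

    rng = np.random.default_rng(4)
    genome = small_sim.genome
    for gene in small_sim.genes:
        cds_positions = [s for s, e, _ in gene.cds] + [e for s, e, _ in gene.cds]
        cds_positions += [
            int(rng.integers(s, e + 1)) for s, e, _ in gene.cds for _ in range(3)
        ]
        for pos in cds_positions:
            ref = genome[gene.chrom][pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            effect = classify_effect(
                _rec(chrom=gene.chrom, pos=pos, ref=ref, alt=alt), gene, genome
            )
            mutated = dict(genome)
            seq = mutated[gene.chrom]
            mutated[gene.chrom] = seq[: pos - 1] + alt + seq[pos:]
            new_cds = spliced_cds(gene, mutated)
            old_cds = spliced_cds(gene, genome)
            c = effect.codon_number
            assert str(Seq(old_cds[3 * c - 3 : 3 * c]).translate()) == effect.ref_aa
            assert str(Seq(new_cds[3 * c - 3 : 3 * c]).translate()) == effect.alt_aa


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------


def _annotated(pos, effect_kind, codon, ad_F=(0, 60), ad_N=(60, 0), gene="gX"):
    from bsamap.qtl_mapping import EffectCall

    rec = _rec(pos=pos, pool_F_ad=ad_F, pool_N_ad=ad_N, oriented=True, a_is_alt=True)
    eff = EffectCall(
        effect=effect_kind, codon_number=codon, ref_aa="S", alt_aa="A",
        cds_pos=codon * 3 - 2, gene_id=gene,
    )
    return rec, eff


def test_candidate_filter_excludes_synonymous_and_discordant():
    table = candidate_filter(
        [
            _annotated(100, "missense", 10),
            _annotated(200, "synonymous", 11),
            _annotated(300, "missense", 12, ad_F=(30, 30), ad_N=(30, 30)),
        ]
    )
    assert table["pos"].tolist() == [100]


def test_candidate_filter_domain_breaks_association_ties():
    table = candidate_filter(
        [
            _annotated(100, "missense", 10, gene="g_other"),
            _annotated(200, "missense", 41, gene="g_causal"),
        ],
        domains={"g_causal": [(30, 80)]},
    )
    assert table.iloc[0]["gene_id"] == "g_causal"
    assert bool(table.iloc[0]["in_domain"])
    assert table["rank"].tolist() == [1, 2]


def test_candidate_filter_ranks_by_association_without_domains():
    table = candidate_filter(
        [
            _annotated(100, "missense", 10, ad_F=(10, 50), ad_N=(50, 10)),
            _annotated(200, "missense", 11, ad_F=(0, 60), ad_N=(60, 0)),
        ]
    )
    assert table.iloc[0]["pos"] == 200  # complete separation wins
    assert table.iloc[0]["delta_snp_index"] == pytest.approx(1.0)


def test_candidate_filter_empty_input():
    table = candidate_filter([])
    assert len(table) == 0


# ---------------------------------------------------------------------------
# genotype-phenotype concordance
# ---------------------------------------------------------------------------


def test_concordance_perfect_on_clean_simulation(small_sim):
    ci = small_sim.causal_index
    genotypes = {
        sid: ("F" if o else "N")
        for sid, o in zip(small_sim.strain_ids, small_sim.origins[:, ci])
    }
    phenotypes = dict(zip(small_sim.strain_ids, small_sim.phenotypes))
    frac, table = genotype_concordance(genotypes, phenotypes)
    assert frac == 1.0
    assert table.loc["F", "non_fruiting"] == 0
    assert table.loc["N", "fruiting"] == 0
    assert table.to_numpy().sum() == small_sim.config.n_progeny


def test_concordance_single_mismatch():
    ids = [f"s{i}" for i in range(156)]
    genotypes = {s: "F" for s in ids}
    phenotypes = {s: "fruiting" for s in ids}
    phenotypes[ids[0]] = "non_fruiting"
    frac, _ = genotype_concordance(genotypes, phenotypes)
    assert frac == pytest.approx(155 / 156)


def test_concordance_shuffled_phenotypes_near_half(small_sim):
    ci = small_sim.causal_index
    genotypes = {
        sid: ("F" if o else "N")
        for sid, o in zip(small_sim.strain_ids, small_sim.origins[:, ci])
    }
    rng = np.random.default_rng(9)
    shuffled = rng.permutation(small_sim.phenotypes)
    phenotypes = dict(zip(small_sim.strain_ids, shuffled))
    frac, _ = genotype_concordance(genotypes, phenotypes)
    assert 0.3 < frac < 0.7


def test_concordance_id_mismatch_raises():
    with pytest.raises(ValueError, match="s2"):
        genotype_concordance({"s1": "F"}, {"s1": "fruiting", "s2": "fruiting"})
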