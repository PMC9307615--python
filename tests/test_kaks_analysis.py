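import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from scvartools.concordance import ConditionVariantSet, merge_replicates
from scvartools.effect_annotator import AnnotatedVariant, VariantCall, classify
from scvartools.genome_model import AnnotatedGenome, DepthTrack, GeneRecord
from scvartools.kaks_analysis import (
    GeneKaKs,
    condition_covered_mask,
    format_ratio,
    genome_wide_kaks,
    per_gene_kaks,
    potential_sites,
    select_genes_of_interest,
)
from scvartools.synthetic_data import (
    SimConfig,
    build_genome,
    nonsynonymous_site_mutation,
    simulate,
    synonymous_site_mutation,
)

BASES = "ACGT"


def _merged_with_effects(n_ka: int, n_ks: int, condition="c") -> ConditionVariantSet:
    """A merged set with the requested effect counts, planted on a real
    genome and classified (not label-assigned)."""
    cfg = SimConfig(seed=101, n_contigs=1, contig_length=80_000, n_genes=30,
                    mean_gene_length=900, hotspot_genes=0, singleton_noise_rate=0)
    genome = build_genome(cfg, np.random.default_rng(101))
    rng = np.random.default_rng(202)
    cds = [g for g in genome.genes if g.kind == "CDS"]
    merged = ConditionVariantSet(condition=condition)
    taken: dict[str, set] = {g.gene_id: set() for g in cds}
    for i, want_syn in enumerate([False] * n_ka + [True] * n_ks):
        gene = cds[i % len(cds)]
        fn = synonymous_site_mutation if want_syn else nonsynonymous_site_mutation
        v = fn(genome, gene, rng, taken=taken[gene.gene_id])
        taken[gene.gene_id].add(v.pos)
        vc = VariantCall(v.contig, v.pos, v.ref, v.alt, condition=condition)
        merged.variants[vc.key] = vc
        merged.support[vc.key] = 2
    merged.annotate(genome)
    return merged, genome


class TestGenomeWideKaKs:
    @pytest.mark.parametrize(
        "ka,ks,expected",
        [(64, 117, "0.54"), (0, 10, "0.00")],
    )
    def test_counts_and_rounding(self, ka, ks, expected):
        merged, _ = _merged_with_effects(ka, ks)
        gw = genome_wide_kaks(merged)
        assert (gw.ka_total, gw.ks_total) == (ka, ks)
        assert format_ratio(gw.ratio) == expected

    def test_zero_ks_is_infinite_sentinel(self):
        merged, _ = _merged_with_effects(3, 0)
        gw = genome_wide_kaks(merged)
        assert math.isinf(gw.ratio)

    def test_requires_annotation(self):
        with pytest.raises(ValueError):
            genome_wide_kaks(ConditionVariantSet(condition="c"))

    def test_scaling_invariance(self):
        merged1, _ = _merged_with_effects(4, 10)
        merged2, _ = _merged_with_effects(8, 20)
        assert genome_wide_kaks(merged1).ratio == pytest.approx(
            genome_wide_kaks(merged2).ratio
        )


class TestPotentialSites:
    def test_gga_offset2_is_fourfold_degenerate(self):
        # gene of GGA codons only: every offset-2 position contributes 1.0 syn
        seq = "GGA" * 10
        genome = AnnotatedGenome({"c1": seq}, [GeneRecord("g", "c1", 0, 30, "+", "CDS")])
        syn, nonsyn = potential_sites(genome, genome.genes[0])
        # offsets 0 and 1 of GGA are non-degenerate (0 syn), offset 2 fully (1.0)
        assert syn == pytest.approx(10.0)
        assert nonsyn == pytest.approx(20.0)

    def test_zero_coverage_gives_zero_sites(self, toy_genome):
        gene = toy_genome.genes[0]
        mask = np.zeros(gene.length, dtype=bool)
        assert potential_sites(toy_genome, gene, mask) == (0.0, 0.0)

    def test_enumeration_oracle_full_coverage(self):
        """syn + nonsyn = gene length; equals brute force over 3L substitutions
        using Biopython translation."""
        cfg = SimConfig(seed=55, n_contigs=1, contig_length=20_000, n_genes=6,
                        mean_gene_length=300)
        genome = build_genome(cfg, np.random.default_rng(55))
        for gene in genome.genes:
            if gene.kind != "CDS":
                continue
            cds = genome.cds_sequence(gene)
            syn_bf = 0.0
            for i in range(len(cds)):
                ci, off = i // 3, i % 3
                codon = cds[3 * ci : 3 * ci + 3]
                aa = str(Seq(codon).translate(table=11))
                n_syn = sum(
                    str(Seq(codon[:off] + b + codon[off + 1 :]).translate(table=11)) == aa
                    for b in BASES
                    if b != codon[off]
                )
                syn_bf += n_syn / 3
            syn, nonsyn = potential_sites(genome, gene)
            assert syn == pytest.approx(syn_bf)
            assert syn + nonsyn == pytest.approx(gene.length)

    def test_strand_symmetric(self, toy_genome):
        gene_a = next(g for g in toy_genome.genes if g.gene_id == "geneA")
        gene_b = next(g for g in toy_genome.genes if g.gene_id == "geneB")
        assert potential_sites(toy_genome, gene_a) == pytest.approx(
            potential_sites(toy_genome, gene_b)
        )


class TestPerGeneKaKs:
    def test_planted_counts_recovered_noise_free(self):
        """10 synonymous + 2 non-synonymous planted in one gene ->
        unnormalized counts 10 and 2 after the full merge path."""
        cfg = SimConfig(seed=77, n_contigs=1, contig_length=50_000, n_genes=12,
                        mean_gene_length=600, hotspot_genes=0, singleton_noise_rate=0)
        genome = build_genome(cfg, np.random.default_rng(77))
        gene = next(g for g in genome.genes if g.kind == "CDS")
        rng = np.random.default_rng(88)
        taken: set = set()
        calls = []
        for want_syn in [True] * 10 + [False] * 2:
            fn = synonymous_site_mutation if want_syn else nonsynonymous_site_mutation
            v = fn(genome, gene, rng, taken=taken)
            taken.add(v.pos)
            calls.append(v)
        reps = [[VariantCall(v.contig, v.pos, v.ref, v.alt, condition="c", replicate=r)
                 for v in calls] for r in ("r1", "r2")]
        merged = merge_replicates(reps, condition="c")
        merged.annotate(genome)
        results, excluded = per_gene_kaks(genome, merged)
        row = next(r for r in results if r.gene_id == gene.gene_id)
        assert (row.ka_count, row.ks_count) == (2, 10)
        assert excluded == []
        # hand-computed rate ratio from the enumeration-backed site counts
        syn_sites, nonsyn_sites = potential_sites(genome, gene)
        assert row.ratio == pytest.approx((2 / nonsyn_sites) / (10 / syn_sites))

    def test_half_coverage_doubles_rates_keeps_ratio(self):
        """All variants in the covered half: rates ~double, ratio stays
        within the site-composition wobble of the two halves."""
        seq_codons = ["ATG"] + ["GGA", "GAA"] * 49 + ["TAA"]
        seq = "".join(seq_codons)
        genome = AnnotatedGenome({"c1": seq}, [GeneRecord("g", "c1", 0, len(seq), "+", "CDS")])
        gene = genome.genes[0]
        half = gene.length // 2
        mask_full = np.ones(gene.length, dtype=bool)
        mask_half = np.zeros(gene.length, dtype=bool)
        mask_half[:half] = True
        syn_f, nonsyn_f = potential_sites(genome, gene, mask_full)
        syn_h, nonsyn_h = potential_sites(genome, gene, mask_half)
        ka, ks = 2, 10  # all within the covered half
        rate_full = (ka / nonsyn_f, ks / syn_f)
        rate_half = (ka / nonsyn_h, ks / syn_h)
        assert rate_half[0] == pytest.approx(2 * rate_full[0], rel=0.05)
        assert rate_half[1] == pytest.approx(2 * rate_full[1], rel=0.05)
        assert (rate_half[0] / rate_half[1]) == pytest.approx(
            rate_full[0] / rate_full[1], rel=0.05
        )

    def test_uncovered_gene_excluded_and_listed(self, toy_genome):
        merged, genome = _merged_with_effects(1, 1)
        empty_track = DepthTrack("r1", {})
        results, excluded = per_gene_kaks(genome, merged, [empty_track, empty_track])
        assert results == []
        assert len(excluded) == sum(1 for g in genome.genes if g.kind == "CDS")

    def test_conservation_over_effect_classes(self, sim_bundle):
        genome = sim_bundle.genome
        for cond, reps in sim_bundle.calls.items():
            merged = merge_replicates(list(reps.values()), condition=cond)
            merged.annotate(genome)
            results, _ = per_gene_kaks(genome, merged)
            coding = sum(r.ka_count + r.ks_count for r in results)
            others = sum(
                1 for a in merged.annotations.values()
                if a.effect not in ("synonymous", "non_synonymous")
            )
            assert coding + others == len(merged)


class TestCoveredMask:
    def test_requires_two_replicates(self):
        t_cov = DepthTrack("a", {"c1": np.array([[0, 100, 5]])})
        t_un = DepthTrack("b", {})
        gene = GeneRecord("g", "c1", 0, 60, "+", "CDS")
        assert condition_covered_mask(gene, [t_cov, t_un]).sum() == 0
        assert condition_covered_mask(gene, [t_cov, t_cov]).sum() == 60


class TestSelectGenesOfInterest:
    def _row(self, gene_id, cond, ka, ks, syn_sites=100.0, nonsyn_sites=200.0):
        return GeneKaKs(gene_id, cond, ka, ks, 1.0, syn_sites, nonsyn_sites)

    def test_syn_dense_across_three_conditions(self):
        # ratios ~0.13/0.11/0.13-style: heavily synonymous in all conditions
        per_cond = {
            c: [self._row("tnp", c, 1, 15)] for c in ("a", "b", "c")
        }
        (goi,) = select_genes_of_interest(per_cond)
        assert goi.gene_id == "tnp"
        assert goi.direction == "synonymous_dense"
        assert goi.n_conditions == 3

    def test_boundary_ratio_one_excluded(self):
        # ka_rate == ks_rate -> ratio exactly 1 -> neither class
        per_cond = {c: [self._row("g", c, 2, 1, syn_sites=100, nonsyn_sites=200)]
                    for c in ("a", "b", "c")}
        assert per_cond["a"][0].ratio == pytest.approx(1.0)
        assert select_genes_of_interest(per_cond) == []

    def test_boundary_syn_dense_excluded(self):
        # powers of two keep the ratio an exact double equal to the threshold
        per_cond = {c: [self._row("g", c, 1, 5, syn_sites=64.0, nonsyn_sites=64.0)]
                    for c in ("a", "b")}
        assert per_cond["a"][0].ratio == pytest.approx(0.2)
        assert select_genes_of_interest(per_cond) == []

    def test_zero_ka_with_variants_is_syn_dense(self):
        per_cond = {c: [self._row("btuD", c, 0, 3)] for c in ("a", "b")}
        (goi,) = select_genes_of_interest(per_cond)
        assert goi.direction == "synonymous_dense"

    def test_no_variants_never_selected(self):
        per_cond = {c: [self._row("g", c, 0, 0)] for c in ("a", "b", "c")}
        assert select_genes_of_interest(per_cond) == []

    def test_nonsyn_enriched(self):
        per_cond = {c: [self._row("g", c, 20, 1)] for c in ("a", "b")}
        (goi,) = select_genes_of_interest(per_cond)
        assert goi.direction == "non_synonymous_enriched"

    def test_planted_recovery_no_noise(self):
        cfg = SimConfig(seed=31, n_contigs=1, contig_length=80_000, n_genes=30,
                        mean_gene_length=600, hotspot_genes=4,
                        hotspot_variants_per_gene=10, singleton_noise_rate=0,
                        replicate_detection_prob=1.0, breadth_mean=1.0)
        res = simulate(cfg)
        per_cond = {}
        for cond, reps in res.calls.items():
            merged = merge_replicates(list(reps.values()), condition=cond)
            merged.annotate(res.genome)
            results, _ = per_gene_kaks(res.genome, merged, list(res.tracks[cond].values()))
            per_cond[cond] = results
        selected = {g.gene_id for g in select_genes_of_interest(per_cond)
                    if g.direction == "synonymous_dense"}
        assert selected == set(res.truth.hotspot_gene_ids)
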