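"""Mutation classification under the vertebrate mitochondrial code,
NG86 site counting, Ka/Ks, and the rank-sum / gene-set comparisons."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.stats import hypergeom

from mitovar.fixtures import synthetic_reference
from mitovar.reference import MitoReference
from mitovar.selection import (
    GeneAnnotation,
    Mutation,
    classify,
    dedup,
    enumerate_coding_changes,
    geneset_compare,
    ka_ks,
    load_gene_annotations,
    maf_compare,
    ng86_site_counts,
)

# no start/stop requirements are imposed on toy genes; vertebrate mito
# code stops (TAA, TAG, AGA, AGG) are simply avoided inside them
TOY_SEQ = "ATGGCTGCAAAATTTCGATGGCATGTTCCC"  # 10 codons
TOY_REF = MitoReference(sequence=TOY_SEQ, name="toy")
TOY_GENE = [GeneAnnotation(gene="toy", start=1, end=30, strand="+")]


def brute_force_category(reference, gene, position, alt):
    """Oracle: translate the whole (rev-complemented if needed) gene
    before and after the mutation with Biopython, table 2."""
    seq = list(reference.sequence)
    seq[position - 1] = alt
    mutated = "".join(seq)

    def protein(s):
        cds = s[gene.start - 1 : gene.end]
        if gene.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        pad = (3 - len(cds) % 3) % 3
        return str(Seq(cds + "A" * pad).translate(table=2))

    return "S" if protein(reference.sequence) == protein(mutated) else "NS"


class TestClassify:
    def test_synonymous_third_position(self):
        # codon 2 GCT -> GCC, both Ala
        ann = classify(6, "T", "C", TOY_GENE, TOY_REF)
        assert ann.category == "S"
        assert ann.genes == ("toy",)

    def test_noncoding_outside_any_gene(self):
        gene = [GeneAnnotation(gene="toy", start=1, end=15, strand="+")]
        ann = classify(20, TOY_REF.base(20), "A", gene, TOY_REF)
        assert ann.category == "NC"
        assert ann.genes == ()

    def test_agrees_with_full_gene_translation(self, rng):
        """Every possible change in the toy gene, forward and reverse
        strand annotations, versus the brute-force translation oracle."""
        for strand in "+-":
            gene = GeneAnnotation(gene="toy", start=1, end=30, strand=strand)
            for pos in range(1, 31):
                ref_base = TOY_REF.base(pos)
                for alt in "ACGT":
                    if alt == ref_base:
                        continue
                    got = classify(pos, ref_base, alt, [gene], TOY_REF).category
                    want = brute_force_category(TOY_REF, gene, pos, alt)
                    assert got == want, (strand, pos, ref_base, alt)

    def test_fourfold_third_positions_all_synonymous(self):
        # GCN = Ala and GTN = Val: every third-position change is S
        ref = MitoReference(sequence="GCTGTA", name="ff")
        gene = [GeneAnnotation(gene="ff", start=1, end=6, strand="+")]
        for pos in (3, 6):
            for alt in "ACGT":
                if alt == ref.base(pos):
                    continue
                assert classify(pos, ref.base(pos), alt, gene, ref).category == "S"

    def test_first_positions_of_nondegenerate_codons_nonsynonymous(self):
        # AAA (Lys) and TTT (Phe): first-position changes always alter the aa
        ref = MitoReference(sequence="AAATTT", name="nd")
        gene = [GeneAnnotation(gene="nd", start=1, end=6, strand="+")]
        for pos in (1, 4):
            for alt in "ACGT":
                if alt == ref.base(pos):
                    continue
                assert classify(pos, ref.base(pos), alt, gene, ref).category == "NS"

    def test_overlapping_genes_any_rule(self):
        # S overall only if synonymous in BOTH frames
        ref = MitoReference(sequence="ATGGCTGCAAAA", name="ov")
        genes = [
            GeneAnnotation(gene="g1", start=1, end=12, strand="+"),
            GeneAnnotation(gene="g2", start=2, end=10, strand="+"),
        ]
        ann = classify(6, ref.base(6), "C", genes, ref)
        assert set(ann.genes) == {"g1", "g2"}
        # GCT->GCC is silent in g1's frame but codon 2 of g2 ("TGC"->"CGC"
        # frame shift view) need not be; oracle decides
        want = (
            "S"
            if all(
                brute_force_category(ref, g, 6, "C") == "S" for g in genes
            )
            else "NS"
        )
        assert ann.category == want

    def test_reference_mismatch_and_range_errors(self):
        with pytest.raises(ValueError):
            classify(1, "C", "G", TOY_GENE, TOY_REF)  # actual base is A
        with pytest.raises(IndexError):
            classify(31, "A", "G", TOY_GENE, TOY_REF)

    def test_real_annotation_positions(self, ref):
        """The three recurrent tumor positions: 3424 lies in ND1, 14804
        in CYB, 16117 in the noncoding control region."""
        annotations = load_gene_annotations()
        for pos, gene in ((3424, "ND1"), (14804, "CYB")):
            base = ref.base(pos)
            alt = "A" if base != "A" else "G"
            ann = classify(pos, base, alt, annotations, ref)
            assert gene in ann.genes
            assert ann.category in ("S", "NS")
        base = ref.base(16117)
        ann = classify(16117, base, "C" if base != "C" else "T", annotations, ref)
        assert ann.category == "NC"

    def test_atp8_atp6_overlap_annotated_with_both(self, ref):
        annotations = load_gene_annotations()
        base = ref.base(8530)
        alt = "A" if base != "A" else "C"
        ann = classify(8530, base, alt, annotations, ref)
        assert set(ann.genes) >= {"ATP8", "ATP6"}


class TestDedup:
    def test_shared_mutation_counted_once_with_occurrences(self):
        muts = [Mutation(14804, "G", "A", sample=f"s{i}") for i in range(23)]
        out = dedup(muts)
        assert len(out) == 1
        assert out[0].sample.count(",") == 22

    def test_disjoint_sets_concatenate(self):
        muts = [Mutation(1, "A", "C", "x"), Mutation(2, "C", "G", "y")]
        assert len(dedup(muts)) == 2

    def test_empty_input(self):
        assert dedup([]) == []

    def test_same_position_different_alt_kept_separate(self):
        muts = [Mutation(5, "A", "C", "x"), Mutation(5, "A", "G", "y")]
        assert len(dedup(muts)) == 2


class TestNg86:
    @pytest.mark.parametrize(
        "codon,n_exp,s_exp",
        [
            # hand-counted under the vertebrate mitochondrial code
            ("TTT", 8 / 3, 1 / 3),  # Phe: only TTC is silent
            ("GCT", 2.0, 1.0),      # Ala: third position fourfold
            ("ATG", 3.0, 0.0),      # Met (ATA is Met too -> 1/3? see below)
        ],
    )
    def test_single_codon_site_counts(self, codon, n_exp, s_exp):
        if codon == "ATG":
            # mito code: ATA is also Met, so third position has 1 of 3 silent
            n_exp, s_exp = 3 - 1 / 3, 1 / 3
        n, s = ng86_site_counts(codon)
        assert n == pytest.approx(n_exp)
        assert s == pytest.approx(s_exp)
        assert n + s == pytest.approx(3.0)

    def test_site_counts_are_additive_over_codons(self):
        n1, s1 = ng86_site_counts("TTT")
        n2, s2 = ng86_site_counts("GCT")
        n12, s12 = ng86_site_counts("TTTGCT")
        assert n12 == pytest.approx(n1 + n2)
        assert s12 == pytest.approx(s1 + s2)

    def test_length_not_codon_multiple_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("ACGTA")


class TestKaKs:
    def test_hand_computed_toy_ratio(self):
        """One S and one NS mutation on the 10-codon toy gene: the ratio
        must equal (1/N_sites)/(1/S_sites) with hand-verifiable sites."""
        n_sites, s_sites = ng86_site_counts(TOY_SEQ)
        muts = [
            Mutation(6, "T", "C"),   # GCT->GCC, S
            Mutation(1, "A", "C"),   # ATG->CTG, M->L, NS
        ]
        res = ka_ks(muts, TOY_GENE, TOY_REF, n_resamples=200, seed=0)
        assert (res.ns_observed, res.s_observed) == (1, 1)
        assert res.ka == pytest.approx(1 / n_sites)
        assert res.ks == pytest.approx(1 / s_sites)
        assert res.ratio == pytest.approx(s_sites / n_sites)

    def test_only_synonymous_mutations_give_zero_ka(self):
        muts = [Mutation(6, "T", "C")]
        res = ka_ks(muts, TOY_GENE, TOY_REF, n_resamples=50, seed=0)
        assert res.ka == 0.0
        assert res.ratio == 0.0

    def test_no_synonymous_mutations_flagged_undefined(self):
        muts = [Mutation(1, "A", "C")]
        res = ka_ks(muts, TOY_GENE, TOY_REF, n_resamples=50, seed=0)
        assert res.ratio is None

    def test_noncoding_mutations_ignored(self):
        gene = [GeneAnnotation(gene="toy", start=1, end=15, strand="+")]
        res = ka_ks([Mutation(20, TOY_REF.base(20), "A")], gene, TOY_REF,
                    n_resamples=10, seed=0)
        assert res.ratio is None and res.ns_observed == res.s_observed == 0

    def test_bootstrap_ci_reproducible_and_brackets_estimate(self, rng):
        ref = synthetic_reference(length=3000, seed=5, n_positions=())
        gene = [GeneAnnotation(gene="g", start=1, end=2999, strand="+")]
        pool = enumerate_coding_changes(gene, ref)
        idx = rng.choice(len(pool), size=120, replace=False)
        muts = [pool[i] for i in idx]
        r1 = ka_ks(muts, gene, ref, n_resamples=400, seed=7)
        r2 = ka_ks(muts, gene, ref, n_resamples=400, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.ratio <= r1.ci_high
        assert r1.n_valid_resamples > 350


class TestMafCompare:
    def test_identical_groups_p_one(self):
        assert maf_compare([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == pytest.approx(1.0)

    def test_fully_separated_five_vs_five_exact_p(self):
        a = [0.01, 0.02, 0.03, 0.04, 0.05]
        b = [0.11, 0.12, 0.13, 0.14, 0.15]
        # exact two-sided: 2 / C(10, 5)
        assert maf_compare(a, b) == pytest.approx(2 / 252, rel=1e-6)

    def test_invariant_to_monotone_transform(self, rng):
        a = rng.uniform(0.01, 0.5, 12)
        b = rng.uniform(0.01, 0.5, 15)
        assert maf_compare(a, b) == pytest.approx(maf_compare(a**2, b**2))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            maf_compare([], [0.1])


class TestGenesetCompare:
    def test_published_ns_s_table_not_significant(self):
        # 9 NS / 3 S in the mito-gene set vs 199 NS / 44 S elsewhere
        _, p_prop = geneset_compare([1.0], [1.0], (9, 3), (199, 44))
        assert p_prop > 0.05

    def test_identical_proportions_p_one(self):
        _, p_prop = geneset_compare([1.0], [1.0], (10, 5), (20, 10))
        assert p_prop == pytest.approx(1.0)

    def test_fisher_agrees_with_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals the sum of hypergeometric point
        probabilities no larger than the observed table's."""
        a, b, c, d = 9, 3, 199, 44
        n_total, k_row, k_col = a + b + c + d, a + b, a + c
        probs = [
            hypergeom.pmf(x, n_total, k_row, k_col)
            for x in range(max(0, k_row + k_col - n_total), min(k_row, k_col) + 1)
        ]
        obs = hypergeom.pmf(a, n_total, k_row, k_col)
        expected = sum(p for p in probs if p <= obs * (1 + 1e-9))
        _, p_prop = geneset_compare([1.0], [1.0], (a, b), (c, d))
        assert p_prop == pytest.approx(expected, rel=1e-6)
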