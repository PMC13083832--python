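import numpy as np
import pandas as pd
import pytest

from kdrkit.core_io import MISSING, GeneModel, VariantRecord
from kdrkit.effects_freqs import (
    allele_frequencies,
    annotate_effects,
    filter_by_frequency,
    frequency_matrix,
)

import _oracles
from conftest import make_genotypes, make_samples


def plus_model(seq="GTGGGAGCTTGGTAA"):
    # single-exon +strand gene at chr positions 11..25
    return GeneModel("tx1", "2L", "+", [(11, 25)], cds_seq=seq)


class TestAnnotateEffects:
    def test_triallelic_v402l_both_changes_nonsynonymous(self):
        # codon 1 GTG (Val); G>T -> TTG Leu, G>C -> CTG Leu: two records
        m = plus_model()
        effs = annotate_effects([VariantRecord("2L", 11, "G", ("T", "C"))], m)
        assert [(e.effect, e.ref_aa, e.alt_aa) for e in effs] == [
            ("nonsynonymous", "V", "L"),
            ("nonsynonymous", "V", "L"),
        ]
        assert {e.allele_index for e in effs} == {1, 2}

    def test_third_base_wobble_synonymous(self):
        # codon 2 GGA (Gly); third base A>G -> GGG Gly
        m = plus_model()
        effs = annotate_effects([VariantRecord("2L", 16, "A", ("G",))], m)
        assert effs[0].effect == "synonymous"
        assert effs[0].codon_number == 2

    def test_minus_strand_annotates_via_reverse_complement(self):
        # -strand gene over 11..19; CDS (transcript orientation) = revcomp
        plus_seq = "GTGGGAGCT"
        import kdrkit.core_io as cio

        m = GeneModel("tx2", "2L", "-", [(11, 19)], cds_seq=cio.revcomp(plus_seq))
        # genomic C>A at position 13 -> transcript base G>T in codon 3
        # cds = AGCTCCCAC; codon 3 = CAC (His); genomic pos 13 -> cds index 6
        effs = annotate_effects([VariantRecord("2L", 13, "G", ("T",))], m)
        e = effs[0]
        assert e.codon_number == 3
        # manual: codon CAC (H) -> AAC (N): nonsynonymous
        assert (e.ref_aa, e.alt_aa, e.effect) == ("H", "N", "nonsynonymous")

    def test_noncoding_and_indels(self):
        m = plus_model()
        effs = annotate_effects([VariantRecord("2L", 5, "A", ("T",))], m)
        assert effs[0].effect == "non_coding"
        with pytest.warns(UserWarning, match="non-SNP"):
            effs = annotate_effects([VariantRecord("2L", 11, "G", ("GA",))], m)
        assert effs == []

    def test_involution_consistency(self):
        # applying alt then the reverse substitution restores ref_aa
        m = plus_model()
        fwd = annotate_effects([VariantRecord("2L", 12, "T", ("A",))], m)[0]
        mutated_seq = m.cds_seq[:1] + "A" + m.cds_seq[2:]
        m2 = GeneModel("tx1", "2L", "+", [(11, 25)], cds_seq=mutated_seq)
        back = annotate_effects([VariantRecord("2L", 12, "A", ("T",))], m2)[0]
        assert back.alt_aa == fwd.ref_aa


def cohort_fixture():
    """120 diploids, one site with a singleton alt + one triallelic site."""
    calls_single = [[0, 0]] * 119 + [[0, 1]]
    # triallelic: counts over 240 chromosomes: alt1 24 (0.1), alt2 84 (0.35)
    calls_tri = [[1, 1]] * 12 + [[2, 2]] * 42 + [[0, 0]] * 66
    g = make_genotypes(
        np.array([calls_single, calls_tri]), n_alleles=[2, 3]
    )
    samples = make_samples(
        [{"sample_id": f"s{j}", "taxon": "coluzzii", "site": "Bana"} for j in range(120)]
    )
    return g, samples


class TestAlleleFrequencies:
    def test_singleton_among_240_chromosomes(self):
        g, samples = cohort_fixture()
        t = allele_frequencies(g, samples, grouping="taxon")
        row = t[(t["pos"] == 100) & (t["change"] == "A>C")].iloc[0]
        assert row["frequency"] == pytest.approx(1 / 240)
        assert round(row["frequency"], 6) == 0.004167
        assert row["n_chromosomes"] == 240

    def test_monomorphic_reference_site_zero(self):
        g = make_genotypes([[[0, 0], [0, 0]]])
        samples = make_samples(
            [{"sample_id": "s0", "taxon": "coluzzii", "site": "B"},
             {"sample_id": "s1", "taxon": "coluzzii", "site": "B"}]
        )
        t = allele_frequencies(g, samples, grouping="taxon")
        assert t.iloc[0]["frequency"] == 0.0

    def test_triallelic_cumulative_row_is_additive(self):
        g, samples = cohort_fixture()
        t = allele_frequencies(g, samples, grouping="taxon")
        tri = t[t["pos"] == 101]
        per_allele = tri[tri["change"] != "cumulative"]["frequency"]
        cum = tri[tri["change"] == "cumulative"]["frequency"].iloc[0]
        assert sorted(np.round(per_allele, 6)) == [0.1, 0.35]
        assert cum == pytest.approx(0.45)

    def test_per_site_frequency_conservation(self, two_background_cohort):
        _, c = two_background_cohort
        t = allele_frequencies(c.genotypes, c.samples, grouping="taxon_site")
        for (gname, pos), sub in t.groupby(["group", "pos"]):
            alts = sub[sub["change"] != "cumulative"]["frequency"].sum()
            assert 0.0 <= alts <= 1.0 + 1e-9

    def test_zero_chromosome_group_gets_nan(self):
        g = make_genotypes([[[MISSING, MISSING], [0, 1]]])
        samples = make_samples(
            [{"sample_id": "s0", "taxon": "coluzzii", "site": "B"},
             {"sample_id": "s1", "taxon": "gambiae_ss", "site": "B"}]
        )
        t = allele_frequencies(g, samples, grouping="taxon")
        col = t[t["group"] == "coluzzii"].iloc[0]
        assert np.isnan(col["frequency"]) and col["n_chromosomes"] == 0

    def test_recovers_generator_marginals_within_3se(self, two_background_cohort, kdr_cfg):
        spec, c = two_background_cohort
        t = allele_frequencies(c.genotypes, c.samples, grouping="taxon_site",
                               named_alleles=kdr_cfg)
        # 995F marginal in the coluzzii/Bana group: 0.4 (FL1T carries F)
        row = t[(t["group"] == "coluzzii/Bana") & (t["aa_label"] == "995F")].iloc[0]
        n = row["n_chromosomes"]
        se = np.sqrt(0.4 * 0.6 / n)
        assert abs(row["frequency"] - 0.4) < 3 * se


class TestFilterByFrequency:
    def make_table(self, freqs):
        return pd.DataFrame(
            {
                "group": ["g"] * len(freqs),
                "chrom": ["2L"] * len(freqs),
                "pos": range(len(freqs)),
                "change": ["A>T"] * len(freqs),
                "aa_label": [""] * len(freqs),
                "frequency": freqs,
                "n_chromosomes": [100] * len(freqs),
            }
        )

    def test_threshold_is_strict(self):
        t = self.make_table([0.05, 0.051])
        kept = filter_by_frequency(t)
        assert list(kept["pos"]) == [1]

    def test_kept_if_common_in_any_group(self):
        t = pd.concat(
            [self.make_table([0.2]), self.make_table([0.01]).assign(group="h")]
        )
        kept = filter_by_frequency(t)
        assert set(kept["group"]) == {"g", "h"}  # row kept in every group

    def test_survivor_set_matches_brute_force(self):
        rng = np.random.default_rng(3)
        freqs = rng.random(25)
        t = self.make_table(freqs)
        kept = filter_by_frequency(t, 0.5)
        assert set(kept["pos"]) == {i for i, f in enumerate(freqs) if f > 0.5}
        assert kept.attrs["n_surviving_alleles"] == len(set(kept["pos"]))


class TestFrequencyMatrix:
    def base_table(self, data, groups):
        rows = []
        for i, vals in enumerate(data):
            for g, f in zip(groups, vals):
                rows.append(
                    {"group": g, "chrom": "2L", "pos": i, "change": "A>T",
                     "aa_label": "", "frequency": f, "n_chromosomes": 10}
                )
        return pd.DataFrame(rows)

    def test_identical_rows_are_adjacent_leaves(self):
        t = self.base_table(
            [[0.9, 0.1, 0.0], [0.9, 0.1, 0.0], [0.0, 0.0, 0.9]], ["a", "b", "c"]
        )
        mat, row_order, _, _, _ = frequency_matrix(t)
        labels = list(mat.index)
        i0 = row_order.index(labels.index("2L:0:A>T"))
        i1 = row_order.index(labels.index("2L:1:A>T"))
        assert abs(i0 - i1) == 1

    def test_linkage_heights_match_exhaustive_agglomeration(self):
        rng = np.random.default_rng(5)
        t = self.base_table(rng.random((4, 3)), ["a", "b", "c"])
        mat, _, _, row_Z, _ = frequency_matrix(t)
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(mat.to_numpy()))
        expected = _oracles.brute_average_linkage(D)
        assert sorted(row_Z[:, 2]) == pytest.approx(expected)

    def test_constant_matrix_deterministic_order(self):
        t = self.base_table(np.full((3, 2), 0.5), ["a", "b"])
        out1 = frequency_matrix(t)
        out2 = frequency_matrix(t)
        assert out1[1] == out2[1] and out1[2] == out2[2]

    def test_single_row_identity_ordering(self):
        t = self.base_table([[0.5, 0.1]], ["a", "b"])
        mat, row_order, col_order, row_Z, _ = frequency_matrix(t)
        assert row_order == [0] and row_Z is None
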