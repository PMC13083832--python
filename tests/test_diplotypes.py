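import itertools

import numpy as np
import pytest

from kdrkit.core_io import MISSING
from kdrkit.diplotypes import (
    call_diplotypes,
    default_kdr_config,
    diplotype_clustering,
    diplotype_frequencies,
    pca_dosage,
)
from kdrkit.simgen import CohortGroupSpec, KdrCohortSpec, simulate_kdr_cohort

import _oracles
from conftest import make_genotypes, make_samples


def kdr_matrix(genotypes_by_label, cfg, phased=False):
    """Build a genotype/haplotype matrix over the three configured kdr loci.

    ``genotypes_by_label``: per sample, a pair of label strings (phased) —
    converted to matrices in config locus order sorted by position."""
    loci_sorted = sorted(cfg.loci, key=lambda l: l.pos)
    order = [cfg.loci.index(l) for l in loci_sorted]
    records = [l.variant_record() for l in loci_sorted]
    from kdrkit.core_io import GenotypeMatrix, HaplotypeMatrix

    n = len(genotypes_by_label)
    haps = np.zeros((len(loci_sorted), 2 * n), dtype=np.int16)
    for j, (h1, h2) in enumerate(genotypes_by_label):
        for hap_i, lab in enumerate((h1, h2)):
            idx = cfg.label_to_indices(lab)
            haps[:, 2 * j + hap_i] = [idx[k] for k in order]
    ids = [f"s{j}" for j in range(n)]
    hm = HaplotypeMatrix(records, haps, ids, phased=True)
    return hm if phased else hm.to_genotypes()


class TestPhasedCalls:
    def test_reads_labels_off_haplotype_columns(self, kdr_cfg):
        hm = kdr_matrix([("FL1T", "LVI")], kdr_cfg, phased=True)
        calls, excluded = call_diplotypes(hm, kdr_cfg)
        assert excluded == []
        assert calls[0].group_label == "FL1T/LVI"
        assert calls[0].phase_source == "phased_input"

    def test_homozygous_resistant_and_wild_type(self, kdr_cfg):
        hm = kdr_matrix([("FVI", "FVI"), ("LVI", "LVI")], kdr_cfg, phased=True)
        calls, _ = call_diplotypes(hm, kdr_cfg)
        assert [c.group_label for c in calls] == ["FVI/FVI", "LVI/LVI"]

    def test_group_label_symmetric_in_order(self, kdr_cfg):
        a = kdr_matrix([("FL1T", "LVI")], kdr_cfg, phased=True)
        b = kdr_matrix([("LVI", "FL1T")], kdr_cfg, phased=True)
        ca, _ = call_diplotypes(a, kdr_cfg)
        cb, _ = call_diplotypes(b, kdr_cfg)
        assert ca[0].group_label == cb[0].group_label

    def test_accuracy_is_total_on_simulated_truth(self, two_background_cohort, kdr_cfg):
        _, c = two_background_cohort
        calls, excluded = call_diplotypes(c.haplotypes, kdr_cfg)
        assert not excluded
        truth = dict(zip(c.truth["sample_id"], c.truth["group_label"]))
        assert all(truth[x.sample_id] == x.group_label for x in calls)


class TestUnphasedCalls:
    def test_single_het_locus_is_unambiguous(self, kdr_cfg):
        gm = kdr_matrix([("FVI", "LVI")], kdr_cfg)
        calls, _ = call_diplotypes(gm, kdr_cfg)
        assert calls[0].phase_source == "unambiguous"
        assert calls[0].group_label == "FVI/LVI"

    def test_missing_genotype_excludes_sample_with_reason(self, kdr_cfg):
        gm = kdr_matrix([("FVI", "LVI")], kdr_cfg)
        gm.calls[0, 0] = (MISSING, MISSING)
        calls, excluded = call_diplotypes(gm, kdr_cfg)
        assert calls == []
        assert excluded[0][0] == "s0" and "missing" in excluded[0][1]

    def test_triple_het_resolved_by_cohort_em_matches_enumeration(self, kdr_cfg):
        # cohort: many FL1T/FL1T and LVI/LVI homozygotes fix the label pool;
        # one triple heterozygote must resolve to FL1T/LVI
        cohort = [("FL1T", "FL1T")] * 10 + [("LVI", "LVI")] * 10 + [("FL1T", "LVI")]
        gm = kdr_matrix(cohort, kdr_cfg)
        calls, _ = call_diplotypes(gm, kdr_cfg)
        trip = calls[-1]
        assert trip.phase_source == "em_resolved"
        assert trip.group_label == "FL1T/LVI"
        # exhaustive Bayes oracle: plug in directly-counted unambiguous
        # haplotype frequencies, score every compatible pair
        freqs = {"FL1T": 20 / 42, "LVI": 20 / 42}
        pairs = {}
        for h1_syms in itertools.product(*[["F", "L"], ["L1", "V"], ["T", "I"]]):
            h1 = "".join(h1_syms)
            h2 = "".join(
                {"F": "L", "L": "F"}[h1_syms[0]]
                + {"L1": "V", "V": "L1"}[h1_syms[1]]
                + {"T": "I", "I": "T"}[h1_syms[2]]
            )
            key = tuple(sorted((h1, h2)))
            pairs[key] = freqs.get(h1, 1 / 42) * freqs.get(h2, 1 / 42)
        best = max(pairs, key=pairs.get)
        assert set(best) == {trip.hap1_label, trip.hap2_label}
        assert trip.posterior > trip.runner_up_prob

    def test_em_accuracy_on_two_background_cohort(self, two_background_cohort, kdr_cfg):
        _, c = two_background_cohort
        calls, _ = call_diplotypes(c.genotypes, kdr_cfg)
        truth = dict(zip(c.truth["sample_id"], c.truth["group_label"]))
        acc = np.mean([truth[x.sample_id] == x.group_label for x in calls])
        assert acc >= 0.95


class TestDiplotypeFrequencies:
    def test_112_of_113_gives_0991(self, kdr_cfg):
        labels = [("FVI", "FVI")] * 112 + [("FVI", "LVI")]
        hm = kdr_matrix(labels, kdr_cfg, phased=True)
        calls, _ = call_diplotypes(hm, kdr_cfg)
        samples = make_samples(
            [{"sample_id": f"s{j}", "taxon": "gambiae_ss", "site": "x"} for j in range(113)]
        )
        t = diplotype_frequencies(calls, samples, grouping="taxon", od_min_count=0)
        row = t[t["diplotype"] == "FVI/FVI"].iloc[0]
        assert row["count"] == 112 and row["n_classified"] == 113
        assert round(row["frequency"], 3) == 0.991

    def test_single_sample_frequency_one(self, kdr_cfg):
        hm = kdr_matrix([("FL1T", "FL1T")], kdr_cfg, phased=True)
        calls, _ = call_diplotypes(hm, kdr_cfg)
        samples = make_samples([{"sample_id": "s0", "taxon": "coluzzii", "site": "x"}])
        t = diplotype_frequencies(calls, samples, od_min_count=0)
        assert t.iloc[0]["frequency"] == 1.0

    def test_frequencies_sum_to_one_per_group(self, two_background_cohort, kdr_cfg):
        _, c = two_background_cohort
        calls, _ = call_diplotypes(c.haplotypes, kdr_cfg)
        t = diplotype_frequencies(calls, c.samples, grouping="taxon_site")
        for _, sub in t.groupby("group"):
            assert sub["frequency"].sum() == pytest.approx(1.0)

    def test_hwe_expectation_on_simulated_cohort(self, kdr_cfg):
        n = 600
        spec = KdrCohortSpec(
            groups=[CohortGroupSpec("coluzzii", "Bana", n, {"FL1T": 0.4, "LVI": 0.6})],
            n_background_sites=0,
            seed=21,
        )
        c = simulate_kdr_cohort(spec)
        calls, _ = call_diplotypes(c.haplotypes, kdr_cfg)
        t = diplotype_frequencies(calls, c.samples, od_min_count=0)
        p = 2 * 0.4 * 0.6
        row = t[t["diplotype"] == "FL1T/LVI"].iloc[0]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(row["frequency"] - p) < 3 * se

    def test_rare_groups_pool_into_od(self, kdr_cfg):
        labels = [("FVI", "FVI")] * 10 + [("SVI", "LVI")]
        hm = kdr_matrix(labels, kdr_cfg, phased=True)
        calls, _ = call_diplotypes(hm, kdr_cfg)
        samples = make_samples(
            [{"sample_id": f"s{j}", "taxon": "arabiensis", "site": "x"} for j in range(11)]
        )
        t = diplotype_frequencies(calls, samples, od_min_count=3)
        assert set(t["diplotype"]) == {"FVI/FVI", "OD"}


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self):
        g = make_genotypes([[[0, 1], [0, 1], [1, 1]]])
        Z, _, _ = diplotype_clustering(g)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_linkage_heights_match_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        calls = rng.integers(0, 2, size=(6, 5, 2))
        g = make_genotypes(calls)
        Z, _, _ = diplotype_clustering(g)
        from kdrkit.diplotypes import _dosage_matrix
        from scipy.spatial.distance import pdist, squareform

        X, _ = _dosage_matrix(g)
        D = squareform(pdist(X, metric="cityblock"))
        assert sorted(Z[:, 2]) == pytest.approx(_oracles.brute_average_linkage(D))

    def test_two_backgrounds_recovered_as_two_flat_clusters(self, kdr_cfg):
        spec = KdrCohortSpec(
            groups=[CohortGroupSpec("coluzzii", "Bana", 40, {"FL1T": 0.5, "LVI": 0.5})],
            n_background_sites=0,
            seed=13,
        )
        c = simulate_kdr_cohort(spec)
        # cluster haplotype-derived dosages into 3 diplotype groups
        Z, flat, ids = diplotype_clustering(c.genotypes, n_clusters=3)
        truth = dict(zip(c.truth["sample_id"], c.truth["group_label"]))
        by_cluster = {}
        for sid, k in zip(ids, flat):
            by_cluster.setdefault(k, set()).add(truth[sid])
        # each flat cluster is pure w.r.t. the truth diplotype group
        assert all(len(v) == 1 for v in by_cluster.values())


class TestPcaDosage:
    def test_antipodal_profiles_put_all_variance_on_pc1(self):
        g = make_genotypes([[[1, 1], [0, 0]], [[0, 0], [1, 1]], [[1, 1], [0, 0]]])
        coords, evr, _ = pca_dosage(g, n_components=2)
        assert evr[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 2, size=(3, 4, 2))
        g = make_genotypes(calls)
        coords, evr, _ = pca_dosage(g, n_components=2)
        from kdrkit.diplotypes import _dosage_matrix

        X, _ = _dosage_matrix(g)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(w)[::-1]
        w = w[order]
        expected_evr = w / w.sum()
        assert evr == pytest.approx(expected_evr[:2])
        # coordinates agree up to per-component sign
        proj = Xc @ V[:, order[:2]]
        for k in range(2):
            assert np.allclose(np.abs(proj[:, k]), np.abs(coords[:, k]), atol=1e-9)

    def test_duplicated_sample_identical_coordinates(self):
        calls = np.array([[[0, 1], [0, 1], [1, 1]], [[0, 0], [0, 0], [1, 0]]])
        g = make_genotypes(calls)
        coords, _, _ = pca_dosage(g)
        assert np.allclose(coords[0], coords[1])

    def test_zero_variance_matrix_rejected(self):
        g = make_genotypes([[[0, 1], [0, 1]]])
        with pytest.raises(ValueError, match="variance"):
            pca_dosage(g)
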