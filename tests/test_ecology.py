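"""Community ecology: rarefaction, indices, clustering, NMDS, univariate tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes
from sklearn.metrics import adjusted_rand_score, silhouette_score

from mucometa import ecology as eco
from mucometa import synthetic as syn


def _table(counts, patients=None, sites=None):
    counts = pd.DataFrame(np.asarray(counts, dtype=np.int64))
    counts.index = [f"S{i}" for i in range(len(counts))]
    counts.columns = [f"g{j}" for j in range(counts.shape[1])]
    n = len(counts)
    patients = patients or [f"P{i}" for i in range(n)]
    sites = sites or ["tumour"] * n
    return eco.OtuTable(
        counts=counts,
        patient_ids=pd.Series(patients, index=counts.index),
        sites=pd.Series(sites, index=counts.index),
    )


def _planted_communities(n_per=17, n_taxa=30, seed=0, effect=2.0):
    """Three community types with distinct dominant taxa."""
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for k in range(3):
        base = np.zeros(n_taxa)
        base[k * 10:(k + 1) * 10] = effect
        for _ in range(n_per):
            logp = base + rng.normal(0, 0.4, n_taxa)
            p = np.exp(logp)
            p /= p.sum()
            rows.append(rng.multinomial(5000, p))
            truth.append(k)
    return _table(rows), np.array(truth)


class TestRarefy:
    def test_row_at_target_depth_unchanged(self):
        t = _table([[60, 40], [30, 20]])
        out = eco.rarefy(t, depth=50, seed=0)
        assert out.counts.loc["S1"].tolist() == [30, 20]
        assert out.counts.sum(axis=1).eq(50).all()

    def test_hypergeometric_expectation(self):
        rng = np.random.default_rng(1)
        draws = np.array(
            [rng.multivariate_hypergeometric([600, 400], 100) for _ in range(1000)]
        )
        # oracle: subsampling 100 of (600, 400) has mean (60, 40)
        var = 100 * 0.6 * 0.4 * (1000 - 100) / (1000 - 1)
        se = math.sqrt(var / 1000)
        assert abs(draws[:, 0].mean() - 60) < 3 * se
        t = _table([[600, 400]] * 5)
        reps = [eco.rarefy(t, depth=100, seed=s).counts.to_numpy()[:, 0]
                for s in range(200)]
        assert abs(np.mean(reps) - 60) < 3 * math.sqrt(var / 1000)

    def test_depth_exceeding_row_sum_rejected(self):
        with pytest.raises(ValueError, match="S1"):
            eco.rarefy(_table([[60, 60], [5, 5]]), depth=20)

    def test_deterministic(self):
        t = _table([[600, 400], [300, 700]])
        a = eco.rarefy(t, depth=100, seed=7).counts
        b = eco.rarefy(t, depth=100, seed=7).counts
        pd.testing.assert_frame_equal(a, b)


class TestShannon:
    def test_uniform_community(self):
        assert np.isclose(eco.shannon_index(np.ones(4) / 4), math.log(4))

    def test_single_genus_zero(self):
        assert eco.shannon_index([0.0, 1.0, 0.0]) == 0.0

    def test_mixed_community_matches_direct_formula(self):
        p = np.array([0.5, 0.3, 0.2])
        oracle = -sum(x * math.log(x) for x in p)
        assert np.isclose(eco.shannon_index(p), oracle, atol=1e-12)
        assert np.isclose(oracle, 1.029653, atol=1e-6)

    def test_maximal_at_uniformity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            assert eco.shannon_index(p) <= math.log(6) + 1e-12

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            eco.shannon_index([-0.1, 1.1])


class TestTau:
    def test_identical_pair(self):
        t = _table([[5, 3, 1], [5, 3, 1]])
        assert np.isclose(eco.tau_index(t, "S0"), 1.0)

    def test_reversed_ranks(self):
        t = _table([[1, 2, 3, 4], [4, 3, 2, 1]])
        assert np.isclose(eco.tau_index(t, "S0"), -1.0)

    def test_matches_pair_count_oracle(self):
        t = _table([[10, 5, 2, 7], [3, 8, 1, 9], [6, 6, 4, 2]])
        x = t.counts.loc["S0"].to_numpy(dtype=float)

        def tau_b(u, v):
            nc = nd = 0
            tx = ty = 0
            n = len(u)
            for i in range(n):
                for j in range(i + 1, n):
                    a, b = u[i] - u[j], v[i] - v[j]
                    if a == 0 and b == 0:
                        tx += 1
                        ty += 1
                    elif a == 0:
                        tx += 1
                    elif b == 0:
                        ty += 1
                    elif a * b > 0:
                        nc += 1
                    else:
                        nd += 1
            n0 = n * (n - 1) / 2
            return (nc - nd) / math.sqrt((n0 - tx) * (n0 - ty))

        oracle = np.mean([
            tau_b(x, t.counts.loc[s].to_numpy(dtype=float)) for s in ("S1", "S2")
        ])
        assert np.isclose(eco.tau_index(t, "S0"), oracle, atol=1e-12)

    def test_constant_vector_reported_missing(self):
        t = _table([[3, 3, 3], [1, 2, 3]])
        assert math.isnan(eco.tau_index(t, "S0"))


class TestNormalizeToTumour:
    def test_values_divided_by_patient_tumour_value(self):
        values = pd.Series({"a": 2.0, "b": 1.0, "c": 3.0})
        patients = pd.Series({"a": "P1", "b": "P1", "c": "P1"})
        sites = pd.Series({"a": "tumour", "b": "5cm", "c": "10cm"})
        out = eco.normalize_index_to_tumour(values, patients, sites)
        assert out.tolist() == [1.0, 0.5, 1.5]

    def test_missing_tumour_sample_names_patient(self):
        values = pd.Series({"a": 2.0, "b": 1.0})
        patients = pd.Series({"a": "P9", "b": "P9"})
        sites = pd.Series({"a": "5cm", "b": "10cm"})
        with pytest.raises(ValueError, match="P9"):
            eco.normalize_index_to_tumour(values, patients, sites)


class TestBrayCurtis:
    def test_identical_rows_distance_zero(self):
        D = eco.bray_curtis(_table([[3, 1], [3, 1]]))
        assert np.isclose(D.iloc[0, 1], 0.0)

    def test_disjoint_support_distance_one(self):
        D = eco.bray_curtis(_table([[5, 0], [0, 9]]))
        assert np.isclose(D.iloc[0, 1], 1.0)

    def test_matches_direct_formula(self):
        D = eco.bray_curtis(_table([[6, 2], [2, 4]]))
        assert np.isclose(D.iloc[0, 1], 6 / 14, atol=1e-12)

    def test_bounded_symmetric_zero_diagonal(self):
        t, _ = _planted_communities(n_per=4)
        D = eco.bray_curtis(t).to_numpy()
        assert ((D >= 0) & (D <= 1)).all()
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_allclose(np.diag(D), 0)


class TestWardClustering:
    def test_recovers_planted_community_types(self):
        t, truth = _planted_communities()
        dend = eco.ward_cluster(eco.bray_curtis(t))
        labels = dend.cut(3)
        assert adjusted_rand_score(truth, labels.to_numpy()) > 0.9

    def test_k_equal_n_gives_singletons(self):
        t = _table([[5, 1], [1, 5], [3, 3]])
        dend = eco.ward_cluster(eco.bray_curtis(t))
        assert dend.cut(3).nunique() == 3

    def test_merge_heights_monotone(self):
        t, _ = _planted_communities(n_per=6)
        dend = eco.ward_cluster(eco.bray_curtis(t))
        assert (np.diff(dend.linkage[:, 2]) >= -1e-10).all()

    def test_newick_export_contains_all_leaves(self):
        t = _table([[5, 1], [1, 5], [3, 3]])
        nwk = eco.ward_cluster(eco.bray_curtis(t)).to_newick()
        assert nwk.endswith(";") and all(s in nwk for s in t.sample_ids)


class TestPatientConcordance:
    @staticmethod
    def _cohort_distance(within_sd, seed=0, n_patients=8):
        rng = np.random.default_rng(seed)
        rows, patients = [], []
        for i in range(n_patients):
            centre = rng.normal(0, 2.0, 12)
            for s in range(3):
                logp = centre + rng.normal(0, within_sd, 12)
                p = np.exp(logp)
                rows.append(rng.multinomial(3000, p / p.sum()))
                patients.append(f"P{i}")
        t = _table(rows, patients=patients,
                   sites=["tumour", "5cm", "10cm"] * n_patients)
        return t

    def test_tight_patient_triplets_concordant(self):
        t = self._cohort_distance(within_sd=0.05)
        dend = eco.ward_cluster(eco.bray_curtis(t))
        _, n = eco.patient_concordance(dend, t.patient_ids)
        assert n >= 7

    def test_concordance_invariant_to_input_order(self):
        t = self._cohort_distance(within_sd=0.3, seed=3)
        perm = np.random.default_rng(4).permutation(len(t.counts))
        t2 = eco.OtuTable(counts=t.counts.iloc[perm],
                          patient_ids=t.patient_ids.iloc[perm],
                          sites=t.sites.iloc[perm])
        f1, n1 = eco.patient_concordance(
            eco.ward_cluster(eco.bray_curtis(t)), t.patient_ids)
        f2, n2 = eco.patient_concordance(
            eco.ward_cluster(eco.bray_curtis(t2)), t2.patient_ids)
        assert n1 == n2
        assert f1.sort_index().equals(f2.sort_index())

    def test_patient_effect_raises_concordance(self):
        strong = weak = 0
        for rep in range(10):
            ts = self._cohort_distance(0.05, seed=100 + rep)
            tw = self._cohort_distance(1.5, seed=100 + rep)
            strong += eco.patient_concordance(
                eco.ward_cluster(eco.bray_curtis(ts)), ts.patient_ids)[1]
            weak += eco.patient_concordance(
                eco.ward_cluster(eco.bray_curtis(tw)), tw.patient_ids)[1]
        assert strong > weak


class TestNmds:
    def test_planar_distances_recovered(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(15, 2))
        D = pd.DataFrame(
            np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)))
        res = eco.nmds(D, n_restarts=8, seed=0)
        assert res.stress < 0.01
        _, _, disparity = procrustes(pts, res.coordinates.to_numpy())
        assert disparity < 1e-3

    def test_best_restart_returned(self):
        t, _ = _planted_communities(n_per=5)
        res = eco.nmds(eco.bray_curtis(t), n_restarts=6, seed=1)
        assert res.stress <= res.all_stresses.min() + 1e-12

    def test_separated_groups_silhouette(self):
        t, truth = _planted_communities(n_per=10, effect=3.0, seed=6)
        res = eco.nmds(eco.bray_curtis(t), n_restarts=6, seed=2)
        assert silhouette_score(res.coordinates.to_numpy(), truth) > 0.5


class TestTaxonFeatureTests:
    def test_planted_enrichment_found_first(self):
        rng = np.random.default_rng(7)
        n = 54
        feature = pd.Series(np.repeat([0, 1], n // 2))
        rows = []
        for i in range(n):
            logp = np.zeros(40)
            if feature.iloc[i]:
                logp[0] = np.log(4.0)
            logp += rng.normal(0, 0.3, 40)
            p = np.exp(logp)
            rows.append(rng.multinomial(8000, p / p.sum()))
        t = _table(rows)
        feature.index = t.counts.index
        out = eco.taxon_feature_tests(t, feature)
        assert out["p"].idxmin() == "g0"
        assert out.loc["g0", "p"] < 0.01
        assert out.loc["g0", "direction"] == 1

    def test_all_zero_genus_p_one(self):
        t = _table([[5, 0], [3, 0], [4, 0], [6, 0]])
        f = pd.Series([0, 0, 1, 1], index=t.counts.index)
        out = eco.taxon_feature_tests(t, f)
        assert out.loc["g1", "p"] == 1.0

    def test_single_level_feature_rejected(self):
        t = _table([[1, 2], [3, 4]])
        with pytest.raises(ValueError):
            eco.taxon_feature_tests(t, pd.Series([1, 1], index=t.counts.index))


class TestClusterFeatureAssociation:
    def test_fisher_matches_hypergeometric_enumeration(self):
        clusters = pd.Series([1] * 8 + [2] * 10)
        feature = pd.DataFrame({"f": [1] * 8 + [0] * 10}, index=clusters.index)
        out = eco.cluster_feature_association(clusters, feature)
        # oracle: sum hypergeometric probabilities of tables at least as extreme
        probs = [stats.hypergeom.pmf(a, 18, 8, 8) for a in range(9)]
        observed = probs[8]
        p_oracle = sum(pr for pr in probs if pr <= observed + 1e-12)
        assert np.isclose(out.loc["f", "p"], p_oracle, atol=1e-12)
        assert out.loc["f", "test"] == "fisher-exact"

    def test_independent_feature_calibrated(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 300
        for _ in range(reps):
            clusters = pd.Series(rng.integers(1, 3, 18))
            if clusters.nunique() < 2:
                continue
            feature = pd.DataFrame({"f": rng.integers(0, 2, 18)},
                                   index=clusters.index)
            if feature["f"].nunique() < 2:
                continue
            out = eco.cluster_feature_association(clusters, feature)
            rejections += out.loc["f", "p"] < 0.05
        # Fisher is conservative on discrete margins: size must not exceed 0.07
        assert rejections / reps <= 0.07

    def test_ordinal_feature_uses_kruskal(self):
        clusters = pd.Series([1] * 6 + [2] * 6)
        feature = pd.DataFrame({"T_stage": [1, 1, 2, 1, 2, 1, 4, 3, 4, 4, 3, 4]},
                               index=clusters.index)
        out = eco.cluster_feature_association(clusters, feature,
                                              ordinal=("T_stage",))
        assert out.loc["T_stage", "test"] == "kruskal-wallis"
        assert out.loc["T_stage", "p"] < 0.05
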