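"""Energy filtering, PCA, clustering and cohort selection."""

import numpy as np
import pytest

from afmfit.uml_selection import (
    CohortConfig,
    CohortSelector,
    FilterConfig,
    STAGE1_COMPONENTS,
    cluster,
    energy_filter,
    pca,
    run_uml,
    select_cohort,
    select_representative_cluster,
    standardize,
)
from afmfit.synthetic_fixtures import PlantedTrajectorySpec, planted_trajectory

from .conftest import make_records


class TestStandardize:
    def test_direct_value(self):
        out = standardize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-1.22474487, 0.0, 1.22474487],
                                   atol=1e-8)

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize([2.0, 2.0, 2.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        z = standardize(rng.normal(3, 7, 100))
        np.testing.assert_allclose(standardize(z), z, atol=1e-9)


class TestEnergyFilter:
    def test_identical_frames_all_survive(self):
        recs = make_records({"e_total": np.ones(20)})
        s1, s2 = energy_filter(recs)
        assert len(s1) == len(s2) == 20

    def test_constructed_outlier_removed(self):
        rng = np.random.default_rng(1)
        vals = {c: rng.normal(0, 1, 100) for c in STAGE1_COMPONENTS}
        vals["e_repulsive"] = rng.normal(0, 1, 100)
        vals["e_repulsive"][17] = vals["e_repulsive"].std() * 30  # >> +3 sigma
        recs = make_records(vals)
        s1, _ = energy_filter(recs)
        assert 17 not in s1
        assert len(s1) >= 97      # only chance-level +3-sigma crossings besides

    def test_stage2_cc_lower_bound(self):
        rng = np.random.default_rng(2)
        cc = rng.uniform(0.7, 0.9, 200)
        cc[5] = 0.01                       # catastrophic correlation
        recs = make_records({"cc_afm": cc})
        _, s2 = energy_filter(recs)
        assert 5 not in s2

    def test_seven_components_participate(self):
        cfg = FilterConfig()
        assert set(cfg.stage1_cutoffs) == {"e_repulsive", "e_local",
                                           "e_stacking", "e_pairing", "b_stage"}
        assert set(cfg.stage2_cutoffs) == {"cc_afm", "e_total"}

    def test_counts_monotone(self):
        recs, _ = planted_trajectory(PlantedTrajectorySpec(n_frames=500, seed=3))
        s1, s2 = energy_filter(recs)
        assert len(recs) >= len(s1) >= len(s2) > 0

    def test_too_few_frames(self):
        recs = make_records({"e_total": np.arange(5.0)})
        with pytest.raises(ValueError):
            energy_filter(recs)


class TestPCA:
    def test_isotropic_noise_trace_conserved(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (4000, 10))
        X = (X - X.mean(0)) / X.std(0)
        res = pca(X)
        assert res.eigenvalues.sum() == pytest.approx(10.0, rel=1e-9)
        assert np.all(res.eigenvalues > 0.8) and np.all(res.eigenvalues < 1.2)

    def test_planar_data_two_components(self):
        rng = np.random.default_rng(5)
        basis = rng.normal(size=(2, 10))
        X = rng.normal(size=(500, 2)) @ basis
        res = pca(X)
        assert res.explained_variance_ratio[:2].sum() >= 0.999

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        X = rng.normal(0, 1, (300, 10))
        res = pca(X)
        np.testing.assert_allclose(res.loadings @ res.loadings.T, np.eye(10),
                                   atol=1e-8)

    def test_matches_covariance_eigendecomposition(self):
        # brute-force oracle on a small input, population covariance
        rng = np.random.default_rng(7)
        X = rng.normal(0, 2, (150, 10))
        X = X - X.mean(axis=0)
        res = pca(X)
        S = X.T @ X / X.shape[0]
        w, v = np.linalg.eigh(S)
        w, v = w[::-1], v[:, ::-1]
        np.testing.assert_allclose(res.eigenvalues, w, atol=1e-8)
        for k in range(10):
            dot = abs(v[:, k] @ res.loadings[k])
            assert dot == pytest.approx(1.0, abs=1e-8)   # up to sign

    def test_component_floor_is_three(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(500, 1)) @ rng.normal(size=(1, 10))
        X = X + 1e-6 * rng.normal(size=X.shape)
        res = pca(X)
        assert res.n_components_selected >= 3


class TestCluster:
    def test_two_blob_recovery(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.3, (150, 3))
        b = rng.normal(8, 0.3, (150, 3))
        X = np.vstack([a, b])
        res = cluster(X, k_max=6, seed=0)
        assert res.k_selected == 2
        # labels partition the blobs exactly (oracle: distance to true centers)
        true = (np.linalg.norm(X - 8.0, axis=1)
                < np.linalg.norm(X - 0.0, axis=1)).astype(int)
        same = (res.labels == true).mean()
        assert same in (0.0, 1.0)     # up to label swap

    def test_single_blob_flat_curve(self):
        rng = np.random.default_rng(10)
        X = rng.normal(0, 0.2, (200, 3))
        res = cluster(X, k_max=5, seed=0)
        assert res.k_selected in (1, 2)
        drops = res.wcss_curve[:-1] - res.wcss_curve[1:]
        assert drops[0] <= 0.5 * res.wcss_curve[0]

    def test_wcss_non_increasing(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (120, 4))
        res = cluster(X, k_max=6, seed=3)
        assert np.all(np.diff(res.wcss_curve) <= 1e-9)

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(12)
        X = np.vstack([rng.normal(0, 0.4, (80, 3)), rng.normal(6, 0.4, (80, 3))])
        perm = rng.permutation(len(X))
        r1 = cluster(X, k_max=4, seed=5)
        r2 = cluster(X[perm], k_max=4, seed=5)
        # the selected clustering is order-invariant: same k, same optimum,
        # identical partition up to label renaming
        assert r1.k_selected == r2.k_selected
        assert r1.wcss_curve[r1.k_selected - 1] == pytest.approx(
            r2.wcss_curve[r2.k_selected - 1], rel=1e-9)
        mapping = {}
        for a, b in zip(r2.labels, r1.labels[perm]):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_k_max_validation(self):
        with pytest.raises(ValueError):
            cluster(np.zeros((10, 2)), k_max=1)


class TestRepresentativeCluster:
    def test_dominant_cluster_selected(self):
        rng = np.random.default_rng(13)
        n = 200
        labels = np.repeat([0, 1], n // 2)
        e = np.where(labels == 1, -10.0, 10.0) + rng.normal(0, 0.5, n)
        recs = make_records({"e_local": e, "e_total": e, "e_go": e})
        from afmfit.uml_selection import ClusterResult
        cl = ClusterResult(labels=labels, k_selected=2,
                           wcss_curve=np.array([1.0, 0.5]),
                           centers=np.zeros((2, 3)))
        assert select_representative_cluster(cl, recs) == 1

    def test_conflicting_rankings_sum_rule(self):
        rng = np.random.default_rng(14)
        n = 300
        labels = np.repeat([0, 1, 2], n // 3)
        vals = {}
        for comp in ("e_local", "e_total", "e_go"):
            vals[comp] = rng.normal(0, 1, n)
        recs = make_records(vals)
        from afmfit.uml_selection import ClusterResult
        cl = ClusterResult(labels=labels, k_selected=3,
                           wcss_curve=np.array([1.0]), centers=np.zeros((3, 3)))
        got = select_representative_cluster(cl, recs)
        # oracle: brute-force the sum-of-standardized-means rule
        score = np.zeros(3)
        for comp in ("e_local", "e_total", "e_go"):
            z = standardize(vals[comp])
            for c in range(3):
                score[c] += z[labels == c].mean()
        assert got == int(np.argmin(score))

    def test_single_cluster_trivial(self):
        recs = make_records({"e_total": np.arange(10.0)})
        from afmfit.uml_selection import ClusterResult
        cl = ClusterResult(labels=np.zeros(10, dtype=int), k_selected=1,
                           wcss_curve=np.array([1.0]), centers=np.zeros((1, 3)))
        assert select_representative_cluster(cl, recs) == 0


class TestCohort:
    def test_dominating_frame_in_cohort(self):
        rng = np.random.default_rng(15)
        n = 100
        vals = {"cc_afm": rng.uniform(0.3, 0.6, n),
                "e_total": rng.normal(10, 1, n),
                "e_local": rng.normal(5, 1, n),
                "e_go": rng.normal(-5, 1, n)}
        vals["cc_afm"][42] = 0.99
        vals["e_total"][42] = -50.0
        vals["e_local"][42] = -50.0
        vals["e_go"][42] = -50.0
        recs = make_records(vals)
        cohort = select_cohort(recs)
        assert 42 in cohort

    def test_independent_marginals_fraction(self):
        rng = np.random.default_rng(16)
        n = 40_000
        recs = make_records({
            "cc_afm": rng.uniform(0, 1, n),
            "e_total": rng.uniform(0, 1, n),
            "e_local": rng.uniform(0, 1, n),
            "e_go": rng.uniform(0, 1, n),
        })
        cohort = select_cohort(recs, CohortConfig())
        # P = 0.10 * 0.25^3 under independence
        p = 0.10 * 0.25 ** 3
        sd = np.sqrt(p * (1 - p) / n)
        assert len(cohort) / n == pytest.approx(p, abs=5 * sd)

    def test_adversarial_anticorrelation_relaxes(self):
        n = 200
        cc = np.linspace(0, 1, n)
        recs = make_records({"cc_afm": cc, "e_total": cc,
                             "e_local": cc, "e_go": cc})
        # high CC frames have high energies: strict intersection empty
        with pytest.warns(UserWarning, match="relaxed"):
            cohort = select_cohort(recs, CohortConfig(
                cc_quantile_min=0.95,
                energy_quantile_max={"e_total": 0.05, "e_local": 0.05,
                                     "e_go": 0.05}))
        assert len(cohort) > 0


class TestPipeline:
    def test_cohort_enriched_in_low_rmsd(self):
        recs, labels = planted_trajectory(
            PlantedTrajectorySpec(n_frames=4000, seed=17))
        res = run_uml(recs, seed=0)
        assert np.median(labels[res.cohort_indices]) < np.median(labels)

    def test_stage_counts_monotone_and_provenance(self):
        recs, _ = planted_trajectory(PlantedTrajectorySpec(n_frames=1500, seed=18))
        res = run_uml(recs, seed=1)
        p = res.provenance
        assert (p["n_input"] >= p["n_stage1"] >= p["n_stage2"]
                >= p["n_cluster"] >= p["n_cohort"] > 0)

    def test_deterministic_per_seed(self):
        recs, _ = planted_trajectory(PlantedTrajectorySpec(n_frames=1200, seed=19))
        r1 = run_uml(recs, seed=7)
        r2 = run_uml(recs, seed=7)
        np.testing.assert_array_equal(r1.cohort_indices, r2.cohort_indices)

    def test_estimator_wrapper(self):
        recs, _ = planted_trajectory(PlantedTrajectorySpec(n_frames=1200, seed=20))
        sel = CohortSelector(random_state=3).fit(recs)
        assert len(sel.cohort_indices_) == sel.provenance_["n_cohort"]
        cohort = sel.transform(recs)
        assert len(cohort) == len(sel.cohort_indices_)
        params = sel.get_params()
        assert params["random_state"] == 3

    def test_selection_tightens_rmsd_across_stages(self):
        recs, labels = planted_trajectory(
            PlantedTrajectorySpec(n_frames=4000, seed=21))
        res = run_uml(recs, seed=2)
        med_full = np.median(labels)
        med_filter = np.median(labels[res.stage2_indices])
        med_cluster = np.median(labels[res.cluster_indices])
        med_cohort = np.median(labels[res.cohort_indices])
        assert med_filter <= med_full
        assert med_cluster <= med_filter + 1e-9
        assert med_cohort <= med_cluster + 1e-9
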