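import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import rand_score

from matshare import (
    DistanceMatrix,
    SimConfig,
    bray_curtis,
    build_modified_otu_table,
    cluster_infants,
    cluster_shared_abundance_test,
    pcoa,
    related_profiles,
    simulate_cohort,
    table_bray_curtis,
)
from matshare.ecology import ModifiedOtuTable
from matshare.feature_tables import collapse_to_otus, relative_abundance
from matshare.transmission import SharedProfile


def brute_force_bc(x, y):
    return np.sum(np.abs(x - y)) / np.sum(x + y)


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        ab = np.array([[0.5, 0.5], [0.5, 0.5]])
        dm = bray_curtis(ab, ["a", "b"], transform="none")
        assert dm.values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        ab = np.array([[1.0, 0.0], [0.0, 1.0]])
        dm = bray_curtis(ab, ["a", "b"], transform="none")
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_hand_value_with_sqrt(self):
        # sqrt profiles (0.894, 0.447) vs (0.447, 0.894) -> 1/3
        ab = np.array([[0.8, 0.2], [0.2, 0.8]])
        dm = bray_curtis(ab, ["a", "b"], transform="sqrt")
        assert dm.values[0, 1] == pytest.approx(1 / 3, abs=1e-9)

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(10):
            ab = rng.uniform(0.01, 1.0, size=(5, 5))
            ab /= ab.sum(axis=0)
            for transform in ("none", "sqrt"):
                dm = bray_curtis(ab, list("abcde"), transform=transform)
                x = np.sqrt(ab) if transform == "sqrt" else ab
                for i in range(5):
                    for j in range(5):
                        assert dm.values[i, j] == pytest.approx(
                            brute_force_bc(x[:, i], x[:, j]), abs=1e-12
                        )

    def test_matches_scipy_braycurtis(self, rng):
        ab = rng.uniform(0.0, 1.0, size=(8, 6)) + 0.01
        dm = bray_curtis(ab, [f"s{i}" for i in range(6)], transform="none")
        ref = squareform(pdist(ab.T, metric="braycurtis"))
        np.testing.assert_allclose(dm.values, ref, atol=1e-12)

    def test_empty_profile_rejected(self):
        ab = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="empty profile"):
            bray_curtis(ab, ["a", "b"])

    def test_distance_matrix_invariants(self, small_cohort):
        dm = table_bray_curtis(small_cohort.table)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)
        assert dm.values.min() >= 0 and dm.values.max() <= 1.0 + 1e-12


class TestDistanceMatrixType:
    def test_asymmetry_rejected(self):
        bad = np.array([[0.0, 0.3], [0.4, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(("a", "b"), bad)

    def test_nonzero_diagonal_rejected(self):
        bad = np.array([[0.1, 0.3], [0.3, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(("a", "b"), bad)


class TestPcoa:
    def test_equilateral_triplet_equal_eigenvalues(self):
        d = np.ones((3, 3)) - np.eye(3)
        ordination = pcoa(DistanceMatrix(("a", "b", "c"), d))
        positive = ordination.eigenvalues[ordination.eigenvalues > 1e-12]
        assert len(positive) == 2
        assert positive[0] == pytest.approx(positive[1])

    def test_duplicate_samples_coincide(self):
        d = np.array(
            [
                [0.0, 0.0, 0.8],
                [0.0, 0.0, 0.8],
                [0.8, 0.8, 0.0],
            ]
        )
        ordination = pcoa(DistanceMatrix(("a", "a2", "c"), d))
        np.testing.assert_allclose(
            ordination.coordinates[0], ordination.coordinates[1], atol=1e-9
        )

    def test_euclidean_input_exact_reconstruction(self, rng):
        points = rng.uniform(size=(12, 2))
        d = squareform(pdist(points))
        d /= d.max()  # scale into [0, 1]
        ordination = pcoa(DistanceMatrix(tuple(f"s{i}" for i in range(12)), d))
        assert np.all(ordination.eigenvalues >= -1e-9)
        recon = squareform(pdist(ordination.coordinates))
        np.testing.assert_allclose(recon, d, atol=1e-9)

    def test_proportions_sum_to_one(self, small_cohort):
        ordination = pcoa(table_bray_curtis(small_cohort.table))
        assert ordination.proportion_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(ordination.eigenvalues) <= 1e-9)

    def test_too_few_samples_rejected(self):
        d = np.array([[0.0, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError, match="three samples"):
            pcoa(DistanceMatrix(("a", "b"), d))


@pytest.fixture(scope="module")
def modified_table_setup():
    cohort = simulate_cohort(SimConfig(n_pairs=30, tau0=0.4, seed=77))
    otu_table, mapping = collapse_to_otus(cohort.table, cohort.taxonomy)
    profiles = related_profiles(cohort.table, cohort.metadata)
    mot = build_modified_otu_table(cohort.table, cohort.metadata, mapping, profiles)
    return cohort, otu_table, mapping, profiles, mot


class TestModifiedOtuTable:
    def test_split_sum_example(self):
        from matshare import CohortMetadata, FeatureTable
        import pandas as pd

        table = FeatureTable(
            ("a", "b", "c"),
            ("inf", "mom"),
            np.array([[3, 1], [1, 0], [6, 9]]),
        )
        md = CohortMetadata(
            pd.DataFrame(
                [
                    {"sample_id": "mom", "subject_id": "s", "role": "mother",
                     "pair_id": ""},
                    {"sample_id": "inf", "subject_id": "s", "role": "infant",
                     "pair_id": "mom"},
                ]
            )
        )
        mapping = {"a": "O1", "b": "O1", "c": "O2"}
        profiles = related_profiles(table, md)
        mot = build_modified_otu_table(table, md, mapping, profiles)
        i = mot.otu_ids.index("O1")
        assert mot.shared[i, 0] == pytest.approx(0.3)  # a shared
        assert mot.nonshared[i, 0] == pytest.approx(0.1)  # b infant-only

    def test_no_shared_asvs_gives_zero_column(self):
        cohort = simulate_cohort(
            SimConfig(n_pairs=6, tau0=0.0, covariate_effects={},
                      background_rate=0.0, seed=2)
        )
        _, mapping = collapse_to_otus(cohort.table, cohort.taxonomy)
        profiles = related_profiles(cohort.table, cohort.metadata)
        mot = build_modified_otu_table(
            cohort.table, cohort.metadata, mapping, profiles
        )
        np.testing.assert_allclose(mot.shared, 0.0)

    def test_conservation_against_otu_table(self, modified_table_setup):
        cohort, otu_table, _, _, mot = modified_table_setup
        rel = relative_abundance(otu_table)
        for col, infant in enumerate(mot.infant_ids):
            j = otu_table.sample_index(infant)
            for row, otu in enumerate(mot.otu_ids):
                i = otu_table.feature_index(otu)
                assert mot.totals()[row, col] == pytest.approx(rel[i, j], abs=1e-9)

    def test_mismatched_profiles_rejected(self, modified_table_setup):
        cohort, _, mapping, profiles, _ = modified_table_setup
        wrong = [
            SharedProfile(
                infant_sample_id=p.infant_sample_id,
                mother_sample_id="M9999",
                shared_asvs=p.shared_asvs,
                n_shared=p.n_shared,
                pct_shared=p.pct_shared,
                shared_abundance=p.shared_abundance,
            )
            for p in profiles
        ]
        with pytest.raises(ValueError):
            build_modified_otu_table(
                cohort.table, cohort.metadata, mapping, wrong
            )


class TestClustering:
    def test_identical_blocks_recovered(self):
        # 3 blocks of identical profiles -> each block is one cluster
        base = np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        profiles = np.repeat(base, 4, axis=1)  # 12 infants
        ids = tuple(f"i{k}" for k in range(12))
        mot = ModifiedOtuTable(
            infant_ids=ids,
            otu_ids=("o1", "o2", "o3"),
            shared=profiles,
            nonshared=np.zeros_like(profiles),
        )
        assignment = cluster_infants(mot, k=3)
        labels = [assignment.assignments[i] for i in ids]
        truth = np.repeat([0, 1, 2], 4)
        assert rand_score(truth, labels) == 1.0

    def test_k_one_single_cluster(self, modified_table_setup):
        *_, mot = modified_table_setup
        assignment = cluster_infants(mot, k=1)
        assert set(assignment.assignments.values()) == {1}

    def test_k_above_n_rejected(self, modified_table_setup):
        *_, mot = modified_table_setup
        with pytest.raises(ValueError, match="k must"):
            cluster_infants(mot, k=len(mot.infant_ids) + 1)

    def test_exactly_k_nonempty_clusters(self, modified_table_setup):
        *_, mot = modified_table_setup
        for k in (2, 5, 8):
            assignment = cluster_infants(mot, k=k)
            assert len(set(assignment.assignments.values())) == k

    def test_two_regime_recovery(self):
        cohort = simulate_cohort(
            SimConfig(
                n_pairs=60,
                tau0=0.7,
                feeding_frequencies={"breast": 0.5, "formula": 0.5},
                covariate_effects={"breast": -0.7, "formula": 0.0},
                seed=7,
            )
        )
        _, mapping = collapse_to_otus(cohort.table, cohort.taxonomy)
        profiles = related_profiles(cohort.table, cohort.metadata)
        mot = build_modified_otu_table(
            cohort.table, cohort.metadata, mapping, profiles
        )
        assignment = cluster_infants(mot, k=2)
        truth = [cohort.truth[i].feeding for i in mot.infant_ids]
        predicted = [assignment.assignments[i] for i in mot.infant_ids]
        assert rand_score(truth, predicted) > 0.9


def make_profiles(values_by_cluster):
    profiles = []
    assignments = {}
    n = 0
    for label, values in values_by_cluster.items():
        for v in values:
            sid = f"i{n}"
            n += 1
            profiles.append(
                SharedProfile(
                    infant_sample_id=sid,
                    mother_sample_id=f"m{n}",
                    shared_asvs=frozenset(),
                    n_shared=0,
                    pct_shared=0.0,
                    shared_abundance=float(v),
                )
            )
            assignments[sid] = label
    from matshare.ecology import ClusterAssignment

    return profiles, ClusterAssignment(assignments, k=len(values_by_cluster))


class TestClusterSharedAbundanceTest:
    def test_identical_clusters_p_near_one(self):
        values = list(np.linspace(0.1, 0.9, 12))
        profiles, assignment = make_profiles({1: values, 2: values})
        summary, pairwise = cluster_shared_abundance_test(assignment, profiles)
        assert pairwise[0].p > 0.9
        assert summary["median"].nunique() == 1

    def test_shifted_cluster_detected(self):
        rng = np.random.default_rng(5)
        base = {1: rng.uniform(0.0, 0.3, 30), 2: rng.uniform(0.0, 0.3, 30)}
        base[3] = rng.uniform(0.0, 0.3, 30) + 0.4
        profiles, assignment = make_profiles(base)
        _, pairwise = cluster_shared_abundance_test(assignment, profiles)
        for r in pairwise:
            if "3" in (r.level_a, r.level_b):
                assert r.p < 0.01
            else:
                assert r.p > 0.01

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(99)
        rejected = total = 0
        for _ in range(200):
            groups = {c: rng.normal(size=10) for c in (1, 2, 3)}
            profiles, assignment = make_profiles(groups)
            _, pairwise = cluster_shared_abundance_test(assignment, profiles)
            rejected += sum(r.p < 0.05 for r in pairwise)
            total += len(pairwise)
        assert rejected / total <= 0.05

    def test_singleton_only_clusters_rejected(self):
        profiles, assignment = make_profiles({1: [0.1], 2: [0.2], 3: [0.1, 0.4]})
        with pytest.raises(ValueError, match="two or more members"):
            cluster_shared_abundance_test(assignment, profiles)
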