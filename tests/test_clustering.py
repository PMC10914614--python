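"""Correlation distance, agglomeration, embedding, centroid assignment."""

import numpy as np
import pytest

from gradscope.clustering import (
    UNASSIGNED,
    ReferenceCentroid,
    assign_to_reference,
    build_reference_centroids,
    distance_matrix,
    embed_2d,
    hierarchical_cluster,
    linkage_matrix,
    merge_sequence,
    profile_distance,
)
from gradscope.errors import (
    InsufficientReferenceError,
    ParameterError,
    UndefinedCorrelationError,
)
from gradscope.io import AnnotationTable
from gradscope.profiles import SedimentationProfile
from gradscope.simulate import assignment_accuracy

from conftest import bruteforce_agglomeration, pearson_textbook


def _profile(fractions, pid="p", organism="host"):
    fr = np.asarray(fractions, dtype=float)
    return SedimentationProfile(
        protein_id=pid,
        fractions=fr,
        pellet_share=0.0,
        total_intensity=float(fr.sum()),
        peak_fraction=int(np.argmax(fr)) + 1,
        organism=organism,
    )


def _random_profiles(n, seed):
    rng = np.random.default_rng(seed)
    return [
        _profile(rng.uniform(0, 1, size=20), pid=f"p{i}") for i in range(n)
    ]


class TestProfileDistance:
    def test_identity_is_zero(self):
        p = _profile(np.linspace(0, 1, 20))
        assert profile_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelation_is_two(self):
        x = np.linspace(0, 1, 20)
        assert profile_distance(_profile(x), _profile(1 - x)) == pytest.approx(
            2.0, abs=1e-12
        )

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x, y = rng.uniform(0, 1, size=(2, 20))
            assert profile_distance(_profile(x), _profile(y)) == pytest.approx(
                1 - pearson_textbook(x, y), abs=1e-12
            )

    def test_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x, y = rng.uniform(0, 1, size=(2, 20))
            p, q = _profile(x), _profile(y)
            assert profile_distance(p, q) == pytest.approx(
                profile_distance(q, p), abs=1e-12
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            profile_distance(_profile(np.ones(20)), _profile(np.arange(20)))


class TestHierarchicalCluster:
    def test_identical_pair_coclusters(self):
        x = np.zeros(20)
        x[9] = 1.0
        y = np.zeros(20)
        y[0] = 1.0
        labels = hierarchical_cluster(
            [_profile(x, "a"), _profile(x, "b"), _profile(y, "c")], k=2
        )
        assert labels[0] == labels[1] != labels[2]

    def test_k_equals_n_gives_singletons(self):
        ps = _random_profiles(5, seed=9)
        labels = hierarchical_cluster(ps, k=5)
        assert len(set(labels)) == 5

    def test_k_too_large_rejected(self):
        with pytest.raises(ParameterError):
            hierarchical_cluster(_random_profiles(3, seed=10), k=4)

    @pytest.mark.parametrize("method", ["average", "complete"])
    def test_merge_order_matches_bruteforce(self, method):
        """For n <= 6, the merge sequence equals exhaustive agglomeration
        that recomputes all pairwise linkage values each step."""
        rng = np.random.default_rng(11)
        for trial in range(40):
            n = int(rng.integers(3, 7))
            ps = _random_profiles(n, seed=1000 + trial)
            D = distance_matrix(ps)
            Z = linkage_matrix(ps, method)
            assert merge_sequence(Z, n) == bruteforce_agglomeration(D, method)


class TestEmbedding:
    def test_same_seed_same_coordinates(self):
        ps = _random_profiles(30, seed=12)
        a = embed_2d(ps, seed=5, perplexity=5)
        b = embed_2d(ps, seed=5, perplexity=5)
        np.testing.assert_array_equal(a, b)

    def test_three_profiles_smoke(self):
        ps = _random_profiles(3, seed=13)
        coords = embed_2d(ps, seed=0, perplexity=1)
        assert coords.shape == (3, 2) and np.all(np.isfinite(coords))

    def test_perplexity_too_large_rejected(self):
        with pytest.raises(ParameterError):
            embed_2d(_random_profiles(10, seed=14), seed=0, perplexity=5)

    def test_complexes_separate_in_embedding(self, normalized_study):
        """Within-complex embedded distances are smaller on average than
        between-complex distances on the default simulation."""
        retained = normalized_study["retained"]
        truth = normalized_study["truth"]
        machinery = truth.machinery_proteins()
        coords = embed_2d(retained, seed=42, perplexity=30)
        by_id = {p.protein_id: coords[i] for i, p in enumerate(retained)}
        ids = [pid for pid in machinery if pid in by_id]
        within, between = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                d = float(np.linalg.norm(by_id[a] - by_id[b]))
                (within if machinery[a] == machinery[b] else between).append(d)
        assert np.mean(within) < np.mean(between)


class TestReferenceCentroids:
    def _annotations(self, mapping):
        return AnnotationTable(
            protein_ids=list(mapping),
            organism=["host"] * len(mapping),
            reference_complex=list(mapping.values()),
        )

    def test_identical_members_give_that_profile(self):
        x = np.zeros(20)
        x[9] = 1.0
        ps = [_profile(x, f"m{i}") for i in range(3)]
        ann = self._annotations({f"m{i}": "30S" for i in range(3)})
        (c,) = build_reference_centroids(ps, ann)
        np.testing.assert_allclose(c.centroid, x)
        assert c.n_members == 3

    def test_mean_of_two_peaks(self):
        a = np.zeros(20)
        a[9] = 1.0  # F10
        b = np.zeros(20)
        b[11] = 1.0  # F12
        ps = [_profile(a, "a"), _profile(b, "b"), _profile((a + b) / 2, "c")]
        ann = self._annotations({"a": "50S", "b": "50S", "c": "50S"})
        (c,) = build_reference_centroids(ps, ann)
        assert c.centroid[9] == pytest.approx(0.5)
        assert c.centroid[11] == pytest.approx(0.5)

    def test_too_few_members_rejected(self):
        x = np.linspace(0, 1, 20)
        ps = [_profile(x, "a"), _profile(x, "b")]
        ann = self._annotations({"a": "RNAP", "b": "RNAP"})
        with pytest.raises(InsufficientReferenceError, match="RNAP"):
            build_reference_centroids(ps, ann)

    def test_centroids_recover_generative_centers(self, normalized_study):
        """Centroid argmax fraction equals the rounded class center."""
        expected = {"RNAP": 5, "30S": 11, "50S": 14, "other": 17}
        for c in normalized_study["centroids"]:
            assert int(np.argmax(c.centroid)) + 1 == expected[c.label]


class TestAssignment:
    def _centroids(self):
        c30 = np.exp(-0.5 * ((np.arange(1, 21) - 11) / 1.2) ** 2)
        c50 = np.exp(-0.5 * ((np.arange(1, 21) - 14) / 1.2) ** 2)
        return [
            ReferenceCentroid("30S", c30 / c30.max(), 3),
            ReferenceCentroid("50S", c50 / c50.max(), 3),
        ]

    def test_centroid_query_scores_one(self):
        cents = self._centroids()
        a = assign_to_reference(_profile(cents[0].centroid), cents)
        assert a.label == "30S" and a.score == pytest.approx(1.0)

    def test_anticorrelated_query_unassigned(self):
        cents = self._centroids()
        q = _profile(1.0 - cents[0].centroid / cents[0].centroid.max())
        a = assign_to_reference(q, cents, r_min=0.8)
        assert a.label == UNASSIGNED

    def test_zero_variance_query_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            assign_to_reference(_profile(np.ones(20)), self._centroids())

    def test_no_centroids_rejected(self):
        with pytest.raises(ParameterError):
            assign_to_reference(_profile(np.arange(20.0)), [])

    def test_recovery_accuracy_on_default_simulation(self, normalized_study):
        acc = assignment_accuracy(
            normalized_study["assignments"], normalized_study["truth"]
        )
        assert acc >= 0.95

    def test_assignment_invariant_under_raw_rescaling(self, normalized_study):
        """Scaling a protein's raw intensities does not change its
        assignment (normalization guarantees this end to end)."""
        from gradscope.profiles import normalize_profile

        corrected = normalized_study["corrected"]
        centroids = normalized_study["centroids"]
        row = corrected.row("phage_rib50_001")
        p1 = normalize_profile(row, "q")
        p2 = normalize_profile(row * 37.5, "q")
        a1 = assign_to_reference(p1, centroids)
        a2 = assign_to_reference(p2, centroids)
        assert (a1.label, pytest.approx(a1.score)) == (a2.label, a2.score)
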