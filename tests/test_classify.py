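"""Unit and property tests for the three-pronged classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.neighbors import NearestCentroid

from tgxddi.classify import (
    DDI,
    INCONCLUSIVE,
    NON_DDI,
    DendrogramBranchClassifier,
    LabeledProfileSet,
    MethodCall,
    Pc1BandClassifier,
    ShrunkenCentroidClassifier,
    ThreeProngedClassifier,
    combine_method_calls,
    fit_pca,
    hca_call,
    load_model,
    nsc_posterior,
    pa_call,
    pca_call,
    save_model,
    three_pronged_call,
    train_nsc,
)
from tgxddi.errors import (
    AlignmentError,
    DegenerateModelError,
    DegenerateSeparationError,
)

from .oracles import class_centroids, naive_average_linkage, naive_two_cut, pca_scores_eigh


# ---------------------------------------------------------------------------
# Nearest shrunken centroid
# ---------------------------------------------------------------------------

class TestShrunkenCentroid:
    def test_zero_shrinkage_reproduces_class_means(self, toy_training):
        model = train_nsc(toy_training, shrinkage=0.0)
        X, y = toy_training.X.to_numpy(), toy_training.y.to_numpy()
        expected = class_centroids(X, y)
        for k, cls in enumerate(model.classes_):
            np.testing.assert_allclose(model.centroids_[k], expected[cls])

    def test_full_shrinkage_collapses_to_overall_centroid(self, toy_training):
        model = train_nsc(toy_training, shrinkage=1e6)
        for row in model.centroids_:
            np.testing.assert_allclose(row, model.overall_centroid_)

    def test_centroids_match_sklearn_oracle_under_shrinkage(self, rng):
        """Partial shrinkage agrees with the reference soft-threshold
        implementation in scikit-learn's NearestCentroid."""
        X = rng.normal(size=(12, 6))
        y = np.array([DDI] * 6 + [NON_DDI] * 6)
        for delta in (0.3, 1.0):
            ours = ShrunkenCentroidClassifier(shrinkage=delta).fit(X, y)
            ref = NearestCentroid(shrink_threshold=delta).fit(X, y)
            np.testing.assert_allclose(ours.centroids_, ref.centroids_, atol=1e-10)

    def test_posterior_at_ddi_centroid_is_confident(self, toy_training):
        model = train_nsc(toy_training)
        profile = pd.DataFrame(
            [toy_training.profiles[["d1", "d2"]].mean(axis=1)],
            columns=toy_training.profiles.index,
        )
        post = nsc_posterior(model, profile)
        assert post[DDI] > 0.99

    def test_equidistant_profile_splits_posterior(self, toy_training):
        model = train_nsc(toy_training)
        midpoint = pd.DataFrame(
            [[0.0, 0.0]], columns=list(toy_training.profiles.index)
        )
        post = nsc_posterior(model, midpoint)
        assert post[DDI] == pytest.approx(0.5)
        assert post[NON_DDI] == pytest.approx(0.5)

    def test_priors_shift_the_posterior(self, toy_training):
        # classes_ is sorted, so priors are (DDI, nonDDI).
        model = ShrunkenCentroidClassifier(priors=(0.9, 0.1)).fit(
            toy_training.X, toy_training.y
        )
        midpoint = np.zeros((1, 2))
        proba = model.predict_proba(midpoint)[0]
        assert proba[list(model.classes_).index(DDI)] > 0.5

    def test_gene_mismatch_raises_alignment_error(self, toy_training):
        model = train_nsc(toy_training)
        bad = pd.DataFrame([[0.0, 0.0]], columns=["g1", "other"])
        with pytest.raises(AlignmentError):
            nsc_posterior(model, bad)

    def test_zero_variance_with_zero_s0_is_degenerate(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [3.0, 4.0], [3.0, 4.0]])
        y = np.array([DDI, DDI, NON_DDI, NON_DDI])
        with pytest.raises(DegenerateModelError):
            ShrunkenCentroidClassifier(s0=0.0).fit(X, y)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=2,
            max_size=2,
        )
    )
    def test_posterior_normalization_property(self, values):
        """Posteriors are positive and sum to 1 for any finite profile."""
        profiles = pd.DataFrame(
            {
                "d1": [9.0, 10.0],
                "d2": [11.0, 10.0],
                "n1": [-9.0, -10.0],
                "n2": [-11.0, -10.0],
            },
            index=["g1", "g2"],
        )
        labels = pd.Series({"d1": DDI, "d2": DDI, "n1": NON_DDI, "n2": NON_DDI})
        model = train_nsc(LabeledProfileSet(profiles, labels))
        proba = model.predict_proba(np.array([values]))[0]
        # The softmax may underflow to exactly 0 far from a centroid, so
        # nonnegativity (not strict positivity) is the invariant.
        assert (proba >= 0).all() and (proba <= 1).all()
        assert proba.sum() == pytest.approx(1.0)


def test_pa_call_threshold_rule():
    assert pa_call({DDI: 0.95, NON_DDI: 0.05}).call == DDI
    assert pa_call({DDI: 0.08, NON_DDI: 0.92}).call == NON_DDI
    assert pa_call({DDI: 0.85, NON_DDI: 0.15}).call == INCONCLUSIVE
    assert pa_call({DDI: 0.9, NON_DDI: 0.1}).call == DDI  # threshold inclusive


# ---------------------------------------------------------------------------
# PCA prong
# ---------------------------------------------------------------------------

class TestPc1Band:
    def test_training_scores_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(5, 4))
        X[:3] += 3.0  # separate the classes
        y = np.array([DDI, DDI, DDI, NON_DDI, NON_DDI])
        model = Pc1BandClassifier().fit(X, y)
        ref = pca_scores_eigh(X)
        # Signs are convention; compare componentwise magnitudes.
        np.testing.assert_allclose(
            np.abs(model.training_scores_), np.abs(ref), atol=1e-8
        )

    def test_orientation_puts_ddi_mean_positive(self, training):
        model = fit_pca(training)
        assert model.pc1_class_means_[DDI] > model.pc1_class_means_[NON_DDI]
        assert model.pc1_class_means_[DDI] > 0

    def test_training_scores_are_centered(self, training):
        model = fit_pca(training)
        np.testing.assert_allclose(
            model.training_scores_.mean(axis=0), 0.0, atol=1e-9
        )

    def test_band_arithmetic_on_toy_means(self):
        """With all variance on one gene (class means at +/-10 on PC1) and
        band fraction 0.1, the band has half-width 2 around 0."""
        profiles = pd.DataFrame(
            {
                "d1": [9.0, 5.0],
                "d2": [11.0, 5.0],
                "n1": [-9.0, 5.0],
                "n2": [-11.0, 5.0],
            },
            index=["g1", "g2"],
        )
        labels = pd.Series({"d1": DDI, "d2": DDI, "n1": NON_DDI, "n2": NON_DDI})
        model = fit_pca(LabeledProfileSet(profiles, labels), band_fraction=0.1)
        assert model.band_halfwidth_ == pytest.approx(2.0)
        assert model.midpoint_ == pytest.approx(0.0)
        direction = model.components_[0]

        def profile_at(score):
            return pd.DataFrame(
                [model.mean_ + score * direction],
                columns=list(profiles.index),
            )

        assert pca_call(model, profile_at(1.9)).call == INCONCLUSIVE
        assert pca_call(model, profile_at(2.1)).call == DDI
        assert pca_call(model, profile_at(-2.1)).call == NON_DDI
        assert pca_call(model, profile_at(0.0)).call == INCONCLUSIVE

    def test_zero_band_has_no_inconclusive_zone(self, toy_training):
        model = fit_pca(toy_training, band_fraction=0.0)
        calls = model.predict(np.array([[0.5, 0.5], [-0.5, -0.5]]))
        assert INCONCLUSIVE not in calls

    def test_profile_at_class_mean_is_called(self, toy_training):
        model = fit_pca(toy_training, band_fraction=0.1)
        ddi_mean = toy_training.profiles[["d1", "d2"]].mean(axis=1)
        call = pca_call(model, pd.DataFrame([ddi_mean]))
        assert call.call == DDI

    def test_identical_class_means_raise(self):
        X = np.array([[1.0], [-1.0], [2.0], [-2.0]])
        y = np.array([DDI, DDI, NON_DDI, NON_DDI])
        with pytest.raises(DegenerateSeparationError):
            Pc1BandClassifier().fit(X, y)

    def test_band_fraction_bounds(self, toy_training):
        with pytest.raises(ValueError):
            fit_pca(toy_training, band_fraction=0.5)


# ---------------------------------------------------------------------------
# HCA prong
# ---------------------------------------------------------------------------

class TestDendrogramBranch:
    def test_duplicate_of_training_agent_gets_its_class(self, toy_training):
        profile = toy_training.profiles["d1"].to_frame().T
        assert hca_call(toy_training, profile).call == DDI
        profile = toy_training.profiles["n2"].to_frame().T
        assert hca_call(toy_training, profile).call == NON_DDI

    def test_far_outlier_is_singleton_inconclusive(self, toy_training):
        outlier = pd.DataFrame(
            [[0.0, 1000.0]], columns=list(toy_training.profiles.index)
        )
        call = hca_call(toy_training, outlier)
        assert call.call == INCONCLUSIVE

    def test_mixed_branch_without_majority_is_inconclusive(self):
        """A branch holding 3 DDI and 3 non-DDI training agents cannot give
        a call at the default strict-majority purity threshold."""
        pts = {
            "d1": [0.0, 0.0], "d2": [0.1, 0.0], "d3": [0.2, 0.0],
            "n1": [0.05, 0.0], "n2": [0.15, 0.0], "n3": [0.25, 0.0],
            "d4": [100.0, 100.0], "n4": [100.1, 100.0],
        }
        labels = pd.Series(
            {k: (DDI if k.startswith("d") else NON_DDI) for k in pts}
        )
        training = LabeledProfileSet(
            profiles=pd.DataFrame(pts, index=["g1", "g2"]), labels=labels
        )
        test = pd.DataFrame([[0.12, 0.0]], columns=["g1", "g2"])
        assert hca_call(training, test).call == INCONCLUSIVE

    def test_merge_order_matches_bruteforce_oracle(self, rng):
        """scipy's average-linkage dendrogram agrees with a naive O(n^3)
        agglomerative implementation on small point sets."""
        for _ in range(5):
            pts = rng.normal(size=(6, 3))
            Z = scipy_linkage(pdist(pts), method="average")
            ref = naive_average_linkage(pts)
            np.testing.assert_allclose(
                sorted(Z[:, 2]), sorted(m[2] for m in ref), atol=1e-10
            )
            # The 2-cluster cut partitions identically.
            cut = fcluster(Z, t=2, criterion="maxclust")
            ours = [frozenset(np.flatnonzero(cut == c)) for c in (1, 2)]
            assert set(ours) == set(naive_two_cut(pts))

    def test_invalid_metric_and_linkage_rejected(self, toy_training):
        with pytest.raises(ValueError):
            DendrogramBranchClassifier(metric="hamming").fit(
                toy_training.X, toy_training.y
            )
        with pytest.raises(ValueError):
            DendrogramBranchClassifier(linkage="centroid").fit(
                toy_training.X, toy_training.y
            )


# ---------------------------------------------------------------------------
# Call combination
# ---------------------------------------------------------------------------

_RANK = {NON_DDI: 0, INCONCLUSIVE: 1, DDI: 2}


class TestCombination:
    @pytest.mark.parametrize(
        "calls, expected",
        [
            ((DDI, NON_DDI, NON_DDI), DDI),
            ((NON_DDI, NON_DDI, NON_DDI), NON_DDI),
            ((NON_DDI, INCONCLUSIVE, INCONCLUSIVE), INCONCLUSIVE),
            ((NON_DDI, NON_DDI, INCONCLUSIVE), NON_DDI),
            ((INCONCLUSIVE, INCONCLUSIVE, INCONCLUSIVE), INCONCLUSIVE),
            ((INCONCLUSIVE, DDI, INCONCLUSIVE), DDI),
        ],
    )
    def test_combination_rule(self, calls, expected):
        assert combine_method_calls(*calls) == expected

    def test_conservatism_monotonicity(self):
        """Upgrading any single method call toward DDI never moves the
        combined call away from DDI (checked over all combinations)."""
        states = (NON_DDI, INCONCLUSIVE, DDI)
        for combo in itertools.product(states, repeat=3):
            base = combine_method_calls(*combo)
            for i in range(3):
                for upgraded in states:
                    if _RANK[upgraded] <= _RANK[combo[i]]:
                        continue
                    new = list(combo)
                    new[i] = upgraded
                    assert _RANK[combine_method_calls(*new)] >= _RANK[base]

    def test_three_pronged_call_wraps_method_calls(self):
        sc = three_pronged_call(
            MethodCall("PA", DDI, 0.97),
            MethodCall("PCA", NON_DDI, -1.0),
            MethodCall("HCA", NON_DDI, 1.0),
            sample_id="s1",
        )
        assert sc.call == DDI
        assert sc.sample_id == "s1"


# ---------------------------------------------------------------------------
# Meta-estimator
# ---------------------------------------------------------------------------

class TestThreePronged:
    def test_permutation_invariance(self, training, rng):
        """Permuting gene order identically in training and test leaves
        every call unchanged."""
        clf = ThreeProngedClassifier().fit(training)
        test = training.profiles.iloc[:, :4].T + rng.normal(
            0, 0.1, size=(4, training.profiles.shape[0])
        )
        baseline = [sc.call for sc in clf.classify(test)]

        perm = rng.permutation(training.profiles.index.to_numpy())
        shuffled = LabeledProfileSet(
            profiles=training.profiles.loc[perm], labels=training.labels
        )
        clf2 = ThreeProngedClassifier().fit(shuffled)
        permuted_calls = [sc.call for sc in clf2.classify(test[perm])]
        assert permuted_calls == baseline

    def test_recovers_training_labels(self, training):
        clf = ThreeProngedClassifier().fit(training)
        calls = clf.predict(training.X)
        assert (calls == training.y.to_numpy()).all()

    def test_model_json_round_trip(self, training, tmp_path, rng):
        clf = ThreeProngedClassifier().fit(training)
        path = tmp_path / "model.json"
        save_model(clf, path)
        loaded = load_model(path)
        test = pd.DataFrame(
            rng.normal(size=(5, training.profiles.shape[0])),
            columns=list(training.profiles.index),
        )
        original = [(s.call, s.pa.call, s.pca.call, s.hca.call) for s in clf.classify(test)]
        restored = [(s.call, s.pa.call, s.pca.call, s.hca.call) for s in loaded.classify(test)]
        assert original == restored
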