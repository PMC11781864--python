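"""Naive-Bayes decoder, LOOCV, shuffle significance, cluster permutation."""

import numpy as np
import pytest

from contextmod import (PoissonNBDecoder, cluster_permutation, loocv_accuracy,
                        loocv_predictions, mode_labels, nb_loocv,
                        shuffle_significance, time_resolved, trial_features)
from contextmod.decoding import (CHANCE, confusion_matrix, find_clusters,
                                 sign_test_bins, sliding_window_counts)
from oracles import brute_force_nb_loocv


def tuned_counts(rng, n_per_class=15, n_units=12, n_tuned=None):
    """Count matrix for a 4-class session; tuned units prefer one identity.

    By default every unit is tuned; pass ``n_tuned`` for the realistic
    sparse composition (most recorded units unresponsive).
    """
    ident = np.repeat([1, 1, 2, 2], n_per_class)
    story = np.tile(np.repeat([1, 2], n_per_class), 2)
    if n_tuned is None:
        pref = rng.integers(1, 3, n_units)
    else:
        pref = np.array([1, 2] * (n_tuned // 2) + [0] * (n_units - n_tuned))
    lam = np.where(ident[:, None] == pref[None, :], 15.0, 2.5)
    return rng.poisson(lam), ident, story


# ---------------------------------------------------------------------------
# estimator API
# ---------------------------------------------------------------------------

def test_estimator_sklearn_conventions(rng):
    X, ident, story = tuned_counts(rng)
    y = mode_labels(ident, story, "identity")
    est = PoissonNBDecoder()
    assert est.get_params() == {"pseudocount": 0.5, "likelihood": "poisson",
                                "priors": "uniform"}
    est.set_params(pseudocount=1.0).fit(X, y)
    assert est.rate_.shape == (2, X.shape[1])
    assert est.classes_.tolist() == [1, 2]
    proba = est.predict_proba(X[:5])
    np.testing.assert_allclose(proba.sum(axis=1), 1.0)
    assert est.predict(X).shape == (X.shape[0],)
    assert est.score(X, y) > 0.9


def test_estimator_in_sklearn_cross_validation(rng):
    from sklearn.model_selection import LeaveOneOut, cross_val_score
    X, ident, story = tuned_counts(rng, n_per_class=5, n_units=8)
    y = mode_labels(ident, story, "identity")
    scores = cross_val_score(PoissonNBDecoder(), X, y, cv=LeaveOneOut())
    assert scores.mean() > 0.8


def test_gaussian_variant_runs(rng):
    X, ident, story = tuned_counts(rng)
    est = PoissonNBDecoder(likelihood="gaussian").fit(X, ident)
    assert (est.predict(X) == ident).mean() > 0.9


# ---------------------------------------------------------------------------
# LOOCV correctness
# ---------------------------------------------------------------------------

def test_loocv_matches_brute_force_enumeration(rng):
    """Vectorized LOOCV equals the exhaustive per-fold Bayes-rule oracle."""
    for trial in range(5):
        n_per = rng.integers(3, 6)
        X = rng.poisson(3, (4 * n_per, rng.integers(2, 5)))
        y = np.repeat(np.arange(4), n_per)
        for priors in ("uniform", "empirical"):
            got = loocv_predictions(X, y, 0.5, priors)
            want = brute_force_nb_loocv(X, y, 0.5, priors)
            np.testing.assert_array_equal(got, want)


def test_loocv_matches_per_fold_estimator_refit(rng):
    """Vectorized path equals literally refitting the estimator per fold."""
    X, ident, story = tuned_counts(rng, n_per_class=6, n_units=5)
    y = mode_labels(ident, story, "four_class")
    fast = loocv_predictions(X, y)
    mask = np.ones(len(y), dtype=bool)
    for i in range(len(y)):
        mask[i] = False
        est = PoissonNBDecoder().fit(X[mask], y[mask])
        assert est.predict(X[i:i + 1])[0] == fast[i]
        mask[i] = True


def test_perfectly_separable_unit_gives_accuracy_one(rng):
    # one unit with disjoint count supports per class
    y = np.repeat([0, 1], 10)
    X = np.where(y == 0, 2, 40)[:, None] + rng.integers(0, 2, (20, 1))
    assert loocv_accuracy(X, y) == 1.0


def test_shuffled_labels_accuracy_near_chance(rng):
    X, ident, story = tuned_counts(rng, n_per_class=15, n_units=20)
    accs = [loocv_accuracy(X, rng.permutation(mode_labels(ident, story, "four_class")))
            for _ in range(30)]
    assert abs(np.mean(accs) - 0.25) < 0.05


def test_loocv_invariances(rng):
    X, ident, story = tuned_counts(rng, n_per_class=8, n_units=6)
    y = mode_labels(ident, story, "four_class")
    base = loocv_predictions(X, y)
    # unit reordering
    perm = rng.permutation(X.shape[1])
    np.testing.assert_array_equal(loocv_predictions(X[:, perm], y), base)
    # adding an uninformative all-zero unit (smoothing keeps it constant)
    X_aug = np.column_stack([X, np.zeros(len(y), dtype=int)])
    np.testing.assert_array_equal(loocv_predictions(X_aug, y), base)


def test_loocv_requires_two_per_class():
    X = np.ones((3, 2))
    with pytest.raises(ValueError):
        loocv_predictions(X, np.array([0, 1, 1]))


# ---------------------------------------------------------------------------
# session-level results
# ---------------------------------------------------------------------------

def test_confusion_rows_and_accuracy_consistency(rng):
    X, ident, story = tuned_counts(rng)
    res = nb_loocv(X, ident, story, "four_class")
    np.testing.assert_allclose(res.confusion.sum(axis=1), 1.0, atol=1e-9)
    y = mode_labels(ident, story, "four_class")
    freq = np.array([(y == c).mean() for c in res.classes])
    assert res.accuracy == pytest.approx(float(np.diag(res.confusion) @ freq))


def test_identity_only_session_has_block_confusion(rng):
    """Identity decodes; stories within an identity are interchangeable.

    Uses the realistic sparse composition (two tuned units among many).
    Story assignments within an identity carry no signal; leave-one-out
    even tilts them slightly below chance (the held-out trial's own story
    class is depleted of its identity signature), so the within-identity
    split is checked loosely and the story decoder against a generous band
    around chance — the same signature the full paradigm shows.
    """
    between = np.zeros(4)
    c00 = []
    acc_id, acc_story = [], []
    for rep in range(10):
        X, ident, story = tuned_counts(rng, n_per_class=15, n_units=20,
                                       n_tuned=2)
        res = nb_loocv(X, ident, story, "four_class")
        c = res.confusion
        between[rep % 4] += c[0, 2] + c[0, 3] + c[1, 2] + c[1, 3]
        c00.append(c[0, 0])
        acc_id.append(nb_loocv(X, ident, story, "identity").accuracy)
        acc_story.append(nb_loocv(X, ident, story, "story").accuracy)
    assert between.sum() / 10 < 0.2        # almost no cross-identity confusion
    assert 0.2 < np.mean(c00) < 0.8        # stories mixed within identity
    assert np.mean(acc_id) > 0.9
    assert 0.3 < np.mean(acc_story) < 0.6  # near (slightly below) chance


def test_shuffle_significance_tuned_vs_null(rng):
    X, ident, story = tuned_counts(rng, n_per_class=10, n_units=10)
    _, p, _ = shuffle_significance(X, ident, story, "identity",
                                   n_shuffles=500, rng=rng)
    assert p < 0.01
    X0 = rng.poisson(3, X.shape)
    acc0, p0, surr = shuffle_significance(X0, ident, story, "identity",
                                          n_shuffles=500, rng=rng)
    assert p0 > 0.01
    assert abs(surr.mean() - 0.5) < 0.05


def test_trial_features_rates(rng):
    trains = [np.array([0.25, 0.3, 0.4, 0.6]), np.array([])]
    feats = trial_features(trains, np.array([0.0]), [(0.2, 0.7), (0.2, 0.7)])
    assert feats.shape == (1, 2)
    assert feats[0, 0] == pytest.approx(8.0)   # 4 spikes / 0.5 s
    assert feats[0, 1] == 0.0


# ---------------------------------------------------------------------------
# sliding windows, sign tests, clusters
# ---------------------------------------------------------------------------

def test_sliding_window_alignment():
    spikes = np.array([0.05, 0.26, 0.28])
    times = np.array([0.2])
    trailing = sliding_window_counts(spikes, np.array([0.0]), times, 0.2, "trailing")
    centered = sliding_window_counts(spikes, np.array([0.0]), times, 0.2, "center")
    np.testing.assert_array_equal(trailing[0], [1])   # [0.0, 0.2): 0.05 only
    np.testing.assert_array_equal(centered[0], [2])   # [0.1, 0.3): 0.26, 0.28


def test_sign_test_matches_binomtest():
    from scipy.stats import binomtest
    vals = np.array([[0.6], [0.7], [0.4], [0.8], [0.9], [0.55]])
    p, stat = sign_test_bins(vals, 0.5)
    assert stat[0] == 5 - 1
    want = binomtest(5, 6, 0.5, alternative="greater").pvalue
    assert p[0] == pytest.approx(want)


def test_find_clusters_duration_rule():
    times = np.arange(0, 1.0, 0.025)
    p = np.ones_like(times)
    stat = np.full_like(times, 6.0)
    p[10:14] = 0.001   # 4 bins x 25 ms = 100 ms -> cluster
    p[20:22] = 0.001   # 50 ms -> too short
    clusters = find_clusters(p, stat, times, alpha=0.01, min_duration=0.1)
    assert len(clusters) == 1
    assert clusters[0].start == pytest.approx(times[10])
    assert clusters[0].stat == pytest.approx(24.0)


def test_cluster_permutation_p_floor(rng):
    """Observed cluster sum above all 1000 surrogates -> p < 0.001."""
    # 8 sessions: the across-session sign test can reach p < 0.01
    # (with 6 or fewer its smallest attainable p is 1/64 > 0.01)
    times = np.arange(0, 1.0, 0.025)
    observed = np.full((8, times.size), 0.5)
    observed[:, 10:20] = 0.95          # strong sustained decoding
    surrogates = 0.5 + 0.02 * rng.standard_normal((1000, 8, times.size))
    clusters = cluster_permutation(observed, surrogates, times, 0.5)
    assert len(clusters) == 1
    assert clusters[0].p < 0.001
    assert clusters[0].p == pytest.approx(1 / 1001)


def test_cluster_permutation_null_case(rng):
    times = np.arange(0, 1.0, 0.025)
    observed = 0.5 + 0.02 * rng.standard_normal((8, times.size))
    surrogates = 0.5 + 0.02 * rng.standard_normal((200, 8, times.size))
    clusters = cluster_permutation(observed, surrogates, times, 0.5)
    assert clusters == []


def test_time_resolved_recovers_identity_cluster(rng):
    """Tuned sessions: an identity cluster appears around the response, and
    story decoding produces none."""
    times = np.arange(0.05, 1.0, 0.025)
    counts, idents, stories = [], [], []
    for s in range(8):
        X, ident, story = None, None, None
        n_per, n_units = 10, 8
        ident = np.repeat([1, 1, 2, 2], n_per)
        story = np.tile(np.repeat([1, 2], n_per), 2)
        pref = rng.integers(1, 3, n_units)
        X3 = np.empty((4 * n_per, n_units, times.size))
        for b, t in enumerate(times):
            # response from 0.3 to 0.8 s; 250 ms trailing window
            overlap = max(0.0, min(t, 0.8) - max(t - 0.25, 0.3))
            lam = 2.5 * 0.25 + np.where(ident[:, None] == pref[None, :],
                                        27.5, 0.0) * overlap
            X3[:, :, b] = rng.poisson(lam)
        counts.append(X3)
        idents.append(ident)
        stories.append(story)
    res = time_resolved(counts, idents, stories, times, n_perm=100, rng=rng)
    assert res.clusters_story == []
    assert len(res.clusters_identity) >= 1
    first = res.clusters_identity[0]
    assert first.p is not None and first.p < 0.05
    assert 0.25 <= first.start <= 0.45    # near the 0.3 s response onset
    assert len(res.clusters_diff) >= 1
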