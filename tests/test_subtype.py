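"""Consensus clustering, marker detection, Fisher enrichment, SVM transfer."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from flora.quantify_de import ExpressionMatrix
from flora.simdata import SimConfig, make_cohort
from flora.subtype import (
    consensus_cluster,
    fisher_enrichment,
    subtype_markers,
    train_transfer_classifier,
)


def _blob_matrix(n_per=15, n_feat=40, sep=6.0, k=2, seed=0):
    rng = np.random.default_rng(seed)
    cols, blocks = [], []
    for c in range(k):
        mu = np.zeros(n_feat)
        mu[c * (n_feat // k) : (c + 1) * (n_feat // k)] = sep
        blocks.append(rng.normal(mu[:, None], 1.0, size=(n_feat, n_per)))
        cols += [f"c{c}_s{j}" for j in range(n_per)]
    vals = pd.DataFrame(
        np.exp2(np.hstack(blocks)), index=[f"f{i}" for i in range(n_feat)],
        columns=cols,
    )
    truth = pd.Series(np.repeat(np.arange(k), n_per), index=cols)
    return ExpressionMatrix(vals, pd.DataFrame(index=cols), "FPKM"), truth


class TestConsensus:
    def test_two_separated_blobs_give_block_perfect_consensus(self):
        expr, truth = _blob_matrix(k=2, seed=1)
        results, _ = consensus_cluster(expr, k_range=(2,), n_resamples=30, seed=1)
        cm = results[2].consensus_matrix.to_numpy()
        labels = truth.to_numpy()
        same = labels[:, None] == labels[None, :]
        cosampled = cm > -1  # all pairs
        assert np.all(cm[same & cosampled] >= 0.999) or np.all(
            np.abs(cm[same] - 1) < 1e-9
        )
        assert np.all(cm[~same] <= 1e-9)

    def test_same_seed_reproduces_labels(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        r1, k1 = consensus_cluster(tum, k_range=(2, 3), n_resamples=25, seed=4)
        r2, k2 = consensus_cluster(tum, k_range=(2, 3), n_resamples=25, seed=4)
        assert k1 == k2
        assert (r1[3].labels == r2[3].labels).all()

    def test_planted_three_subtypes_recovered(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        results, k = consensus_cluster(tum, k_range=(2, 3, 4), n_resamples=30, seed=5)
        assert k == 3
        ari = adjusted_rand_score(
            truth.reindex(results[3].labels.index), results[3].labels
        )
        assert ari >= 0.9

    def test_consensus_matrix_is_valid(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        results, _ = consensus_cluster(tum, k_range=(3,), n_resamples=25, seed=6)
        cm = results[3].consensus_matrix.to_numpy()
        assert np.allclose(cm, cm.T)
        assert np.allclose(np.diag(cm), 1.0)
        assert cm.min() >= 0 and cm.max() <= 1

    def test_too_few_resamples_is_error(self):
        expr, _ = _blob_matrix()
        with pytest.raises(ValueError):
            consensus_cluster(expr, k_range=(2,), n_resamples=5, seed=0)

    def test_zero_variance_features_are_error(self):
        cols = [f"s{j}" for j in range(20)]
        vals = pd.DataFrame(
            np.ones((10, 20)), index=[f"f{i}" for i in range(10)], columns=cols
        )
        expr = ExpressionMatrix(vals, pd.DataFrame(index=cols), "FPKM")
        with pytest.raises(ValueError):
            consensus_cluster(expr, k_range=(2,), n_resamples=25, seed=0)


class TestMarkers:
    def test_exclusive_feature_marks_its_cluster(self):
        expr, truth = _blob_matrix(k=2, seed=2)
        markers = subtype_markers(expr, truth)
        # features 0..19 are high in cluster 0, 20..39 in cluster 1
        assert "f0" in markers[0]
        assert "f20" in markers[1]
        assert not set(markers[0]) & set(markers[1])

    def test_planted_markers_recovered(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        markers = subtype_markers(tum, truth.loc[tum.sample_ids])
        cfg = SimConfig()
        for s in range(cfg.k_subtypes):
            lo = s * cfg.markers_per_subtype
            planted = {f"lnc{j}" for j in range(lo, lo + cfg.markers_per_subtype)}
            found = set(markers[s])
            assert len(found & planted) / len(planted) >= 0.9

    def test_label_permutation_yields_few_markers(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        rng = np.random.default_rng(7)
        perm = pd.Series(
            rng.permutation(truth.loc[tum.sample_ids].to_numpy()),
            index=tum.sample_ids,
        )
        markers = subtype_markers(tum, perm)
        n_called = sum(len(v) for v in markers.values())
        n_tests = len(tum.feature_ids) * 3
        assert n_called <= max(10, 0.05 * n_tests)

    def test_fewer_than_two_clusters_is_error(self):
        expr, truth = _blob_matrix(k=2, seed=3)
        with pytest.raises(ValueError):
            subtype_markers(expr, pd.Series(0, index=expr.sample_ids))


def _fisher_two_sided_oracle(a, b, c, d):
    """Exact enumeration: sum of probabilities of tables as or more extreme."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    p_obs = (
        math.comb(row1, a) * math.comb(n - row1, col1 - a) / math.comb(n, col1)
    )
    total = 0.0
    for x in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
        p = math.comb(row1, x) * math.comb(n - row1, col1 - x) / math.comb(n, col1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisher:
    def _run(self, a, b, c, d):
        labels = pd.Series(
            ["in"] * (a + b) + ["out"] * (c + d),
            index=[f"s{i}" for i in range(a + b + c + d)],
        )
        cats = pd.Series(
            ["yes"] * a + ["no"] * b + ["yes"] * c + ["no"] * d, index=labels.index
        )
        res = fisher_enrichment(labels, cats)
        row = res[(res["cluster"] == "in") & (res["category"] == "yes")].iloc[0]
        return row

    def test_balanced_table_gives_p_one(self):
        row = self._run(5, 5, 5, 5)
        assert row["p"] == pytest.approx(1.0)
        assert row["odds_ratio"] == pytest.approx(1.0)

    def test_perfect_association_flags_infinite_odds(self):
        row = self._run(10, 0, 0, 10)
        assert np.isinf(row["odds_ratio"])
        assert row["p"] == pytest.approx(_fisher_two_sided_oracle(10, 0, 0, 10))

    def test_matches_exact_enumeration_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 11, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            row = self._run(int(a), int(b), int(c), int(d))
            assert row["p"] == pytest.approx(
                _fisher_two_sided_oracle(int(a), int(b), int(c), int(d)), rel=1e-9
            )


class TestTransfer:
    def test_transfer_to_platform_shifted_cohort(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        clf = train_transfer_classifier(
            tum, truth.loc[tum.sample_ids], b.feature_ids, seed=9
        )
        pred = clf.predict(b)
        acc = (pred == truth.reindex(pred.index)).mean()
        assert acc >= 0.9

    def test_resubstitution_at_least_cv_estimate(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        clf = train_transfer_classifier(
            tum, truth.loc[tum.sample_ids], tum.feature_ids, seed=10
        )
        resub = (clf.predict(tum) == truth.loc[tum.sample_ids]).mean()
        assert resub >= clf.cv_accuracy - 1e-9

    def test_too_few_shared_features_is_error(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        with pytest.raises(ValueError):
            train_transfer_classifier(
                tum, truth.loc[tum.sample_ids], ["lnc0"], seed=0
            )

    def test_small_training_class_is_error(self, cohort_fixture):
        a, b, clin, truth = cohort_fixture
        tum = a.subset_samples(a.samples_in_group("tumor"))
        labels = truth.loc[tum.sample_ids].copy()
        labels.iloc[:] = 0
        labels.iloc[:3] = 1
        with pytest.raises(ValueError):
            train_transfer_classifier(tum, labels, tum.feature_ids, seed=0)

    def test_accuracy_degrades_with_platform_noise_on_average(self):
        accs = []
        for noise in (0.2, 2.0, 6.0):
            acc_reps = []
            for rep in range(3):
                cfg = SimConfig(seed=100 + rep, platform_noise_sd=noise)
                a, b, clin, truth = make_cohort(cfg)
                tum = a.subset_samples(a.samples_in_group("tumor"))
                clf = train_transfer_classifier(
                    tum, truth.loc[tum.sample_ids], b.feature_ids, seed=rep
                )
                pred = clf.predict(b)
                acc_reps.append((pred == truth.reindex(pred.index)).mean())
            accs.append(np.mean(acc_reps))
        assert accs[0] >= accs[1] >= accs[2] - 0.05
        assert accs[0] > accs[2]
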