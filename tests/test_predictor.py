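import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from lncda.features import FeatureTable
from lncda.network import EntityRegistry
from lncda.predictor import (
    ForestParams,
    PredictorError,
    SampleSet,
    build_samples,
    cross_validate,
    rank_candidates,
    score_pairs,
    train_forest,
)

from conftest import adjacency


def auc_oracle(labels, scores):
    """Exhaustive concordant-pair count / (P * N), ties worth 0.5."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def encoded_tables(rng, l, d, width=6):
    lreg = EntityRegistry("lncRNA", tuple(f"L{i+1}" for i in range(l)))
    dreg = EntityRegistry("disease", tuple(f"D{j+1}" for j in range(d)))
    return (
        FeatureTable(lreg, rng.random((l, width)), "encoded"),
        FeatureTable(dreg, rng.random((d, width)), "encoded"),
    )


def separable_samples(rng, n=60, width=8, seed=0):
    pos = rng.normal(1.0, 0.2, size=(n // 2, width))
    neg = rng.normal(-1.0, 0.2, size=(n // 2, width))
    feats = np.vstack([pos, neg])
    labels = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
    pairs = [(i, 0) for i in range(n)]
    return SampleSet(pairs=pairs, features=feats, labels=labels, seed=seed)


class TestBuildSamples:
    def test_balanced_and_disjoint_on_small_matrix(self, rng):
        ld = adjacency([[1, 0, 0, 1], [0, 0, 0, 0], [0, 1, 0, 0], [0, 0, 0, 0]])
        lnc, dis = encoded_tables(rng, 4, 4)
        samples = build_samples(ld, lnc, dis, seed=11)
        assert len(samples) == 6 and samples.n_positive == 3
        zero_cells = {tuple(p) for p in np.argwhere(ld.values == 0)}
        negatives = [p for p, y in zip(samples.pairs, samples.labels) if y == 0]
        assert all(p in zero_cells for p in negatives)
        assert len(set(samples.pairs)) == len(samples.pairs)

    def test_same_seed_reproduces_negatives(self, rng):
        ld = adjacency((rng.random((8, 9)) < 0.3).astype(int))
        lnc, dis = encoded_tables(rng, 8, 9)
        s1 = build_samples(ld, lnc, dis, seed=5)
        s2 = build_samples(ld, lnc, dis, seed=5)
        assert s1.pairs == s2.pairs

    def test_pair_features_concatenate_lnc_then_disease(self, rng):
        ld = adjacency([[1, 0], [0, 0]])
        lnc, dis = encoded_tables(rng, 2, 2, width=3)
        samples = build_samples(ld, lnc, dis, seed=0)
        i, j = samples.pairs[0]
        np.testing.assert_array_equal(samples.features[0, :3], lnc.values[i])
        np.testing.assert_array_equal(samples.features[0, 3:], dis.values[j])

    def test_too_few_unlabeled_pairs_rejected(self, rng):
        ld = adjacency([[1, 1], [1, 0]])
        lnc, dis = encoded_tables(rng, 2, 2)
        with pytest.raises(PredictorError, match="unlabeled"):
            build_samples(ld, lnc, dis, seed=0)

    def test_reference_scale_sample_count(self, rng):
        # 2697 positives -> 5394 balanced samples
        flat = np.zeros(240 * 412, dtype=int)
        flat[rng.choice(flat.size, 2697, replace=False)] = 1
        ld = adjacency(flat.reshape(240, 412))
        lnc, dis = encoded_tables(rng, 240, 412, width=4)
        assert len(build_samples(ld, lnc, dis, seed=1)) == 5394


class TestTrainForest:
    def test_separable_data_fits_training_set(self, rng):
        samples = separable_samples(rng)
        clf = train_forest(samples, ForestParams(ntree=50, seed=0))
        acc = (clf.predict(samples.features) == samples.labels).mean()
        assert acc >= 0.99

    def test_scores_are_vote_fractions_in_unit_interval(self, rng):
        samples = separable_samples(rng)
        clf = train_forest(samples, ForestParams(ntree=50, seed=0))
        scores = score_pairs(clf, rng.normal(size=(20, 8)))
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_single_class_rejected(self, rng):
        samples = separable_samples(rng)
        samples.labels[:] = 1
        with pytest.raises(PredictorError, match="both classes"):
            train_forest(samples, ForestParams(ntree=10))

    def test_mtry_defaults_to_floor_sqrt(self):
        assert ForestParams().resolve_mtry(512) == 22
        assert ForestParams().resolve_mtry(652) == 25
        with pytest.raises(PredictorError):
            ForestParams(mtry=20).resolve_mtry(8)


class TestCrossValidate:
    def test_separable_data_gives_perfect_auc(self, rng):
        samples = separable_samples(rng)
        report = cross_validate(samples, ForestParams(ntree=30, seed=0), k=5, seed=1)
        assert report.mean_metrics["auc"] == 1.0

    def test_folds_partition_samples(self, rng):
        samples = separable_samples(rng)
        report = cross_validate(samples, ForestParams(ntree=10, seed=0), k=5, seed=1)
        assert (report.fold_assignments >= 0).all()
        assert set(report.fold_assignments) == set(range(5))

    def test_fold_auc_equals_concordant_pair_oracle(self, rng):
        # noisy features so scores are informative but imperfect
        feats = rng.normal(0, 1, size=(40, 4))
        labels = (feats[:, 0] + rng.normal(0, 1.5, 40) > 0).astype(int)
        samples = SampleSet([(i, 0) for i in range(40)], feats, labels, seed=0)
        report = cross_validate(samples, ForestParams(ntree=25, seed=3), k=4, seed=7)
        for fold, fm in enumerate(report.fold_metrics):
            mask = report.fold_assignments == fold
            expected = auc_oracle(labels[mask], report.pooled_scores[mask])
            assert fm["auc"] == pytest.approx(expected, abs=1e-12)

    def test_permuted_labels_give_chance_auc(self, rng):
        samples = separable_samples(rng, n=200)
        samples.labels = rng.permutation(samples.labels)
        report = cross_validate(samples, ForestParams(ntree=40, seed=0), k=5, seed=2)
        assert 0.4 <= report.mean_metrics["auc"] <= 0.6

    def test_mean_is_arithmetic_fold_average(self, rng):
        samples = separable_samples(rng)
        report = cross_validate(samples, ForestParams(ntree=10, seed=0), k=3, seed=1)
        means = report.mean_metrics
        for key in ("auc", "aupr", "recall", "accuracy", "f1"):
            assert 0.0 <= means[key] <= 1.0
            assert means[key] == pytest.approx(
                np.mean([fm[key] for fm in report.fold_metrics])
            )

    def test_oversized_k_rejected(self, rng):
        samples = separable_samples(rng, n=8)
        with pytest.raises(PredictorError, match="k="):
            cross_validate(samples, ForestParams(ntree=5), k=6, seed=0)


class TestRankCandidates:
    def _fit(self, rng, ld):
        lnc, dis = encoded_tables(rng, *ld.shape)
        samples = build_samples(ld, lnc, dis, seed=3)
        clf = train_forest(samples, ForestParams(ntree=30, seed=0))
        return clf, lnc, dis

    def test_top_n_truncates_to_candidate_count(self, rng):
        ld = adjacency([[1, 0], [0, 0], [0, 1]])
        clf, lnc, dis = self._fit(rng, ld)
        ranked = rank_candidates(clf, ld, lnc, dis, "D1", top_n=100)
        assert len(ranked.entries) == 2  # L2, L3 are the only candidates

    def test_only_unobserved_pairs_are_scored(self, rng):
        ld = adjacency([[1, 0], [0, 0], [0, 1]])
        clf, lnc, dis = self._fit(rng, ld)
        ranked = rank_candidates(clf, ld, lnc, dis, "D1", top_n=10)
        assert all(name != "L1" for name, _, _ in ranked.entries)

    def test_constant_features_fall_back_to_name_order(self, rng):
        ld = adjacency([[0, 1], [0, 1], [0, 1], [1, 0]])
        lreg = EntityRegistry("lncRNA", ("L1", "L2", "L3", "L4"))
        dreg = EntityRegistry("disease", ("D1", "D2"))
        lnc = FeatureTable(lreg, np.zeros((4, 3)), "encoded")
        dis = FeatureTable(dreg, np.zeros((2, 3)), "encoded")
        samples = build_samples(ld, lnc, dis, seed=0)
        clf = train_forest(samples, ForestParams(ntree=10, seed=0))
        ranked = rank_candidates(clf, ld, lnc, dis, "D1", top_n=5)
        names = [name for name, _, _ in ranked.entries]
        scores = [s for _, _, s in ranked.entries]
        assert len(set(scores)) == 1
        assert names == sorted(names)

    def test_scores_non_increasing(self, rng):
        ld = adjacency((rng.random((10, 6)) < 0.3).astype(int))
        clf, lnc, dis = self._fit(rng, ld)
        ranked = rank_candidates(clf, ld, lnc, dis, "D3", top_n=10)
        scores = [s for _, _, s in ranked.entries]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_unknown_disease_rejected(self, rng):
        ld = adjacency([[1, 0], [0, 0]])
        clf, lnc, dis = self._fit(rng, ld)
        with pytest.raises(Exception, match="unknown"):
            rank_candidates(clf, ld, lnc, dis, "nonexistent", top_n=5)

    def test_held_out_partners_rank_above_random_baseline(self, small_network, rng):
        from lncda.pipeline import PipelineConfig, run_pipeline

        ld, md, lm, truth = small_network
        cfg = PipelineConfig(
            lnc_latent_dim=8, dis_latent_dim=8, ae_epochs=40,
            ntree=60, cv_folds=3, seed=5,
        )
        res = run_pipeline(cfg, ld=ld, md=md, lm=lm)
        clf = train_forest(res.samples, ForestParams(ntree=60, seed=5))
        by_disease: dict[int, list[int]] = {}
        for i, j in truth:
            by_disease.setdefault(j, []).append(i)
        norm_ranks = []
        for j, lncs in by_disease.items():
            dname = ld.col_registry.names[j]
            ranked = rank_candidates(
                clf, ld, res.lnc_encoded, res.dis_encoded, dname,
                top_n=ld.shape[0],
            )
            positions = {name: r for r, (name, _, _) in enumerate(ranked.entries)}
            n = len(ranked.entries)
            for i in lncs:
                norm_ranks.append(positions[ld.row_registry.names[i]] / (n - 1))
        observed = np.mean(norm_ranks)
        # random scores put a candidate anywhere uniformly: mean ~0.5
        random_means = [
            np.mean(rng.random(len(norm_ranks))) for _ in range(100)
        ]
        assert observed < np.mean(random_means)
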