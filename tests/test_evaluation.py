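import numpy as np
import pytest

from dtiwlnet import (
    SamplingConfig,
    assemble_samples,
    aupr,
    auroc,
    cross_validate,
    heuristic_cross_validate,
    heuristic_score,
    heuristic_score_matrix,
    with_identity_similarity,
)
from dtiwlnet.evaluation import CVReport, _katz_matrix, _semi_bipartite_adjacency

from conftest import random_network

# -- independent metric oracles ----------------------------------------------


def auroc_pair_counting(scores, labels):
    """O(P*N) Mann-Whitney oracle; tied scores count one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def aupr_threshold_enumeration(scores, labels):
    """Step-wise AP oracle: sum precision * recall increments over the
    distinct score thresholds in descending order."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    ap, prev_recall = 0.0, 0.0
    n_pos = labels.sum()
    for t in sorted(set(scores), reverse=True):
        mask = scores >= t
        tp = int(labels[mask].sum())
        precision = tp / mask.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


class TestMetrics:
    def test_perfect_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_inverted_ranking(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_tied_scores_count_half(self):
        scores = [0.5, 0.5, 0.5, 0.3, 0.8, 0.5]
        labels = [1, 0, 1, 0, 1, 0]
        assert auroc(scores, labels) == pytest.approx(
            auroc_pair_counting(scores, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            aupr([0.1, 0.2], [0, 0])

    @pytest.mark.parametrize("seed", range(20))
    def test_small_case_suite_matches_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        # draw from a coarse grid so ties are frequent
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 0, 1
        assert auroc(scores, labels) == pytest.approx(
            auroc_pair_counting(scores, labels), abs=1e-12
        )
        assert aupr(scores, labels) == pytest.approx(
            aupr_threshold_enumeration(scores, labels), abs=1e-12
        )

    def test_random_scores_aupr_near_prevalence(self):
        rng = np.random.default_rng(0)
        n, p = 5000, 0.2
        labels = (rng.uniform(size=n) < p).astype(int)
        scores = rng.uniform(size=n)
        assert aupr(scores, labels) == pytest.approx(p, abs=0.03)


class TestHeuristics:
    def test_isolated_endpoint_scores_zero(self, isolated_pair_net):
        net = isolated_pair_net
        for method in ("PA", "CN", "Jaccard", "Katz"):
            assert heuristic_score(net, 2, 2, method) == 0.0

    def test_preferential_attachment_degree_product(self, toy_net):
        # d1 has degree 2, t3 degree 1
        assert heuristic_score(toy_net, 0, 2, "PA") == 2.0

    def test_jaccard_normalizes_cn(self, toy_net):
        cn = heuristic_score(toy_net, 0, 2, "CN")
        assert heuristic_score(toy_net, 0, 2, "Jaccard") == pytest.approx(cn / 3.0)

    def test_katz_matches_matrix_power_oracle(self):
        net = random_network(np.random.default_rng(6), 5, 4, density=0.3)
        A = _semi_bipartite_adjacency(net)
        beta, l_max = 0.01, 6
        expected = sum(
            beta**l * np.linalg.matrix_power(A, l) for l in range(1, l_max + 1)
        )
        assert np.allclose(_katz_matrix(net), expected, atol=1e-12)
        assert heuristic_score(net, 1, 2, "Katz") == pytest.approx(
            expected[1, net.m + 2], abs=1e-12
        )

    @pytest.mark.parametrize("method", ["PA", "CN", "Jaccard", "Katz"])
    def test_matrix_matches_scalar(self, method):
        net = random_network(np.random.default_rng(9), 6, 5, density=0.3)
        M = heuristic_score_matrix(net, method)
        for i in range(net.m):
            for j in range(net.n):
                assert M[i, j] == pytest.approx(
                    heuristic_score(net, i, j, method), abs=1e-12
                )

    def test_unknown_method_rejected(self, toy_net):
        with pytest.raises(ValueError, match="unknown heuristic"):
            heuristic_score(toy_net, 0, 0, "Adamic")


@pytest.fixture(scope="module")
def net_and_samples():
    net = random_network(np.random.default_rng(21), 20, 20, density=0.15)
    samples = assemble_samples(net, SamplingConfig(1.0, "all", seed=1))
    return net, samples


class TestCrossValidation:

    def test_folds_partition_samples(self, net_and_samples):
        net, samples = net_and_samples
        seen = []

        def recording_scorer(net_fold, train, test):
            seen.append([(s.drug_index, s.target_index, s.label) for s in test])
            return np.arange(len(test), dtype=float)

        cross_validate(net, samples, n_folds=5, seed=0, scorer=recording_scorer)
        flat = [p for fold in seen for p in fold]
        assert len(flat) == len(samples)
        assert len(set(flat)) == len(flat)

    def test_true_label_oracle_is_perfect(self, net_and_samples):
        net, samples = net_and_samples

        def oracle(net_fold, train, test):
            return np.array([float(s.y) for s in test])

        report = cross_validate(net, samples, n_folds=5, seed=0, scorer=oracle)
        assert all(a == 1.0 and p == 1.0 for a, p in report.per_fold)

    def test_report_summary_consistent_with_folds(self, net_and_samples):
        net, samples = net_and_samples
        report = heuristic_cross_validate(net, samples, "CN", n_folds=5, seed=0)
        rocs = [a for a, _ in report.per_fold]
        prs = [p for _, p in report.per_fold]
        assert report.mean_auroc == pytest.approx(np.mean(rocs), abs=1e-12)
        assert report.sd_auroc == pytest.approx(np.std(rocs, ddof=1), abs=1e-12)
        assert report.mean_aupr == pytest.approx(np.mean(prs), abs=1e-12)

    def test_reproducible_under_fixed_seed(self, net_and_samples):
        net, samples = net_and_samples
        a = heuristic_cross_validate(net, samples, "Katz", n_folds=5, seed=4)
        b = heuristic_cross_validate(net, samples, "Katz", n_folds=4 + 1, seed=4)
        assert a.per_fold == b.per_fold

    def test_test_positive_edges_removed_from_fold_network(self, net_and_samples):
        net, samples = net_and_samples

        def checking_scorer(net_fold, train, test):
            for s in test:
                if s.label == "positive":
                    assert net_fold.Y[s.drug_index, s.target_index] == 0
            for s in train:
                if s.label == "positive":
                    assert net_fold.Y[s.drug_index, s.target_index] == 1
            return np.arange(len(test), dtype=float)

        cross_validate(net, samples, n_folds=5, seed=2, scorer=checking_scorer)

    def test_too_few_positives_rejected(self):
        net = random_network(np.random.default_rng(30), 8, 8, density=0.05)
        samples = assemble_samples(net, SamplingConfig(1.0, "all", seed=0))
        n_pos = sum(s.y for s in samples)
        with pytest.raises(ValueError):
            cross_validate(net, samples, n_folds=n_pos + 1, seed=0,
                           scorer=lambda *_: np.zeros(1))


class TestAblation:
    def test_identity_replacement(self, toy_net):
        dt_only = with_identity_similarity(toy_net)
        assert np.array_equal(dt_only.S_D, np.eye(3))
        assert np.array_equal(dt_only.S_T, np.eye(3))
        assert np.array_equal(dt_only.Y, toy_net.Y)
        dd_kept = with_identity_similarity(toy_net, drugs=False)
        assert np.array_equal(dd_kept.S_D, toy_net.S_D)
        assert np.array_equal(dd_kept.S_T, np.eye(3))
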