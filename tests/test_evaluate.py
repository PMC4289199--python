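"""Tests for metrics, jackknife, grid search, ROC/AUC and split overlap."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import matthews_corrcoef

import recspot as rs


# --- metrics -----------------------------------------------------------------

def test_perfect_prediction():
    m = rs.metrics_from_counts(rs.ConfusionCounts(10, 10, 0, 0))
    assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)


def test_total_inversion():
    m = rs.metrics_from_counts(rs.ConfusionCounts(10, 10, 10, 10))
    assert (m.sn, m.sp, m.acc, m.mcc) == (0.0, 0.0, 0.0, -1.0)


def test_mixed_counts_against_contingency_oracle():
    m = rs.metrics_from_counts(rs.ConfusionCounts(10, 10, 2, 1))
    assert m.sn == pytest.approx(0.8)
    assert m.sp == pytest.approx(0.9)
    assert m.acc == pytest.approx(0.85)
    # independent oracle: rebuild per-sample labels and use sklearn's MCC
    y_true = [1] * 10 + [-1] * 10
    y_pred = [1] * 8 + [-1] * 2 + [-1] * 9 + [1]
    assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))


def test_zero_class_rejected():
    with pytest.raises(ValueError):
        rs.ConfusionCounts(0, 10, 0, 0)


def test_mcc_degenerate_marginal_is_zero():
    # everything predicted hotspot -> one contingency marginal empty
    m = rs.metrics_from_counts(rs.ConfusionCounts(5, 5, 0, 5))
    assert m.mcc == 0.0


@settings(derandomize=True, max_examples=100)
@given(
    n_hot=st.integers(1, 50),
    n_cold=st.integers(1, 50),
    data=st.data(),
)
def test_accuracy_identity(n_hot, n_cold, data):
    """Acc = (Sn*N+ + Sp*N-) / (N+ + N-) for all valid counts."""
    hot_missed = data.draw(st.integers(0, n_hot))
    cold_missed = data.draw(st.integers(0, n_cold))
    m = rs.metrics_from_counts(rs.ConfusionCounts(n_hot, n_cold, hot_missed, cold_missed))
    assert m.acc == pytest.approx((m.sn * n_hot + m.sp * n_cold) / (n_hot + n_cold))


# --- jackknife ---------------------------------------------------------------

def test_separable_planted_data_perfect(planted_small):
    data, cfg = planted_small
    counts, _ = rs.jackknife_evaluate(data, C=32.0)
    assert rs.metrics_from_counts(counts).acc == 1.0


def test_permuted_labels_near_chance(planted_small):
    data, _ = planted_small
    cfg = rs.SyntheticConfig(n_hot=50, n_cold=60, length_range=(300, 500), seed=21)
    seqs, y = rs.generate_dataset(cfg)
    X, layout = rs.encode_dataset(seqs, k_max=2, params=rs.PseDncParams(omega=5))
    rng = np.random.default_rng(0)
    y_perm = rng.permutation(y)
    shuffled = rs.LabeledMatrix(X, y_perm, layout.names)
    counts, _ = rs.jackknife_evaluate(shuffled, C=32.0)
    assert 0.35 <= rs.metrics_from_counts(counts).acc <= 0.65


def test_matches_explicit_five_fold_loop():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(5, 3))
    y = np.array([1, 1, -1, -1, 1])
    data = rs.LabeledMatrix(X, y, ["a", "b", "c"])
    _, decisions = rs.jackknife_evaluate(data, C=2.0)
    for i in range(5):
        others = [j for j in range(5) if j != i]
        model = rs.fit_linear_svm(X[others], y[others], C=2.0)
        assert decisions[i] == pytest.approx(model.decision(X[i : i + 1])[0])


def test_feature_subset_restricts_columns():
    rng = np.random.default_rng(13)
    y = np.repeat([1, -1], 8)
    signal = y + 0.05 * rng.normal(size=16)
    X = np.column_stack([rng.normal(size=16), signal])
    data = rs.LabeledMatrix(X, y, ["noise", "signal"])
    counts, _ = rs.jackknife_evaluate(data, C=10.0, feature_subset=["signal"])
    assert rs.metrics_from_counts(counts).acc == 1.0


def test_too_few_samples_errors():
    with pytest.raises(ValueError):
        rs.jackknife_evaluate(
            rs.LabeledMatrix(np.ones((2, 1)), np.array([1, -1]), ["f"]), C=1.0
        )


def test_duplicated_tiny_set_converges_to_training_accuracy():
    X = np.array([[-1.0], [-0.8], [1.0], [0.8]])
    y = np.array([-1, -1, 1, 1])
    Xd, yd = np.tile(X, (5, 1)), np.tile(y, 5)
    data = rs.LabeledMatrix(Xd, yd, ["f"])
    counts, _ = rs.jackknife_evaluate(data, C=10.0)
    assert rs.metrics_from_counts(counts).acc == 1.0


# --- grid search -------------------------------------------------------------

def test_single_point_grid(planted_small):
    data, _ = planted_small
    ranking = rs.fscore_rank(data)
    res = rs.grid_search(data, ranking, rs.GridSpec(c_values=(8.0,), n_values=(3,)))
    assert res.best_c == 8.0 and res.best_dim == 3
    assert len(res.surface) == 1


def test_duplicated_c_values_idempotent(planted_small):
    data, _ = planted_small
    ranking = rs.fscore_rank(data)
    g1 = rs.GridSpec(c_values=(1.0, 1.0, 8.0), n_values=(2, 4))
    g2 = rs.GridSpec(c_values=(1.0, 8.0), n_values=(2, 4))
    r1, r2 = rs.grid_search(data, ranking, g1), rs.grid_search(data, ranking, g2)
    assert (r1.best_c, r1.best_dim) == (r2.best_c, r2.best_dim)
    assert r1.surface.equals(r2.surface)


def test_tie_prefers_smaller_n_then_smaller_c():
    # perfectly separable single informative feature: every grid point ties at 1.0
    X = np.array([[-1.0, 0.3], [-0.9, 0.1], [1.0, 0.2], [0.9, 0.4]] * 3)
    y = np.array([-1, -1, 1, 1] * 3)
    data = rs.LabeledMatrix(X, y, ["sig", "noise"])
    ranking = rs.fscore_rank(data)
    res = rs.grid_search(data, ranking, rs.GridSpec(c_values=(4.0, 1.0), n_values=(2, 1)))
    assert (res.best_dim, res.best_c) == (1, 1.0)


def test_surface_reproducible(planted_small):
    data, _ = planted_small
    ranking = rs.fscore_rank(data)
    grid = rs.GridSpec(c_values=(1.0, 32.0), n_values=(2, 8))
    s1 = rs.grid_search(data, ranking, grid).surface
    s2 = rs.grid_search(data, ranking, grid).surface
    assert s1.equals(s2)


def test_planted_dimension_plateau():
    # exactly 5 weakly informative features: accuracy rises until the planted
    # dimension is reached, so the grid prefers N >= 5
    accs_by_seed = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        n = 60
        y = np.repeat([1, -1], n // 2)
        informative = [0.35 * y + rng.normal(size=n) for _ in range(5)]
        noise = [rng.normal(size=n) for _ in range(15)]
        X = np.column_stack(informative + noise)
        data = rs.LabeledMatrix(X, y, [f"f{i}" for i in range(20)])
        ranking = rs.fscore_rank(data)
        res = rs.grid_search(
            data, ranking, rs.GridSpec(c_values=(1.0,), n_values=tuple(range(1, 21)))
        )
        accs_by_seed.append(res.surface.set_index("N")["accuracy"])
        assert res.best_dim >= 5
    # on average the full planted set beats the single best feature
    mean_acc = sum(accs_by_seed) / len(accs_by_seed)
    assert mean_acc.loc[5] > mean_acc.loc[1]


def test_n_grid_exceeding_dimension_rejected(planted_small):
    data, _ = planted_small
    ranking = rs.fscore_rank(data)
    with pytest.raises(ValueError):
        rs.grid_search(data, ranking, rs.GridSpec(c_values=(1.0,), n_values=(data.dim + 1,)))


# --- ROC / AUC ---------------------------------------------------------------

def pairwise_auc(y, scores):
    """Exhaustive concordant-pair oracle (ties count half)."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == -1]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_ranking_auc_one():
    y = np.array([1, 1, -1, -1])
    _, auc = rs.roc_auc(y, y.astype(float))
    assert auc == 1.0


def test_inverted_ranking_auc_zero():
    y = np.array([1, 1, -1, -1])
    _, auc = rs.roc_auc(y, -y.astype(float))
    assert auc == 0.0


def test_auc_matches_pair_counting_on_toys():
    y = np.array([1, 1, 1, -1, -1, -1])
    for scores in (
        np.array([0.9, 0.1, 0.5, 0.4, 0.2, 0.8]),
        np.array([0.5, 0.5, 0.3, 0.5, 0.1, 0.2]),  # with ties
        np.array([1.0, 2.0, 3.0, -1.0, -2.0, -3.0]),
    ):
        _, auc = rs.roc_auc(y, scores)
        assert auc == pytest.approx(pairwise_auc(y, scores))


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(17)
    y = np.where(rng.random(30) > 0.5, 1, -1)
    y[:2] = [1, -1]
    scores = rng.normal(size=30)
    _, a1 = rs.roc_auc(y, scores)
    _, a2 = rs.roc_auc(y, np.exp(scores) * 3 + 7)
    assert a1 == pytest.approx(a2)


def test_constant_scores_auc_half():
    y = np.array([1, -1, 1, -1])
    _, auc = rs.roc_auc(y, np.zeros(4))
    assert auc == 0.5


def test_roc_endpoints_and_monotone_fpr():
    rng = np.random.default_rng(23)
    y = np.where(rng.random(20) > 0.5, 1, -1)
    y[:2] = [1, -1]
    points, _ = rs.roc_auc(y, rng.normal(size=20))
    assert tuple(points[0]) == (0.0, 0.0)
    assert tuple(points[-1]) == (1.0, 1.0)
    assert (np.diff(points[:, 0]) >= 0).all()


def test_single_class_rejected():
    with pytest.raises(ValueError):
        rs.roc_auc(np.array([1, 1]), np.array([0.1, 0.2]))


# --- full protocol and overlap ----------------------------------------------

def test_evaluate_with_grid_report_fields(planted_small):
    data, _ = planted_small
    grid = rs.GridSpec(c_values=(1.0, 32.0), n_values=(2, 4, 8))
    report, ranking, result = rs.evaluate_with_grid(data, grid, ranker="fscore")
    assert 0 <= report.acc <= 1 and -1 <= report.mcc <= 1
    assert report.chosen_c in grid.c_values and report.chosen_dim in grid.n_values
    assert report.protocol == "jackknife"
    assert len(ranking.names) == data.dim


def test_nested_protocol_runs_and_is_recorded(planted_small):
    data, _ = planted_small
    grid = rs.GridSpec(c_values=(32.0,), n_values=(4,))
    report, _, _ = rs.evaluate_with_grid(data, grid, ranker="fscore", nested=True)
    assert report.protocol == "jackknife-nested"
    assert report.acc >= 0.9  # strongly separable planted signal


def test_overlap_planted_features_in_all_top_lists(planted_small):
    data, cfg = planted_small
    report = rs.feature_overlap(data, C=32.0, top_n=8, seed=0)
    # the directly planted dinucleotide feature survives in every top list
    for top in (report.top_full, report.top_half1, report.top_half2):
        assert "kmer:CG" in top
    assert report.n_common_kmer + report.n_common_psednc <= 8


def test_overlap_null_matches_hypergeometric_expectation():
    # pure-noise data: pairwise top-N overlap between the two halves should
    # fluctuate around N^2 / D
    d, top_n = 20, 5
    overlaps = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = rng.normal(size=(40, d))
        y = np.repeat([1, -1], 20)
        data = rs.LabeledMatrix(X, y, [f"f{i}" for i in range(d)])
        rep = rs.feature_overlap(data, C=1.0, top_n=top_n, seed=seed)
        overlaps.append(len(set(rep.top_half1) & set(rep.top_half2)))
    expected = top_n**2 / d  # 1.25
    assert abs(np.mean(overlaps) - expected) < 1.0  # Monte-Carlo tolerance
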