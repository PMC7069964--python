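"""Network construction arithmetic, training contracts, pre-training
initialization, and benchmark hyper-parameter search."""
import numpy as np
import pytest

from prognet import models as mdl
from prognet.nn import BimodalNet, FeedForward


def test_microarray_branch_parameter_count():
    # 15*40+40 + 3*(40*40+40) + 40+1 = 5601
    net = FeedForward(15, (40, 40, 40, 40), seed=0)
    assert net.parameter_count() == 5601


def test_default_bimodal_merged_width_and_size():
    spec = mdl.default_bimodal_spec(15, 7)
    assert spec.merged_width == 58
    net = mdl.build_network(spec)
    assert net.merged_width == 58
    assert net.parameter_count() < 20_000


def test_all_zero_weights_predict_half(rng):
    net = FeedForward(4, (8, 8), seed=0)
    net.set_params([np.zeros_like(p) for p in net.params])
    X = rng.normal(size=(10, 4))
    assert np.allclose(net.predict_proba(X), 0.5)


def test_build_determinism_and_seed_sensitivity(rng):
    a = FeedForward(5, (6, 6), seed=3)
    b = FeedForward(5, (6, 6), seed=3)
    c = FeedForward(5, (6, 6), seed=4)
    for pa, pb in zip(a.params, b.params):
        assert (pa == pb).all()
    assert any((pa != pc).any() for pa, pc in zip(a.params, c.params))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        mdl.BranchSpec(4, ())
    with pytest.raises(ValueError):
        mdl.BranchSpec(4, (8, 0))
    with pytest.raises(ValueError):
        mdl.TrainSpec(max_epochs=10, early_stop_patience=20)


def _separable(n=40, seed=0):
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, 2))
    y = (X[:, 0] + X[:, 1] > 0).astype(int)
    X[y == 1] += 2.0
    return X, y


def test_separable_toy_reaches_perfect_training_accuracy():
    X, y = _separable()
    tspec = mdl.TrainSpec(seed=0)
    tm = mdl.train_unimodal(mdl.BranchSpec(2, (16, 16), l2_penalty=0.0),
                            X, y, X, y, tspec)
    acc = ((mdl.predict_risk(tm, X) >= 0.5) == y).mean()
    assert acc == 1.0


def test_training_is_deterministic_for_fixed_seed():
    X, y = _separable(seed=5)
    tspec = mdl.TrainSpec(max_epochs=15, early_stop_patience=15, seed=7)
    spec = mdl.BranchSpec(2, (8, 8), seed=2)
    a = mdl.train_unimodal(spec, X, y, X, y, tspec)
    b = mdl.train_unimodal(spec, X, y, X, y, tspec)
    for pa, pb in zip(a.model.params, b.model.params):
        assert (pa == pb).all()
    assert a.history.val_loss == b.history.val_loss


def test_single_class_labels_rejected():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError):
        mdl.train_unimodal(mdl.BranchSpec(2, (4,)), X, np.zeros(10), X,
                           np.zeros(10))


def test_best_epoch_has_minimum_validation_loss():
    X, y = _separable(seed=2)
    Xv, yv = _separable(seed=3)
    tm = mdl.train_unimodal(mdl.BranchSpec(2, (8, 8)), X, y, Xv, yv,
                            mdl.TrainSpec(max_epochs=30,
                                          early_stop_patience=10, seed=1))
    assert tm.best_epoch == int(np.argmin(tm.history.val_loss))


def _pretrained_pair(seed=0):
    Xm, y = _separable(seed=seed)
    Xc, _ = _separable(seed=seed + 1)
    tspec = mdl.TrainSpec(max_epochs=5, early_stop_patience=5, seed=seed)
    micro = mdl.train_unimodal(mdl.BranchSpec(2, (6, 6), seed=1), Xm, y,
                               Xm, y, tspec, kind="micro")
    clin = mdl.train_unimodal(mdl.BranchSpec(2, (4, 4), seed=2), Xc, y,
                              Xc, y, tspec, kind="clinical")
    return micro, clin, Xm, Xc, y


def test_zero_finetune_preserves_branch_weights_exactly():
    micro, clin, Xm, Xc, y = _pretrained_pair()
    bspec = mdl.BimodalSpec(micro.spec, clin.spec, (5,), seed=9)
    tm = mdl.train_bimodal(micro, clin, Xm, Xc, y, Xm, Xc, y, bspec,
                           mdl.TrainSpec(max_epochs=0,
                                         early_stop_patience=0, seed=9))
    net = tm.model
    for (Wb, bb), (Wu, bu) in zip(net.micro, micro.model.hidden):
        assert (Wb == Wu).all() and (bb == bu).all()
    # branch representation reproduced exactly at initialization
    assert np.allclose(net._split((Xm, Xc))[0], Xm)
    from prognet.nn import _chain_forward
    assert np.array_equal(_chain_forward(net.micro, Xm),
                          micro.model.branch_activation(Xm))


def test_bimodal_input_dim_mismatch_errors():
    micro, clin, Xm, Xc, y = _pretrained_pair()
    bspec = mdl.BimodalSpec(micro.spec, clin.spec, (5,))
    tm = mdl.train_bimodal(micro, clin, Xm, Xc, y, Xm, Xc, y, bspec,
                           mdl.TrainSpec(max_epochs=0, early_stop_patience=0))
    with pytest.raises(ValueError):
        tm.model.predict_proba((Xm[:, :1], Xc))


def test_prediction_contracts(rng):
    net = FeedForward(3, (8, 8), seed=0)
    X = rng.normal(size=(20, 3))
    p = net.predict_proba(X)
    assert ((p > 0) & (p < 1)).all()
    # duplicated sample -> identical probability
    X2 = np.vstack([X, X[:1]])
    p2 = net.predict_proba(X2)
    assert p2[-1] == p[0]
    # batch vs one-at-a-time
    singles = np.array([net.predict_proba(X[i:i + 1])[0] for i in range(20)])
    assert np.allclose(singles, p, atol=1e-6)


def test_label_permuted_training_gives_chance_auc():
    """Training on permuted labels should carry no signal: mean
    validation AUC over seeds stays near 0.5."""
    from prognet.evaluation import roc_and_auc
    r = np.random.default_rng(0)
    X = r.normal(size=(80, 4))
    Xv = r.normal(size=(60, 4))
    yv = r.integers(0, 2, 60)
    while len(set(yv)) < 2:
        yv = r.integers(0, 2, 60)
    aucs = []
    for seed in range(10):
        y = r.permutation(np.repeat([0, 1], 40))
        tm = mdl.train_unimodal(mdl.BranchSpec(4, (8, 8), seed=seed), X, y,
                                Xv, yv, mdl.TrainSpec(max_epochs=20,
                                                      early_stop_patience=20,
                                                      seed=seed))
        aucs.append(roc_and_auc(mdl.predict_risk(tm, Xv), yv).auc)
    assert 0.35 <= float(np.mean(aucs)) <= 0.65


# --- benchmarks ------------------------------------------------------------

def test_rf_depth_is_third_of_input_dim():
    r = np.random.default_rng(0)
    X = r.normal(size=(60, 15))
    y = (X[:, 0] > 0).astype(int)
    tm = mdl.train_benchmark("rf", X, y, cv_folds=5, seed=0)
    assert tm.model.max_depth == 5  # ceil(15 / 3)


def test_knn_selects_small_k_on_fine_structure():
    # checkerboard: 1-NN resolves it, 30-NN (most of the data) cannot
    r = np.random.default_rng(3)
    centers = [(0, 0, 0), (0, 2, 1), (2, 0, 1), (2, 2, 0)]
    X = np.vstack([c[:2] + r.normal(0, 0.15, size=(12, 2)) for c in centers])
    y = np.repeat([c[2] for c in centers], 12)
    tm = mdl.train_benchmark("knn", X, y, cv_folds=4, seed=0)
    assert tm.model.n_neighbors <= 10


def test_benchmark_selection_deterministic():
    r = np.random.default_rng(1)
    X = r.normal(size=(80, 5))
    y = (X[:, 0] + r.normal(0, 0.5, 80) > 0).astype(int)
    a = mdl.train_benchmark("svm", X, y, cv_folds=5, seed=4)
    b = mdl.train_benchmark("svm", X, y, cv_folds=5, seed=4)
    assert a.cv_results["best_params"] == b.cv_results["best_params"]


def test_unknown_benchmark_kind():
    with pytest.raises(ValueError):
        mdl.train_benchmark("mlp", np.zeros((20, 2)),
                            np.repeat([0, 1], 10), cv_folds=2)
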