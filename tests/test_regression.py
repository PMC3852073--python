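"""SVR training, prediction, grid search and cross-validation plans."""

import numpy as np
import pandas as pd
import pytest

from mhc2sk import (
    CVPlan,
    GeneratorConfig,
    GridSpec,
    KernelParams,
    PanKernelSVR,
    StringKernelSVR,
    TrainedModel,
    generate_dataset,
    gram_matrix,
    grid_search,
    run_cv,
    train_svr,
)
from mhc2sk.evaluation import pcc
from tests.conftest import random_peptides


@pytest.fixture(scope="module")
def tiny_dataset():
    return generate_dataset(GeneratorConfig(n_alleles=3, peptides_per_allele=30, seed=17))


# ------------------------------------------------------------------ train_svr

def test_constant_targets_reproduced(small_peptides):
    gram = gram_matrix(small_peptides, "mhc2sk", KernelParams(sigma_c=2.0, l_min=3))
    model = train_svr(gram, np.full(len(small_peptides), 0.37), epsilon=0.1)
    pred = model.predict(small_peptides)
    assert np.all(np.abs(pred - 0.37) <= 0.1 + 1e-6)


def test_separable_two_item_regression():
    gram = gram_matrix(["AAAAAAAAA", "WWWWWWWWW"], "mhc2sk", KernelParams(sigma_c=1.0, l_min=1))
    model = train_svr(gram, [0.0, 1.0], epsilon=0.05)
    pred = model.predict(["AAAAAAAAA", "WWWWWWWWW"])
    assert abs(pred[0] - 0.0) <= 0.05 + 1e-6
    assert abs(pred[1] - 1.0) <= 0.05 + 1e-6


def test_train_rejects_bad_gram(small_peptides):
    gram = gram_matrix(small_peptides[:4], "mhc2sk", KernelParams(sigma_c=2.0, l_min=3))
    bad = gram.values.copy()
    bad[0, 1] = np.nan
    from mhc2sk.regression import _fit_dual

    with pytest.raises(ValueError, match="NaN"):
        _fit_dual(bad, np.zeros(4), 1.0, 0.1, 1e-3)
    with pytest.raises(ValueError, match="symmetric"):
        _fit_dual(gram.values + np.triu(np.ones_like(gram.values)), np.zeros(4), 1.0, 0.1, 1e-3)


def test_training_fit_quality_on_planted_signal(single_allele_dataset):
    """With a tuned bandwidth, the SVR must fit the planted PSSM signal
    closely on its own training data (PCC >= 0.9)."""
    ds = single_allele_dataset.dataset
    gram = gram_matrix(ds.peptides, "mhc2sk", KernelParams(sigma_c=5.0, l_min=1))
    model = train_svr(gram, ds.targets(), C=1.0, epsilon=0.1)
    pred = model.predict(ds.peptides)
    assert pcc(pred, ds.targets()) >= 0.9


# -------------------------------------------------------------------- predict

def test_predict_permutation_equivariance(small_peptides):
    gram = gram_matrix(small_peptides, "mhc2sk", KernelParams(sigma_c=2.0, l_min=3))
    rng = np.random.default_rng(0)
    model = train_svr(gram, rng.uniform(size=len(small_peptides)))
    test = small_peptides[:6]
    pred = model.predict(test)
    perm = [5, 3, 0, 1, 4, 2]
    assert np.allclose(model.predict([test[i] for i in perm]), pred[perm])


def test_rectangular_prediction_matches_joint_gram(small_peptides):
    """Predicting via the rectangular test-vs-support matrix equals reading
    the same kernel values out of a joint square Gram computation."""
    params = KernelParams(sigma_c=2.0, l_min=3)
    train, test = small_peptides[:12], small_peptides[12:]
    gram = gram_matrix(train, "mhc2sk", params)
    rng = np.random.default_rng(1)
    model = train_svr(gram, rng.uniform(size=len(train)))
    pred_rect = model.predict(test)
    joint = gram_matrix(train + test, "mhc2sk", params).values
    sup_idx = [train.index(p) for p in model.support_items]
    pred_joint = joint[np.ix_(range(len(train), len(train) + len(test)), sup_idx)] @ model.dual_coefs + model.bias
    assert np.allclose(pred_rect, pred_joint, atol=1e-8)


def test_model_round_trip_serialization(tmp_path, small_peptides):
    gram = gram_matrix(small_peptides, "mhc2sk", KernelParams(sigma_c=2.0, l_min=3))
    rng = np.random.default_rng(2)
    model = train_svr(gram, rng.uniform(size=len(small_peptides)))
    path = tmp_path / "model.json"
    model.save(path)
    loaded = TrainedModel.load(path)
    assert np.allclose(loaded.predict(small_peptides[:5]), model.predict(small_peptides[:5]))
    assert loaded.params == model.params


# ----------------------------------------------------------------- estimators

def test_string_kernel_estimator_sklearn_clone_and_fit(single_allele_dataset):
    from sklearn.base import clone

    ds = single_allele_dataset.dataset
    est = StringKernelSVR(kernel="mhc2sk", sigma_c=5.0, l_min=1)
    est2 = clone(est)
    est2.fit(ds.peptides[:80], ds.targets()[:80])
    pred = est2.predict(ds.peptides[80:120])
    assert pred.shape == (40,)
    assert est2.get_params()["sigma_c"] == 5.0
    assert hasattr(est2, "dual_coef_") and hasattr(est2, "intercept_")


def test_pan_estimator_unknown_allele_is_fatal(tiny_dataset):
    ds = tiny_dataset.dataset
    mapping = {e.allele_name: e.pseudoseq for e in tiny_dataset.pseudosequences.entries.values()}
    est = PanKernelSVR(pseudosequences=mapping, sigma_c=5.0, l_min=1, sigma_a=6.5)
    X = list(zip(ds.alleles, ds.peptides))
    est.fit(X, ds.targets())
    with pytest.raises((ValueError, KeyError), match="SYN\\*99:01"):
        est.predict([("SYN*99:01", ds.peptides[0])])


def test_normalized_estimator_predicts_consistently(single_allele_dataset):
    """Normalized models must agree between the square-Gram training path
    and the rectangular prediction path on training items."""
    ds = single_allele_dataset.dataset
    est = StringKernelSVR(kernel="mhc2sk", sigma_c=5.0, l_min=1, normalize=True)
    est.fit(ds.peptides[:60], ds.targets()[:60])
    from mhc2sk.kernels import cosine_normalize

    gram = gram_matrix(ds.peptides[:60], "mhc2sk", est._kernel_params(), normalize=True)
    sup = [ds.peptides[:60].index(p) for p in est.support_items_]
    direct = gram.values[np.ix_(range(60), sup)] @ est.dual_coef_ + est.intercept_
    assert np.allclose(est.predict(ds.peptides[:60]), direct, atol=1e-8)


# ------------------------------------------------------------------- CV plans

def test_loo_folds_are_alleles(tiny_dataset):
    ds = tiny_dataset.dataset
    plan = CVPlan(scheme="leave_one_allele_out")
    folds = plan.folds(ds)
    assert len(folds) == 3
    alleles = np.array(ds.alleles)
    for name, train, test in folds:
        assert set(alleles[test]) == {name}
        assert name not in set(alleles[train])


def test_fixed_partition_reproduces_assignment(tiny_dataset):
    ds = tiny_dataset.dataset
    assignment = {(r.allele, r.peptide): i % 4 for i, r in enumerate(ds.records)}
    plan = CVPlan(scheme="fixed_partition", fold_assignment=assignment)
    folds = plan.folds(ds)
    assert [f for f, _, _ in folds] == [0, 1, 2, 3]
    for f, _, test in folds:
        for i in test:
            r = ds.records[i]
            assert assignment[(r.allele, r.peptide)] == f


def test_kfold_partitions_every_record_once(tiny_dataset):
    ds = tiny_dataset.dataset
    folds = CVPlan(scheme="kfold_by_peptide", n_folds=5, seed=1).folds(ds)
    covered = np.concatenate([test for _, _, test in folds])
    assert sorted(covered.tolist()) == list(range(len(ds)))
    for _, train, test in folds:
        assert set(train) & set(test) == set()


def test_no_leakage_in_loo_cv(tiny_dataset):
    """In leave-one-allele-out, no training record may share the test allele."""
    sd = tiny_dataset
    table = run_cv(
        sd.dataset,
        CVPlan(scheme="leave_one_allele_out"),
        kernel_name="mhc2skpan",
        params=KernelParams(sigma_c=5.0, l_min=1, sigma_a=6.5),
        pseudoseqs=sd.pseudosequences,
    )
    assert sorted(table["fold"].unique()) == sorted(set(sd.dataset.alleles))
    for fold, g in table.groupby("fold"):
        assert set(g["allele"]) == {fold}


def test_cv_determinism(tiny_dataset):
    ds = tiny_dataset.dataset
    plan = CVPlan(scheme="kfold_by_peptide", n_folds=4, seed=7)
    t1 = run_cv(ds, plan, kernel_name="mhc2sk", params=KernelParams(sigma_c=5.0, l_min=1))
    t2 = run_cv(ds, plan, kernel_name="mhc2sk", params=KernelParams(sigma_c=5.0, l_min=1))
    pd.testing.assert_frame_equal(t1, t2)


def test_affine_target_invariance_of_pcc(tiny_dataset):
    """Scaling targets affinely and rescaling (C, epsilon) in tandem leaves
    the CV prediction ranking (PCC against targets) essentially unchanged."""
    ds = tiny_dataset.dataset
    plan = CVPlan(scheme="kfold_by_peptide", n_folds=3, seed=5)
    params = KernelParams(sigma_c=5.0, l_min=1)
    t1 = run_cv(ds, plan, kernel_name="mhc2sk", params=params, C=1.0, epsilon=0.1)
    import mhc2sk.io as mio

    scaled = mio.BindingDataset(
        records=[mio.BindingRecord(r.allele, r.peptide, v) for r, v in
                 zip(ds.records, 2.0 * ds.targets() + 1.0)],
        affinity_mode="transformed",
    )
    t2 = run_cv(scaled, plan, kernel_name="mhc2sk", params=params, C=2.0, epsilon=0.2)
    # rank agreement of the two prediction vectors on identical records
    merged = t1.merge(t2, on=["allele", "peptide"], suffixes=("_1", "_2"))
    assert pcc(merged["predicted_1"], merged["predicted_2"]) > 0.999


# ---------------------------------------------------------------- grid search

def test_grid_of_one_point_returns_it(tiny_dataset):
    ds = tiny_dataset.dataset
    grid = GridSpec(sigma_c_values=[2.0], l_min_values=[2], sigma_a_values=[6.5],
                    sigma_p_values=[1.0], L_values=[3])
    plan = CVPlan(scheme="kfold_by_peptide", n_folds=3, seed=0)
    best, table = grid_search(ds, grid, plan, kernel_name="mhc2sk")
    assert best.sigma_c == 2.0 and best.l_min == 2
    assert len(table) == 1
    assert np.isfinite(table["score"].iloc[0])


def test_grid_tie_break_first_in_lexicographic_order(tiny_dataset):
    """Duplicate grid values give identical scores: the first point wins."""
    ds = tiny_dataset.dataset
    grid = GridSpec(sigma_c_values=[2.0, 2.0], l_min_values=[2], sigma_a_values=[6.5])
    plan = CVPlan(scheme="kfold_by_peptide", n_folds=3, seed=0)
    best, table = grid_search(ds, grid, plan, kernel_name="mhc2sk")
    assert len(table) == 2
    assert table["score"].iloc[0] == table["score"].iloc[1]
    assert best.sigma_c == 2.0


def test_grid_spec_validates_ranges():
    with pytest.raises(ValueError):
        GridSpec(sigma_c_values=[6.0])
    with pytest.raises(ValueError):
        GridSpec(l_min_values=[0])
    with pytest.raises(ValueError):
        GridSpec(sigma_c_values=[])


def test_pan_grid_recovers_useful_bandwidth(pan_dataset):
    """On the pan benchmark the selected sigma_a must beat the worst grid
    point and sit near the top of an exhaustive rescoring."""
    sd = pan_dataset
    sub_idx = np.flatnonzero(np.isin(sd.dataset.alleles, sorted(set(sd.dataset.alleles))[:4]))
    ds = sd.dataset.subset(sub_idx[::2])  # 4 alleles, every other record
    grid = GridSpec(sigma_c_values=[5.0], l_min_values=[1], sigma_a_values=[0.5, 2.0, 6.5, 15.0])
    plan = CVPlan(scheme="kfold_by_peptide", n_folds=3, seed=0)
    best, table = grid_search(ds, grid, plan, kernel_name="mhc2skpan", pseudoseqs=sd.pseudosequences)
    scores = table.set_index("sigma_a")["score"]
    assert scores[best.sigma_a] == scores.max()
    assert scores[best.sigma_a] >= scores.min() + 1e-12 or scores.nunique() == 1
    assert scores.max() - scores[best.sigma_a] <= 0.05
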