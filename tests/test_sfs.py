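"""Forward SFS with ridge logistic regression, pseudo-R², McNemar."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ppaspeech.sfs import (
    SFSRidgeClassifier,
    fit_sfs_logistic,
    mcnemar_compare,
    pseudo_r2,
    run_model_grid,
)


def _binary(n1=40, n2=35):
    return np.r_[np.zeros(n1), np.ones(n2)]


def _result_like(ids, y_true, y_pred):
    """Minimal prediction container for McNemar plumbing tests."""

    class R:
        predictions = pd.DataFrame(
            {"subject_id": ids, "y_true": y_true, "y_pred": y_pred}
        )

    return R()


# -- estimator behaviour ----------------------------------------------------

def test_perfectly_separating_feature_wins():
    rng = np.random.default_rng(0)
    y = _binary()
    X = np.c_[
        np.where(y == 0, rng.normal(0, 1, len(y)), rng.normal(10, 1, len(y))),
        rng.normal(0, 1, len(y)),
    ]
    est = SFSRidgeClassifier(random_state=0).fit(X, y)
    assert est.selected_[0] == 0
    assert est.cv_accuracy_ == pytest.approx(1.0)
    assert est.pseudo_r2_ == pytest.approx(1.0, abs=1e-2)
    # estimator API round trip
    assert (est.predict(X) == y).all()
    assert est.get_params()["C"] == 1.0


def test_selection_path_deterministic_and_monotone():
    rng = np.random.default_rng(3)
    y = _binary()
    X = rng.normal(size=(len(y), 6))
    X[y == 1, 0] += 1.0
    a = SFSRidgeClassifier(random_state=7).fit(X, y)
    b = SFSRidgeClassifier(random_state=7).fit(X, y)
    assert a.selected_ == b.selected_
    np.testing.assert_array_equal(a.fold_assignment_, b.fold_assignment_)
    path = a.cv_scores_path_
    assert all(s2 >= s1 - 1e-12 for s1, s2 in zip(path, path[1:]))


def test_max_features_cap_respected():
    rng = np.random.default_rng(4)
    y = _binary()
    X = rng.normal(size=(len(y), 15))
    est = SFSRidgeClassifier(max_features=3, random_state=0).fit(X, y)
    assert len(est.selected_) <= 3


def test_constant_feature_dropped_with_warning():
    rng = np.random.default_rng(5)
    y = _binary()
    X = np.c_[np.ones(len(y)), rng.normal(size=(len(y), 2))]
    X[y == 1, 1] += 3.0
    with pytest.warns(UserWarning, match="constant"):
        est = SFSRidgeClassifier(random_state=0).fit(X, y)
    assert 0 not in est.selected_


def test_small_group_rejected():
    y = np.r_[np.zeros(5), np.ones(30)]
    X = np.random.default_rng(0).normal(size=(35, 3))
    with pytest.raises(ValueError, match="stratification"):
        SFSRidgeClassifier(cv=10).fit(X, y)


def test_agreement_with_sklearn_sequential_selector():
    """On a clean two-signal problem our forward path finds the same feature
    set as scikit-learn's SequentialFeatureSelector (independent oracle)."""
    from sklearn.feature_selection import SequentialFeatureSelector
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    rng = np.random.default_rng(11)
    y = _binary(50, 50)
    X = rng.normal(size=(100, 8))
    X[y == 1, 2] += 2.0
    X[y == 1, 5] += 2.0
    ours = SFSRidgeClassifier(max_features=2, random_state=0).fit(X, y)
    skl = SequentialFeatureSelector(
        make_pipeline(StandardScaler(), LogisticRegression(C=1.0)),
        n_features_to_select=2,
        direction="forward",
        cv=10,
    ).fit(X, y)
    assert set(ours.selected_) == set(np.where(skl.get_support())[0])


def test_informative_features_recovered_over_seeds():
    hits = 0
    n_seeds = 12
    for s in range(n_seeds):
        rng = np.random.default_rng(s)
        y = _binary()
        X = rng.normal(size=(len(y), 22))
        X[y == 1, 0] += 2.0
        X[y == 1, 1] += 2.0
        est = SFSRidgeClassifier(random_state=s).fit(X, y)
        hits += {0, 1} <= set(est.selected_)
    assert hits >= round(0.75 * n_seeds)  # acceptance run uses 50 seeds


def test_null_accuracy_unbiased():
    accs = []
    for s in range(25):
        rng = np.random.default_rng(s)
        y = _binary()
        X = rng.normal(size=(len(y), 8))
        accs.append(SFSRidgeClassifier(random_state=s).fit(X, y).cv_accuracy_)
    assert abs(np.mean(accs) - 0.5) < 0.08  # acceptance run: 200 seeds, 0.05


# -- pseudo-R² --------------------------------------------------------------

def test_pseudo_r2_intercept_only_is_zero():
    y = _binary(20, 30)
    p = np.full(50, y.mean())
    assert pseudo_r2(y, p) == pytest.approx(0.0, abs=1e-12)
    assert pseudo_r2(y, p, kind="mcfadden") == pytest.approx(0.0, abs=1e-12)


def test_pseudo_r2_perfect_prediction_is_one():
    y = _binary(10, 10)
    p = np.where(y == 1, 1 - 1e-12, 1e-12)
    assert pseudo_r2(y, p) == pytest.approx(1.0, abs=1e-9)


def test_pseudo_r2_matches_direct_likelihood_formula():
    """Nagelkerke value equals a from-scratch likelihood computation on a
    fixed synthetic fit."""
    rng = np.random.default_rng(11)
    y = np.r_[np.zeros(10), np.ones(10)]
    x = rng.normal(0, 1, 20) + y
    beta0, beta1 = -0.3, 1.2  # arbitrary fixed model
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))

    ll1 = sum(math.log(pi if yi else 1 - pi) for yi, pi in zip(y, p))
    ll0 = 20 * math.log(0.5)
    n = 20
    cs = 1 - math.exp(2 * (ll0 - ll1) / n)
    expected = cs / (1 - math.exp(2 * ll0 / n))
    assert pseudo_r2(y, p) == pytest.approx(expected, rel=1e-12)


def test_pseudo_r2_rejects_single_class():
    with pytest.raises(ValueError, match="single-class"):
        pseudo_r2(np.ones(10), np.full(10, 0.9))


# -- McNemar ----------------------------------------------------------------

def _exact_oracle(b, c):
    """Two-sided binomial tail enumeration on the discordant pairs."""
    n = b + c
    k = min(b, c)
    tail = sum(math.comb(n, i) for i in range(k + 1)) / 2**n
    return min(1.0, 2 * tail)


def test_mcnemar_identical_predictions():
    ids = np.arange(30)
    y = np.r_[np.zeros(15), np.ones(15)]
    pred = y.copy()
    pred[:3] = 1 - pred[:3]
    mc = mcnemar_compare(_result_like(ids, y, pred), _result_like(ids, y, pred))
    assert mc.only_a_correct == 0 and mc.only_b_correct == 0
    assert mc.p == pytest.approx(1.0)


def test_mcnemar_exact_example_and_symmetry():
    y = np.ones(40)
    pa, pb = y.copy(), y.copy()
    pb[:10] = 0  # A-only correct on 10
    pa[10:12] = 0  # B-only correct on 2
    mc = mcnemar_compare(
        _result_like(np.arange(40), y, pa), _result_like(np.arange(40), y, pb)
    )
    assert (mc.only_a_correct, mc.only_b_correct) == (10, 2)
    assert mc.method == "exact_binomial"
    assert mc.p == pytest.approx(_exact_oracle(10, 2), abs=1e-9)
    assert mc.p == pytest.approx(0.0386, abs=5e-4)

    pa2, pb2 = y.copy(), y.copy()
    pb2[:8] = 0
    pa2[8:16] = 0
    mc2 = mcnemar_compare(
        _result_like(np.arange(40), y, pa2), _result_like(np.arange(40), y, pb2)
    )
    assert mc2.p == pytest.approx(1.0)


def test_mcnemar_exact_matches_enumeration_all_small_tables():
    y = np.ones(60)
    for b, c in itertools.product(range(13), repeat=2):
        if b + c == 0 or b + c >= 25:
            continue
        pa, pb = y.copy(), y.copy()
        pb[:b] = 0
        pa[b:b + c] = 0
        mc = mcnemar_compare(
            _result_like(np.arange(60), y, pa), _result_like(np.arange(60), y, pb)
        )
        assert mc.method == "exact_binomial"
        assert mc.p == pytest.approx(_exact_oracle(b, c), abs=1e-9), (b, c)


def test_mcnemar_chi2_close_to_exact_for_moderate_discordance():
    y = np.ones(100)
    for b, c in [(25, 10), (20, 15), (30, 10), (22, 18)]:
        pa, pb = y.copy(), y.copy()
        pb[:b] = 0
        pa[b:b + c] = 0
        mc = mcnemar_compare(
            _result_like(np.arange(100), y, pa), _result_like(np.arange(100), y, pb)
        )
        assert mc.method == "chi2_cc"
        assert mc.p == pytest.approx(_exact_oracle(b, c), abs=0.02)


def test_mcnemar_requires_same_subjects():
    y = np.ones(10)
    a = _result_like(np.arange(10), y, y)
    b = _result_like(np.arange(5, 15), y, y)
    with pytest.raises(ValueError, match="different subjects"):
        mcnemar_compare(a, b)


# -- DataFrame wrapper & grid ----------------------------------------------

def _cohort_table(seed=0, n=30):
    rng = np.random.default_rng(seed)
    groups = ["HC", "nfvPPA", "svPPA", "lvPPA"]
    rows = []
    for gi, g in enumerate(groups):
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{g}-{i}",
                    "group": g,
                    "sex": int(rng.integers(0, 2)),
                    "age": rng.normal(70, 8),
                    "education": rng.normal(10, 4),
                    "f1": rng.normal(gi, 1.0),
                    "f2": rng.normal(0, 1.0),
                    "lang1": rng.normal(gi * 0.5, 1.0),
                    "gmv1": rng.normal(-gi * 0.5, 1.0),
                }
            )
    return pd.DataFrame(rows)


def test_fit_sfs_logistic_wrapper_outputs():
    t = _cohort_table()
    res = fit_sfs_logistic(
        t, ("HC", "svPPA"), ["f1", "f2"], folds=5, seed=0
    )
    assert res.group_pair == ("HC", "svPPA")
    assert set(res.predictions["subject_id"]) == set(
        t[t.group.isin(["HC", "svPPA"])]["subject_id"]
    )
    assert len(res.predictions) == 60
    assert 0.0 <= res.pseudo_r2 <= 1.0
    assert res.selected and set(res.selected) <= {"f1", "f2"}


def test_grid_combinatorics_and_hc_restriction():
    t = _cohort_table(seed=1)
    blocks = {
        "speech": ["f1", "f2"],
        "standard_language": ["lang1"],
        "gmv": ["gmv1"],
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        grid = run_model_grid(t, blocks, folds=5, seed=0, max_k=2)
    pairs = {k[0] for k in grid.models}
    assert len(pairs) == 6
    hc_keys = [k for k in grid.models if "HC" in k[0]]
    assert all(k[1] == ("speech",) for k in hc_keys)
    assert len(hc_keys) == 3
    patient_pairs = {k[0] for k in grid.models if "HC" not in k[0]}
    for pp in patient_pairs:
        combos = [k[1] for k in grid.models if k[0] == pp]
        assert len(combos) == 7  # 2^3 - 1 block combinations
    assert len(grid.models) == 3 + 3 * 7
    # every pseudo-R2 finite, comparisons within pairs only
    assert np.isfinite(grid.summary()["r2"]).all()
    assert len(grid.comparisons) == 3 * math.comb(7, 2)
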