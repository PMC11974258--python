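"""Cross-sectional statistics: ANCOVA, exact tests, candidate preparation."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ppaspeech import (
    ancova_group_comparison,
    fisher_exact_2xk,
    flag_outliers,
    generate_feature_cohort,
    load_default_profiles,
    select_candidates,
)


def _covars(rng, n):
    return {
        "age": rng.normal(70, 8, n),
        "sex": rng.integers(0, 2, n),
        "education": rng.normal(10, 4, n),
    }


# -- ANCOVA -----------------------------------------------------------------

def test_identical_groups_give_null_omnibus():
    rng = np.random.default_rng(0)
    block = pd.DataFrame({"y": rng.normal(0, 1, 30), **_covars(rng, 30)})
    two = pd.concat(
        [block.assign(group="A"), block.assign(group="B")], ignore_index=True
    )
    r = ancova_group_comparison(two, "y")
    assert r.omnibus_p > 0.99  # literally identical groups
    assert (r.pairwise["adj_p"] > 0.99).all()


def test_bonferroni_adjustment_monotone_and_capped():
    rng = np.random.default_rng(1)
    n = 40
    df = pd.DataFrame(
        {
            "group": np.repeat(["A", "B", "C"], n),
            "y": rng.normal(0, 1, 3 * n),
            **_covars(rng, 3 * n),
        }
    )
    r = ancova_group_comparison(df, "y")
    assert (r.pairwise["adj_p"] >= r.pairwise["raw_p"]).all()
    assert (r.pairwise["adj_p"] <= 1.0).all()
    expected = np.minimum(1.0, r.pairwise["raw_p"] * 3)
    np.testing.assert_allclose(r.pairwise["adj_p"], expected)


def test_published_wps_profiles_separate_with_high_power():
    """Simulated control vs nonfluent cohorts at the published word-rate
    profiles are detected by the adjusted pairwise contrast."""
    profiles = load_default_profiles()
    hits = 0
    n_seeds = 60
    for s in range(n_seeds):
        hc = generate_feature_cohort(profiles["HC"], 23, seed=2 * s)
        nf = generate_feature_cohort(profiles["nfvPPA"], 40, seed=2 * s + 1)
        t = pd.concat([hc, nf], ignore_index=True)
        r = ancova_group_comparison(t, "wps")
        hits += int(r.pairwise["adj_p"].iloc[0] < 0.05)
    assert hits / n_seeds >= 0.95


def test_covariate_only_signal_keeps_group_null():
    """When age alone drives the outcome, the group omnibus p stays uniform."""
    ps = []
    for s in range(500):
        rng = np.random.default_rng(s)
        n = 30
        cov = _covars(rng, 2 * n)
        y = 0.1 * cov["age"] + rng.normal(0, 1, 2 * n)
        df = pd.DataFrame(
            {"group": np.repeat(["A", "B"], n), "y": y, **cov}
        )
        ps.append(ancova_group_comparison(df, "y").omnibus_p)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_constant_covariate_reported():
    rng = np.random.default_rng(2)
    df = pd.DataFrame(
        {
            "group": np.repeat(["A", "B"], 10),
            "y": rng.normal(size=20),
            "age": 70.0,
            "sex": rng.integers(0, 2, 20),
            "education": rng.normal(10, 2, 20),
        }
    )
    with pytest.raises(ValueError, match="age"):
        ancova_group_comparison(df, "y")


# -- Fisher exact -----------------------------------------------------------

def _fisher_2x2_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    def prob(x):
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )
    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1)
        if prob(x) <= p_obs * (1 + 1e-9)
    )


def test_fisher_homogeneous_table_is_one():
    assert fisher_exact_2xk([[10, 10], [10, 10]]) == pytest.approx(1.0)


def test_fisher_diagonal_example():
    assert fisher_exact_2xk([[5, 0], [0, 5]]) == pytest.approx(2 / 252, rel=1e-9)


def test_fisher_matches_enumeration_small_margins():
    """All 2x2 tables with margins <= 10 agree with the brute-force oracle."""
    for a, b, c, d in itertools.product(range(6), repeat=4):
        if min(a + b, c + d, a + c, b + d) == 0:
            continue
        got = fisher_exact_2xk([[a, b], [c, d]])
        assert got == pytest.approx(_fisher_2x2_oracle(a, b, c, d), abs=1e-9)


def _fisher_2x3_oracle(table):
    """Independent 2x3 conditional enumeration (multivariate hypergeometric)."""
    t = np.asarray(table)
    col = t.sum(axis=0)
    r1 = t.sum(axis=1)[0]
    n = t.sum()

    def prob(x0, x1, x2):
        return (
            math.comb(col[0], x0) * math.comb(col[1], x1) * math.comb(col[2], x2)
            / math.comb(n, r1)
        )

    p_obs = prob(*t[0])
    total = 0.0
    for x0 in range(col[0] + 1):
        for x1 in range(col[1] + 1):
            x2 = r1 - x0 - x1
            if 0 <= x2 <= col[2]:
                p = prob(x0, x1, x2)
                if p <= p_obs * (1 + 1e-9):
                    total += p
    return total


def test_fisher_2x3_matches_independent_enumeration():
    for table in (
        [[4, 1, 3], [2, 6, 2]],
        [[7, 3, 1], [2, 8, 5]],
        [[1, 9, 4], [8, 2, 4]],
    ):
        assert fisher_exact_2xk(table) == pytest.approx(
            _fisher_2x3_oracle(table), abs=1e-9
        )


def test_fisher_published_sex_distribution_not_significant():
    # female/male per group at baseline: 13/10, 24/16, 20/15, 11/9
    p = fisher_exact_2xk([[13, 24, 20, 11], [10, 16, 15, 9]])
    assert p > 0.05


def test_fisher_empty_margin_rejected():
    with pytest.raises(ValueError, match="empty margin"):
        fisher_exact_2xk([[0, 5], [0, 5]])


# -- outliers ---------------------------------------------------------------

def test_single_gross_outlier_flagged():
    rng = np.random.default_rng(5)
    df = pd.DataFrame({"v": np.r_[rng.normal(0, 1, 100), [10.0]]})
    flags = flag_outliers(df, "v")
    assert flags.iloc[-1]
    assert flags.sum() <= 3  # at most a couple of chance flags


def test_constant_column_warns_without_flags():
    df = pd.DataFrame({"v": np.ones(10)})
    with pytest.warns(UserWarning, match="constant"):
        flags = flag_outliers(df, "v")
    assert not flags.any()


def test_outliers_need_five_observations():
    with pytest.raises(ValueError, match=">= 5"):
        flag_outliers(pd.DataFrame({"v": [1.0, 2.0]}), "v")


# -- candidate preparation --------------------------------------------------

def _two_group_table(seed=0, n=60):
    rng = np.random.default_rng(seed)
    inf = np.r_[rng.normal(0, 1, n), rng.normal(2, 1, n)]
    return pd.DataFrame(
        {
            "group": np.repeat(["HC", "nfvPPA"], n),
            **_covars(rng, 2 * n),
            "inf1": inf,
            "inf2": 2 * inf + rng.normal(0, 0.01, 2 * n),
            "noise": rng.normal(0, 1, 2 * n),
        }
    )


def test_select_candidates_drops_noise_and_collinear_partner():
    cs = select_candidates(_two_group_table(), ["inf1", "inf2", "noise"])
    assert cs.dropped["noise"] == "no group difference"
    assert len(cs.retained) == 1 and cs.retained[0] in ("inf1", "inf2")
    other = {"inf1", "inf2"} - set(cs.retained)
    assert "multicollinear" in cs.dropped[other.pop()]
    assert "r=1.000" in str(cs.dropped)


def test_select_candidates_permutation_invariant():
    t = _two_group_table(seed=3)
    cs1 = select_candidates(t, ["inf1", "inf2", "noise"])
    shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
    cs2 = select_candidates(shuffled, ["inf1", "inf2", "noise"])
    assert cs1.retained == cs2.retained and cs1.dropped == cs2.dropped


def test_select_candidates_null_false_positive_rate():
    """With identical group profiles, the retained fraction is near alpha."""
    kept = []
    n_vars = 6
    for s in range(40):
        rng = np.random.default_rng(s)
        n = 40
        df = pd.DataFrame(
            {
                "group": np.repeat(["HC", "nfvPPA", "svPPA"], n),
                **_covars(rng, 3 * n),
            }
        )
        for j in range(n_vars):
            df[f"v{j}"] = rng.normal(0, 1, 3 * n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cs = select_candidates(df, [f"v{j}" for j in range(n_vars)])
        kept.append(len(cs.retained) / n_vars)
    # two screens (patients-vs-HC OR among patients) at alpha=0.05 each
    assert np.mean(kept) < 0.2
    assert np.mean(kept) > 0.005


def test_correlated_pair_detected_in_controls():
    profiles = load_default_profiles()
    corr = pd.DataFrame(
        [[1.0, 0.9], [0.9, 1.0]], index=["wps", "wps_np"], columns=["wps", "wps_np"]
    )
    frames = [
        generate_feature_cohort(profiles[g], 40, seed=i, correlation=corr)
        for i, g in enumerate(["HC", "nfvPPA"])
    ]
    t = pd.concat(frames, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cs = select_candidates(t, ["wps", "wps_np"])
    dropped = set(cs.dropped)
    assert any("multicollinear" in r for r in cs.dropped.values())
    assert dropped < {"wps", "wps_np"}


def test_select_candidates_needs_controls():
    t = _two_group_table()
    with pytest.raises(ValueError, match="HC"):
        select_candidates(t[t.group != "HC"], ["inf1"])
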