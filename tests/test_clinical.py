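"""Clinical endpoint analyses: ROC with DeLong CIs, outliers, stepwise OLS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betadrop import clinical
from betadrop.panel_selection import spearman


def auc_all_pairs(pos, neg):
    """Brute-force AUC: fraction of (pos, neg) pairs won, ties half credit."""
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def series(values, prefix="T"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


# --- DeLong AUC ----------------------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_auc_matches_all_pairs_oracle_with_ties(seed):
    rng = np.random.default_rng(seed)
    # integer-valued markers force ties
    pos = rng.integers(0, 8, size=rng.integers(5, 15)).astype(float)
    neg = rng.integers(0, 8, size=rng.integers(5, 15)).astype(float)
    auc, _ = clinical.delong_auc_variance(pos, neg)
    assert auc == pytest.approx(auc_all_pairs(pos, neg), abs=1e-12)


def test_auc_invariant_to_monotone_transform():
    rng = np.random.default_rng(42)
    pos = rng.normal(1, 1, 12)
    neg = rng.normal(0, 1, 15)
    auc1, var1 = clinical.delong_auc_variance(pos, neg)
    auc2, var2 = clinical.delong_auc_variance(np.exp(pos), np.exp(neg))
    assert auc1 == pytest.approx(auc2, abs=1e-12)
    assert var1 == pytest.approx(var2, abs=1e-12)


def test_perfect_separation_auc_one_zero_variance():
    auc, var = clinical.delong_auc_variance(np.array([5.0, 6.0, 7.0]),
                                            np.array([1.0, 2.0, 3.0]))
    assert auc == 1.0
    assert var == 0.0


def test_permuted_labels_auc_near_half():
    rng = np.random.default_rng(0)
    values = rng.normal(0, 1, 400)
    aucs = []
    for _ in range(50):
        rng.shuffle(values)
        auc, _ = clinical.delong_auc_variance(values[:200], values[200:])
        aucs.append(auc)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)


def test_delong_se_close_to_bootstrap():
    rng = np.random.default_rng(3)
    pos = rng.normal(1.0, 1.0, 30)
    neg = rng.normal(0.0, 1.0, 40)
    _, var = clinical.delong_auc_variance(pos, neg)
    boots = []
    for _ in range(2000):
        bp = rng.choice(pos, size=len(pos), replace=True)
        bn = rng.choice(neg, size=len(neg), replace=True)
        boots.append(clinical.delong_auc_variance(bp, bn)[0])
    se_boot = np.std(boots, ddof=1)
    assert np.sqrt(var) == pytest.approx(se_boot, rel=0.15)


def test_delong_se_shrinks_with_sample_size():
    rng = np.random.default_rng(9)
    ses = []
    for n in (50, 500, 5000):
        pos = rng.normal(0.8, 1.0, n)
        neg = rng.normal(0.0, 1.0, n)
        _, var = clinical.delong_auc_variance(pos, neg)
        ses.append(np.sqrt(var))
    assert ses[0] > ses[1] > ses[2]
    # roughly 1/sqrt(n) scaling across a 10x step
    assert ses[0] / ses[1] == pytest.approx(np.sqrt(10), rel=0.35)


def test_roc_delong_wrapper_and_significance():
    marker = series([1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
    outcomes = series(["good"] * 3 + ["poor"] * 4)
    res = clinical.roc_delong(marker, outcomes, assay="m")
    assert res.auc == 1.0
    assert res.ci95 == (1.0, 1.0)
    assert res.significant
    assert res.n_pos == 4 and res.n_neg == 3


def test_roc_delong_requires_both_classes():
    marker = series([1.0, 2.0, 3.0])
    outcomes = series(["good"] * 3)
    with pytest.raises(ValueError, match="both outcome classes"):
        clinical.roc_delong(marker, outcomes)


def test_roc_delong_drops_missing_markers():
    marker = series([1.0, np.nan, 3.0, 10.0, 11.0])
    outcomes = series(["good", "good", "good", "poor", "poor"])
    res = clinical.roc_delong(marker, outcomes)
    assert res.n_pos == 2 and res.n_neg == 2
    assert res.auc == 1.0


# --- outlier flagging ------------------------------------------------------------

def test_tukey_flags_only_upper_spike():
    vals = series([1.0, 1.2, 0.9, 1.1, 1.0, 1.05, 10.0, -5.0])
    flags = {f.pair_id: f.flagged for f in clinical.flag_outliers(vals)}
    assert flags["T6"] is True  # the 10x surge
    assert flags["T7"] is False  # low values are never flagged (one-sided)
    assert sum(flags.values()) == 1


def test_tukey_fence_hand_value():
    vals = series([1.0, 2.0, 3.0, 4.0, 5.0])
    flags = clinical.flag_outliers(vals)
    # Q1=2, Q3=4, fence = 4 + 1.5*2 = 7
    assert flags[0].threshold == pytest.approx(7.0)
    assert not any(f.flagged for f in flags)


def test_tukey_order_invariance():
    rng = np.random.default_rng(5)
    vals = rng.normal(1, 0.2, 12)
    vals[4] = 8.0
    s1 = series(vals)
    perm = rng.permutation(12)
    s2 = s1.iloc[perm]
    f1 = {f.pair_id: f.flagged for f in clinical.flag_outliers(s1)}
    f2 = {f.pair_id: f.flagged for f in clinical.flag_outliers(s2)}
    assert f1 == f2


def test_regression_residual_flags_off_trend_point():
    rng = np.random.default_rng(7)
    cov = series(rng.uniform(1, 5, 15))
    vals = 2.0 * cov + rng.normal(0, 0.05, 15)
    vals["T3"] += 4.0  # far off the regression line
    flags = clinical.flag_outliers(vals, method="regression_residual",
                                   covariate=cov)
    flagged = {f.pair_id for f in flags if f.flagged}
    assert "T3" in flagged


def test_regression_residual_needs_covariate():
    vals = series([1.0, 2.0, 3.0, 4.0, 5.0])
    with pytest.raises(ValueError, match="covariate"):
        clinical.flag_outliers(vals, method="regression_residual")


def test_outliers_need_five_values():
    with pytest.raises(ValueError, match="at least 5"):
        clinical.flag_outliers(series([1.0, 2.0, 3.0, 4.0]))


def test_unknown_outlier_method():
    with pytest.raises(ValueError, match="unknown outlier method"):
        clinical.flag_outliers(series([1.0] * 6), method="zscore")


# --- graft correlations -----------------------------------------------------------

def test_graft_correlations_monotone_variable_significant():
    rng = np.random.default_rng(11)
    n = 12
    pair_ids = [f"T{i}" for i in range(n)]
    x = np.linspace(1, 5, n)
    rq = pd.DataFrame([x], index=["m1"], columns=pair_ids)
    graft = pd.DataFrame(
        {"cpeptide_content": x + rng.normal(0, 0.05, n),  # strongly monotone
         "beta_fraction": rng.uniform(0.2, 0.4, n)},
        index=pair_ids,
    )
    out = clinical.graft_correlations(rq, graft)
    assert out.loc["m1", "spearman_p_cpeptide_content"] < 0.01
    assert out.loc["m1", "regression_p_cpeptide_content"] < 0.01
    assert "regression_p_beta_fraction" not in out.columns


def test_graft_correlations_constant_variable_nan():
    pair_ids = [f"T{i}" for i in range(6)]
    rq = pd.DataFrame([np.arange(6.0)], index=["m1"], columns=pair_ids)
    graft = pd.DataFrame({"cpeptide_content": np.full(6, 2.0)}, index=pair_ids)
    out = clinical.graft_correlations(rq, graft)
    assert np.isnan(out.loc["m1", "spearman_p_cpeptide_content"])


def test_graft_correlations_need_five_transplants():
    pair_ids = [f"T{i}" for i in range(4)]
    rq = pd.DataFrame([np.arange(4.0)], index=["m1"], columns=pair_ids)
    graft = pd.DataFrame({"cpeptide_content": np.arange(4.0)}, index=pair_ids)
    with pytest.raises(ValueError, match="at least 5"):
        clinical.graft_correlations(rq, graft)


# --- Spearman helper ----------------------------------------------------------------

@pytest.mark.parametrize("seed", range(5))
def test_spearman_with_ties_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 5, 12).astype(float)
    y = rng.integers(0, 5, 12).astype(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        pytest.skip("degenerate draw")
    r, p = spearman(x, y)
    r_ref, p_ref = stats.spearmanr(x, y)
    assert r == pytest.approx(r_ref, abs=1e-12)
    assert p == pytest.approx(p_ref, abs=1e-12)


# --- correlogram ---------------------------------------------------------------------

def test_correlogram_symmetric_unit_diagonal():
    rng = np.random.default_rng(13)
    rq = pd.DataFrame(rng.normal(0, 1, size=(4, 8)),
                      index=[f"m{i}" for i in range(4)])
    corr = clinical.correlogram(rq)
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)


def test_correlogram_duplicated_assay_r_one():
    rng = np.random.default_rng(14)
    base = rng.normal(0, 1, 8)
    rq = pd.DataFrame([base, base, rng.normal(0, 1, 8)],
                      index=["m1", "m1_dup", "m2"])
    corr = clinical.correlogram(rq)
    assert corr.loc["m1", "m1_dup"] == pytest.approx(1.0)


def test_correlogram_needs_five_samples():
    rq = pd.DataFrame(np.ones((2, 4)))
    with pytest.raises(ValueError, match="at least 5"):
        clinical.correlogram(rq)


# --- stepwise regression --------------------------------------------------------------

def make_stepwise_data(seed=0, n=40, n_noise=4):
    rng = np.random.default_rng(seed)
    idx = [f"T{i}" for i in range(n)]
    true = rng.normal(0, 1, n)
    markers = pd.DataFrame(
        {"true_marker": true,
         **{f"noise{i}": rng.normal(0, 1, n) for i in range(n_noise)}},
        index=idx,
    )
    outcome = pd.Series(2.0 * true + rng.normal(0, 0.3, n), index=idx)
    return markers, outcome


def test_stepwise_retains_true_predictor():
    markers, outcome = make_stepwise_data()
    out = clinical.stepwise_multiple_regression(markers, outcome)
    assert "true_marker" in out["retained"]
    assert out["coefficients"]["true_marker"] == pytest.approx(2.0, abs=0.3)
    assert all(p <= 0.05 for p in out["p_values"])


def test_stepwise_drops_collinear_duplicate():
    markers, outcome = make_stepwise_data()
    markers["dup"] = 3.0 * markers["true_marker"]
    out = clinical.stepwise_multiple_regression(markers, outcome)
    assert out["dropped_collinear"] == ["dup"]
    assert "true_marker" in out["retained"]


def test_stepwise_null_predictors_usually_all_removed():
    rng = np.random.default_rng(21)
    idx = [f"T{i}" for i in range(40)]
    markers = pd.DataFrame(rng.normal(0, 1, size=(40, 3)),
                           columns=["a", "b", "c"], index=idx)
    outcome = pd.Series(rng.normal(0, 1, 40), index=idx)
    out = clinical.stepwise_multiple_regression(markers, outcome)
    # under the null each survivor needs p < 0.05; demanding an empty model
    # for this one seed is a loose check, not a statistical guarantee
    assert len(out["retained"]) <= 1
    assert len(out["eliminated"]) + len(out["retained"]) == 3


def test_stepwise_minimum_sizes():
    markers, outcome = make_stepwise_data(n=9)
    with pytest.raises(ValueError, match="at least 10"):
        clinical.stepwise_multiple_regression(markers, outcome)
    markers, outcome = make_stepwise_data(n=12, n_noise=0)
    with pytest.raises(ValueError, match="at least 2"):
        clinical.stepwise_multiple_regression(markers, outcome)


def test_stepwise_elimination_order_recorded():
    markers, outcome = make_stepwise_data(seed=2)
    out = clinical.stepwise_multiple_regression(markers, outcome)
    for name, p in out["eliminated"]:
        assert p > 0.05
        assert name.startswith("noise")
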