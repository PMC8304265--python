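"""Detection filtering, global-mean NRQ normalization and imputation."""

import numpy as np
import pandas as pd
import pytest

from betadrop import normalization as norm
from conftest import make_cq, make_nrq, make_paired_cq, make_samples


def brute_force_nrq(cq_values, efficiency=2.0):
    """Independent re-derivation: explicit loops, linear scale throughout."""
    cq = np.asarray(cq_values, dtype=float)
    n_assays, n_samples = cq.shape
    rq = np.full_like(cq, np.nan)
    for i in range(n_assays):
        detected = np.isfinite(cq[i])
        ref = cq[i][detected].mean()
        for j in range(n_samples):
            if np.isfinite(cq[i, j]):
                rq[i, j] = efficiency ** (ref - cq[i, j])
    nrq = np.full_like(cq, np.nan)
    for j in range(n_samples):
        col = rq[:, j]
        det = np.isfinite(col)
        nf = np.exp(np.mean(np.log(col[det])))
        nrq[det, j] = col[det] / nf
    return nrq


# --- detection threshold ---------------------------------------------------

def test_threshold_boundary_inclusive():
    m = make_cq([[35.0, 35.01], [30.0, 34.99]])
    out = norm.apply_detection_threshold(m)
    assert out.cq.iloc[0, 0] == 35.0  # equal to threshold: detectable
    assert np.isnan(out.cq.iloc[0, 1])
    assert out.cq.iloc[1, 1] == 34.99


def test_threshold_all_undetected_unchanged():
    m = make_cq(np.full((3, 2), np.nan))
    out = norm.apply_detection_threshold(m)
    assert out.cq.isna().all().all()


# --- group missingness filter ----------------------------------------------

def _pattern_cq(missing_pre, missing_post, n_pairs=8):
    """One assay with the given per-group missingness, plus a fully detected one."""
    row = []
    for i in range(n_pairs):
        row.append(np.nan if i < missing_pre else 28.0)
        row.append(np.nan if i < missing_post else 27.0)
    return make_paired_cq([row, [25.0] * (2 * n_pairs)], n_pairs)


def test_filter_drops_assay_missing_in_4_of_8_pre():
    m = _pattern_cq(missing_pre=4, missing_post=0)
    kept, report = norm.group_missingness_filter(m)
    assert report.reasons["a0"] == "group_missingness"
    assert report.reasons["a1"] == "kept"
    assert kept.n_assays == 1
    assert report.n_detected + int((report.reasons != "kept").sum()) == report.n_input_assays


def test_filter_keeps_assay_missing_in_3_of_8_both_groups():
    m = _pattern_cq(missing_pre=3, missing_post=3)
    kept, report = norm.group_missingness_filter(m)
    assert report.reasons["a0"] == "kept"
    assert kept.n_assays == 2


def test_filter_generalizes_to_other_group_sizes():
    # 2 of 4 missing trips the >= ceil(0.5 * 4) = 2 rule
    m = _pattern_cq(missing_pre=2, missing_post=0, n_pairs=4)
    _, report = norm.group_missingness_filter(m)
    assert report.reasons["a0"] == "group_missingness"


def test_filter_requires_group_assignment():
    m = make_cq([[28.0, 29.0]], sample_ids=["h1", "h2"],
                samples=make_samples(["h1", "h2"], phases=["healthy", "healthy"]))
    with pytest.raises(ValueError, match="group assignment"):
        norm.group_missingness_filter(m)


def test_spiking_mode_allows_single_missing():
    values = [
        [np.nan, 30.0, 28.0, 26.0],  # 1 missing: kept
        [np.nan, np.nan, 28.0, 26.0],  # 2 missing: excluded
    ]
    m = make_cq(values, sample_ids=[f"sp{i}" for i in range(4)],
                samples=make_samples([f"sp{i}" for i in range(4)],
                                     phases=["spike"] * 4, cohort="control",
                                     spike_levels=[0.0, 5.0, 50.0, 250.0]))
    kept, report = norm.spiking_missingness_filter(m)
    assert list(kept.cq.index) == ["a0"]
    assert report.reasons["a1"] == "group_missingness"


# --- global mean normalization ----------------------------------------------

def test_nrq_matches_brute_force_oracle_hand_matrix():
    values = [[28.0, 29.0], [31.0, 30.5], [26.0, np.nan]]
    m = make_cq(values)
    nrq = norm.global_mean_normalize(m)
    expected = brute_force_nrq(values)
    assert np.allclose(nrq.nrq.to_numpy(), expected, atol=1e-9, equal_nan=True)


@pytest.mark.parametrize("seed", range(5))
def test_nrq_matches_brute_force_oracle_random(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(20, 34, size=(8, 5))
    values[rng.random(values.shape) < 0.15] = np.nan
    m = make_cq(values)
    nrq = norm.global_mean_normalize(m)
    assert np.allclose(nrq.nrq.to_numpy(), brute_force_nrq(values), atol=1e-9, equal_nan=True)


def test_global_shift_invariance():
    rng = np.random.default_rng(1)
    values = rng.uniform(22, 32, size=(10, 3))
    shifted = values.copy()
    shifted[:, 0] -= 1.0  # sample s0 measured one cycle earlier across the board
    a = norm.global_mean_normalize(make_cq(values)).nrq
    b = norm.global_mean_normalize(make_cq(shifted)).nrq
    assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


def test_anchor_choice_invariance_of_sample_ratios():
    # the per-assay anchor is arbitrary: it rescales an assay's NRQ by a
    # constant, so ratios between samples within an assay are unchanged
    rng = np.random.default_rng(2)
    values = rng.uniform(22, 32, size=(7, 4))
    a = norm.global_mean_normalize(make_cq(values), anchor="mean").nrq.to_numpy()
    b = norm.global_mean_normalize(make_cq(values), anchor="min").nrq.to_numpy()
    ratios_a = a / a[:, :1]
    ratios_b = b / b[:, :1]
    assert np.allclose(ratios_a, ratios_b, atol=1e-9)


def test_anchor_choice_invariance_with_missing_complete_cases_nf():
    rng = np.random.default_rng(6)
    values = rng.uniform(22, 32, size=(7, 4))
    values[0, 1] = np.nan
    a = norm.global_mean_normalize(make_cq(values), anchor="mean",
                                   nf_policy="complete_cases").nrq.to_numpy()
    b = norm.global_mean_normalize(make_cq(values), anchor="min",
                                   nf_policy="complete_cases").nrq.to_numpy()
    ratios_a = a / a[:, -1:]
    ratios_b = b / b[:, -1:]
    assert np.allclose(ratios_a, ratios_b, atol=1e-9, equal_nan=True)


def test_geometric_mean_of_nrq_is_one_per_sample():
    rng = np.random.default_rng(3)
    values = rng.uniform(22, 32, size=(9, 4))
    values[rng.random(values.shape) < 0.1] = np.nan
    nrq = norm.global_mean_normalize(make_cq(values)).nrq
    log_gmean = np.log(nrq).mean(axis=0, skipna=True)
    assert np.allclose(log_gmean.to_numpy(), 0.0, atol=1e-9)


def test_idempotence_renormalizing_nrq_expressed_as_cq():
    rng = np.random.default_rng(4)
    values = rng.uniform(22, 32, size=(6, 4))
    nrq1 = norm.global_mean_normalize(make_cq(values)).nrq
    # re-express NRQ as pseudo-Cq (40 - log2 NRQ keeps values positive)
    pseudo_cq = 40.0 - np.log2(nrq1)
    nrq2 = norm.global_mean_normalize(make_cq(pseudo_cq.to_numpy())).nrq
    assert np.allclose(nrq1.to_numpy(), nrq2.to_numpy(), atol=1e-9)


def test_single_assay_matrix_nrq_is_one():
    nrq = norm.global_mean_normalize(make_cq([[28.0, 30.0, 26.5]]))
    assert np.allclose(nrq.nrq.to_numpy(), 1.0)


def test_error_names_sample_with_too_few_detected():
    values = [[28.0, np.nan], [29.0, np.nan], [27.0, 30.0]]
    with pytest.raises(ValueError, match="s1"):
        norm.global_mean_normalize(make_cq(values))


# --- imputation --------------------------------------------------------------

def test_imputed_value_is_min_log10_minus_one():
    values = np.array([[10 ** -0.5, 1.0, np.nan]])
    nrq = make_nrq(values)
    out = norm.impute_missing_log_nrq(nrq)
    assert np.log10(out.nrq.iloc[0, 2]) == pytest.approx(-1.5)
    assert bool(out.imputed.iloc[0, 2])
    assert not out.imputed.iloc[0, 0]


def test_imputation_noop_without_missing():
    values = np.array([[1.0, 2.0], [0.5, 0.25]])
    out = norm.impute_missing_log_nrq(make_nrq(values))
    assert np.array_equal(out.nrq.to_numpy(), values)
    assert not out.imputed.any().any()


def test_imputation_hand_example_touches_only_missing_cells():
    rng = np.random.default_rng(5)
    values = rng.uniform(0.1, 10, size=(2, 8))
    values[0, 3] = np.nan
    values[1, 6] = np.nan
    out = norm.impute_missing_log_nrq(make_nrq(values))
    for i in range(2):
        observed = values[i][np.isfinite(values[i])]
        expected = 10 ** (np.log10(observed.min()) - 1)
        j = 3 if i == 0 else 6
        assert out.nrq.iloc[i, j] == pytest.approx(expected)
        untouched = np.delete(values[i], j)
        assert np.allclose(np.delete(out.nrq.iloc[i].to_numpy(), j), untouched)


def test_imputation_rejects_all_missing_assay():
    values = np.array([[np.nan, np.nan], [1.0, 2.0]])
    with pytest.raises(ValueError, match="zero detected"):
        norm.impute_missing_log_nrq(make_nrq(values))
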