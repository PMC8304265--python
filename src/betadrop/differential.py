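"""Pre/post differential analysis of the discovery cohort.

Per assay: a two-tailed paired Student's t-test on per-pair differences of
log10(NRQ), deliberately without multiple-testing correction (each candidate
is re-tested in independent validation cohorts downstream, which is the
error control this design relies on), a group-level fold change, the
up/down selection rule (up: p < alpha and fold >= 4; down: p < alpha and
fold < 1), and hierarchical cluster ordering of the changed assays for
heatmap display (Manhattan distance, complete linkage).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_types import NrqMatrix, pairs_of

__all__ = [
    "DiffResult",
    "paired_ttest_log_nrq",
    "fold_change",
    "select_changed",
    "cluster_order",
]


@dataclasses.dataclass
class DiffResult:
    """Per-assay differential result on paired pre/post samples."""

    assay: str
    mean_fold: float  # post/pre NRQ ratio under the declared policy
    fold_mean_of_ratios: float
    direction: str  # up | down
    t_statistic: float
    p_value: float
    n_pairs: int
    imputed_count: int
    zero_variance: bool = False


def _paired_log10_diffs(nrq: NrqMatrix, pairs: pd.DataFrame, assay: str) -> np.ndarray:
    log_vals = nrq.log10_nrq.loc[assay]
    d = log_vals[pairs["post"]].to_numpy() - log_vals[pairs["pre"]].to_numpy()
    return d[np.isfinite(d)]


def paired_ttest_log_nrq(
    nrq: NrqMatrix,
    pairs: pd.DataFrame | None = None,
    fold_policy: str = "ratio_of_means",
) -> list[DiffResult]:
    """Paired t-test on log10(NRQ) plus fold change for every assay.

    ``pairs`` is a table with columns ``pre``/``post`` naming the sample ids
    of each transplant (derived from the sample annotations if omitted).
    All-zero differences yield p = 1 with a zero-variance flag.
    """
    if pairs is None:
        pairs = pairs_of(nrq.samples)
    folds = fold_change(nrq, pairs)
    results = []
    for assay in nrq.nrq.index:
        d = _paired_log10_diffs(nrq, pairs, assay)
        if len(d) < 2:
            raise ValueError(f"assay {assay!r}: fewer than 2 complete pairs")
        if np.allclose(d, 0.0):
            t, p, zero_var = 0.0, 1.0, True
        else:
            t, p = stats.ttest_rel(
                nrq.log10_nrq.loc[assay, pairs["post"]].to_numpy(),
                nrq.log10_nrq.loc[assay, pairs["pre"]].to_numpy(),
                nan_policy="omit",
            )
            zero_var = False
            if np.isnan(p):  # identical constant differences, nonzero
                t, p, zero_var = 0.0, 1.0, True
        rom, mor = folds.loc[assay, "ratio_of_means"], folds.loc[assay, "mean_of_ratios"]
        fold = rom if fold_policy == "ratio_of_means" else mor
        imputed = int(nrq.imputed.loc[assay, list(pairs["pre"]) + list(pairs["post"])].sum())
        results.append(
            DiffResult(
                assay=assay,
                mean_fold=float(fold),
                fold_mean_of_ratios=float(mor),
                direction="up" if fold >= 1 else "down",
                t_statistic=float(t),
                p_value=float(p),
                n_pairs=int(len(d)),
                imputed_count=imputed,
                zero_variance=zero_var,
            )
        )
    return results


def fold_change(nrq: NrqMatrix, pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Group-level post/pre fold change per assay under both policies.

    ``ratio_of_means``: mean post-NRQ / mean pre-NRQ (default downstream).
    ``mean_of_ratios``: mean of per-pair post/pre ratios.
    Imputation (if wanted) must already be applied; NRQ is positive so the
    denominators never vanish.
    """
    if pairs is None:
        pairs = pairs_of(nrq.samples)
    pre = nrq.nrq[pairs["pre"]].to_numpy(dtype=float)
    post = nrq.nrq[pairs["post"]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ratio_of_means = np.nanmean(post, axis=1) / np.nanmean(pre, axis=1)
        mean_of_ratios = np.nanmean(post / pre, axis=1)
    return pd.DataFrame(
        {"ratio_of_means": ratio_of_means, "mean_of_ratios": mean_of_ratios},
        index=nrq.nrq.index,
    )


def select_changed(
    results: list[DiffResult],
    fold_threshold: float = 4.0,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Split significant assays into the up set (fold >= threshold) and down set.

    The fold threshold applies to the up direction only; the down set is any
    significant assay with fold < 1.  Significant assays with 1 <= fold <
    threshold belong to neither set (they count toward "significantly
    different" but are not candidates).
    """
    up = [r.assay for r in results if r.p_value < alpha and r.mean_fold >= fold_threshold]
    down = [r.assay for r in results if r.p_value < alpha and r.mean_fold < 1.0]
    return up, down


def cluster_order(
    log10_nrq: pd.DataFrame,
    linkage_method: str = "complete",
    metric: str = "cityblock",
) -> dict:
    """Hierarchical cluster ordering of assays and samples for heatmap display.

    Manhattan (cityblock) distance with complete linkage by default (Ward.D2
    over Euclidean distance available via ``linkage_method='ward'``).  Rows
    are z-scored for display; constant rows (z-score undefined) are flagged
    and left unscaled.  Ties are broken deterministically by input order
    (scipy's linkage is deterministic given the input ordering).
    """
    if log10_nrq.shape[0] < 2:
        raise ValueError("clustering needs at least 2 assays")
    values = log10_nrq.to_numpy(dtype=float)
    row_sd = values.std(axis=1, ddof=0)
    constant_rows = [log10_nrq.index[i] for i in np.flatnonzero(row_sd == 0)]
    z = values.copy()
    ok = row_sd > 0
    z[ok] = (values[ok] - values[ok].mean(axis=1, keepdims=True)) / row_sd[ok, None]

    if linkage_method == "ward":
        row_link = hierarchy.linkage(values, method="ward", metric="euclidean")
        col_link = hierarchy.linkage(values.T, method="ward", metric="euclidean")
    else:
        row_link = hierarchy.linkage(pdist(values, metric=metric), method=linkage_method)
        col_link = hierarchy.linkage(pdist(values.T, metric=metric), method=linkage_method)

    row_order = hierarchy.leaves_list(row_link)
    col_order = hierarchy.leaves_list(col_link)
    return {
        "row_order": [log10_nrq.index[i] for i in row_order],
        "col_order": [log10_nrq.columns[i] for i in col_order],
        "row_linkage": row_link,
        "col_linkage": col_link,
        "z_scores": pd.DataFrame(z, index=log10_nrq.index, columns=log10_nrq.columns),
        "constant_rows": constant_rows,
    }
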