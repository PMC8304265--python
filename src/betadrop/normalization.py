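"""Detection filtering, global-mean normalization and imputation.

Raw Cq values above the detection threshold (35 cycles by default) are
treated as categorical non-detection.  Assays missing in at least half of
either the pre-transplant or the post-transplant group are excluded; in
spiking mode at most one missing value per assay is tolerated.

Normalization follows the global-mean strategy: each sample's normalization
factor is the geometric mean of the relative quantities of all assays
detected in that sample, so per-sample technical shifts (input amount,
extraction efficiency) cancel.  Per assay i and sample j,

    RQ_ij  = E^(Cqref_i − Cq_ij),   Cqref_i = mean detected Cq of assay i
    NF_j   = geometric mean over detected i of RQ_ij
    NRQ_ij = RQ_ij / NF_j

with amplification efficiency E = 2 by default.  The per-assay anchor
Cqref_i is arbitrary: NRQ ratios between samples are invariant to it.

For group-level fold computation, missing values of an assay are imputed as
the assay's minimum observed log10(NRQ) across the cohort minus 1.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

from .io_types import CqMatrix, NrqMatrix

__all__ = [
    "FilterReport",
    "apply_detection_threshold",
    "group_missingness_filter",
    "spiking_missingness_filter",
    "global_mean_normalize",
    "impute_missing_log_nrq",
]

DETECTION_THRESHOLD = 35.0


@dataclasses.dataclass
class FilterReport:
    """Per-assay ledger of the detection-confidence filter."""

    n_input_assays: int
    n_detected: int
    reasons: pd.Series  # assay_id -> {kept | group_missingness | cq_above_threshold_all}
    thresholds: dict

    def __post_init__(self) -> None:
        excluded = int((self.reasons != "kept").sum())
        if self.n_detected + excluded != self.n_input_assays:
            raise ValueError("filter report does not account for every input assay")


def apply_detection_threshold(cq: CqMatrix, threshold: float = DETECTION_THRESHOLD) -> CqMatrix:
    """Censor every Cq strictly above ``threshold`` (values equal are kept)."""
    if threshold <= 0:
        raise ValueError("detection threshold must be positive")
    censored = cq.cq.where(cq.cq <= threshold)
    return CqMatrix(cq=censored, assays=cq.assays, samples=cq.samples, discordant=cq.discordant)


def _missing_threshold(group_size: int, max_missing: int, stated_group_size: int) -> int:
    # generalize "4 of 8" to other group sizes as ceil(fraction * size)
    frac = max_missing / stated_group_size
    return math.ceil(frac * group_size)


def group_missingness_filter(
    cq: CqMatrix,
    max_missing: int = 4,
    stated_group_size: int = 8,
) -> tuple[CqMatrix, FilterReport]:
    """Drop assays undetected in at least half of the pre OR the post group.

    The rule is stated as "at least 4 of 8" for eight transplant pairs and is
    generalized to other group sizes as a fraction (>= ceil(0.5 * size)).
    Every sample must carry a pre_tx/post_tx phase annotation.
    """
    phases = cq.samples["phase"]
    unknown = cq.samples.index[~phases.isin(["pre_tx", "post_tx"])]
    if len(unknown):
        raise ValueError(f"samples without pre/post group assignment: {list(unknown)}")
    pre = cq.samples.index[phases == "pre_tx"]
    post = cq.samples.index[phases == "post_tx"]
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("both pre_tx and post_tx groups must be nonempty")

    missing_pre = cq.cq[pre].isna().sum(axis=1)
    missing_post = cq.cq[post].isna().sum(axis=1)
    thr_pre = _missing_threshold(len(pre), max_missing, stated_group_size)
    thr_post = _missing_threshold(len(post), max_missing, stated_group_size)

    all_missing = cq.cq.isna().all(axis=1)
    dropped = (missing_pre >= thr_pre) | (missing_post >= thr_post)
    reasons = pd.Series("kept", index=cq.cq.index, name="reason")
    reasons[dropped] = "group_missingness"
    reasons[all_missing] = "cq_above_threshold_all"

    kept = cq.subset_assays(reasons.index[reasons == "kept"])
    report = FilterReport(
        n_input_assays=cq.n_assays,
        n_detected=kept.n_assays,
        reasons=reasons,
        thresholds={
            "max_missing": max_missing,
            "stated_group_size": stated_group_size,
            "pre_group_size": int(len(pre)),
            "post_group_size": int(len(post)),
            "pre_missing_threshold": thr_pre,
            "post_missing_threshold": thr_post,
        },
    )
    return kept, report


def spiking_missingness_filter(cq: CqMatrix, max_missing: int = 1) -> tuple[CqMatrix, FilterReport]:
    """Spiking-series mode: allow at most one missing value per assay."""
    missing = cq.cq.isna().sum(axis=1)
    all_missing = cq.cq.isna().all(axis=1)
    reasons = pd.Series("kept", index=cq.cq.index, name="reason")
    reasons[missing > max_missing] = "group_missingness"
    reasons[all_missing] = "cq_above_threshold_all"
    kept = cq.subset_assays(reasons.index[reasons == "kept"])
    report = FilterReport(
        n_input_assays=cq.n_assays,
        n_detected=kept.n_assays,
        reasons=reasons,
        thresholds={"max_missing_per_assay": max_missing},
    )
    return kept, report


def global_mean_normalize(
    cq: CqMatrix,
    efficiency: float = 2.0,
    nf_policy: str = "per_sample_detected",
    anchor: str = "mean",
) -> NrqMatrix:
    """Global-mean normalization of a detection-filtered Cq matrix.

    ``nf_policy`` controls which assays enter a sample's normalization
    factor: ``per_sample_detected`` (all assays detected in that sample,
    default) or ``complete_cases`` (only assays detected in every sample).
    ``anchor`` picks the per-assay reference Cq used to linearize
    (``mean`` detected Cq or ``min``); downstream ratios are invariant to it.
    """
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("amplification efficiency must lie in (1, 2]")
    if nf_policy not in ("per_sample_detected", "complete_cases"):
        raise ValueError(f"unknown nf_policy {nf_policy!r}")

    values = cq.cq
    detected = values.notna()
    n_detected = detected.sum(axis=0)
    # a sample must contribute >= 2 detected assays to a meaningful global
    # mean; a single-assay matrix is a degenerate-but-defined case (NF = RQ,
    # hence NRQ = 1 everywhere)
    min_required = min(2, cq.n_assays)
    too_few = n_detected[n_detected < min_required]
    if len(too_few):
        raise ValueError(
            f"samples with fewer than {min_required} detected assays: {list(too_few.index)}"
        )

    if anchor == "mean":
        cq_ref = values.mean(axis=1)
    elif anchor == "min":
        cq_ref = values.min(axis=1)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")

    log2e = np.log2(efficiency)
    # work in log2 units: log2 RQ = log2(E) * (Cqref - Cq)
    log_rq = values.rsub(cq_ref, axis=0) * log2e

    if nf_policy == "complete_cases":
        nf_rows = detected.all(axis=1)
        if not nf_rows.any():
            raise ValueError("no complete-case assays available for the normalization factor")
        log_nf = log_rq.loc[nf_rows].mean(axis=0)
    else:
        log_nf = log_rq.mean(axis=0, skipna=True)

    log_nrq = log_rq.sub(log_nf, axis=1)
    nrq = np.exp2(log_nrq)
    return NrqMatrix(nrq=nrq, assays=cq.assays, samples=cq.samples)


def impute_missing_log_nrq(nrq: NrqMatrix) -> NrqMatrix:
    """Replace missing values by each assay's minimum log10(NRQ) minus 1.

    The imputed matrix is meant for group-level fold computation only;
    imputed cells are flagged.  An assay with no detected value at all must
    have been removed by the missingness filter and raises an error here.
    """
    values = nrq.nrq.copy()
    missing = values.isna()
    empty = missing.all(axis=1)
    if empty.any():
        raise ValueError(
            f"assays with zero detected values reached imputation: {list(values.index[empty])}"
        )
    if not missing.any().any():
        return NrqMatrix(nrq=values, assays=nrq.assays, samples=nrq.samples,
                         imputed=missing)
    fill = 10.0 ** (np.log10(values.min(axis=1)) - 1.0)
    for assay in values.index[missing.any(axis=1)]:
        values.loc[assay] = values.loc[assay].fillna(fill[assay])
    return NrqMatrix(nrq=values, assays=nrq.assays, samples=nrq.samples, imputed=missing)
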