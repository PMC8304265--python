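"""Reference-free relative quantification (RQ) for validation and clinical cohorts.

When no stable reference microRNAs are available — the degradation path this
pipeline expects — targeted PCR data are expressed as plain relative
quantities assuming doubling per cycle:

* paired mode (validation cohorts): RQ = 2^(Ct_pre − Ct_post) per
  transplant, so RQ > 1 means a post-transplant increase;
* cross-sample mode (clinical cohort): for assay i and sample X,
  RQ_X = 2^(mean Ct_i across samples − Ct_{i,X}), which makes the geometric
  mean of RQ across included samples exactly 1.

Group significance is a two-tailed paired t-test on the per-pair ΔCt.
Half-detected pairs (pre undetected, post detected — the biologically
expected surge) impute the missing pre Ct at the detection threshold,
yielding a conservative lower-bound RQ flagged as censored; fully undetected
pairs are excluded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import CqMatrix, pairs_of
from .normalization import DETECTION_THRESHOLD

__all__ = ["RqResult", "rq_paired", "rq_cross_sample", "cohort_significance"]


@dataclasses.dataclass
class RqResult:
    """Per-assay RQ summary within one cohort."""

    assay: str
    cohort: str
    per_pair_rq: pd.Series  # pair_id -> RQ (NaN where undefined)
    censored: pd.Series  # pair_id -> True where pre Ct was imputed at threshold
    group_rq: float  # arithmetic mean of per-pair RQ (policy switchable)
    p_value: float
    n_pairs: int
    zero_variance: bool = False
    validated: bool = False


def rq_paired(ct_pre: float, ct_post: float) -> float:
    """Fold change 2^(Ct_pre − Ct_post) for one transplant pair."""
    return float(2.0 ** (ct_pre - ct_post))


def _pair_delta_ct(
    cq: CqMatrix,
    assay: str,
    pairs: pd.DataFrame,
    detection_threshold: float,
) -> tuple[pd.Series, pd.Series]:
    """Per-pair ΔCt = Ct_pre − Ct_post with the censoring policy applied."""
    pre = cq.cq.loc[assay, pairs["pre"]].to_numpy(dtype=float)
    post = cq.cq.loc[assay, pairs["post"]].to_numpy(dtype=float)
    delta = np.full(len(pairs), np.nan)
    censored = np.zeros(len(pairs), dtype=bool)
    for i, (a, b) in enumerate(zip(pre, post)):
        pre_ok, post_ok = np.isfinite(a), np.isfinite(b)
        if pre_ok and post_ok:
            delta[i] = a - b
        elif post_ok and not pre_ok:
            delta[i] = detection_threshold - b  # lower-bound surge
            censored[i] = True
        elif pre_ok and not post_ok:
            delta[i] = a - detection_threshold  # lower-bound decrease
            censored[i] = True
        # both undetected: undefined, stays NaN
    idx = pairs.index
    return pd.Series(delta, index=idx), pd.Series(censored, index=idx)


def rq_cross_sample(cq: CqMatrix, detection_threshold: float = DETECTION_THRESHOLD) -> pd.DataFrame:
    """Per-sample RQ per assay, anchored at the assay's cross-cohort mean Ct.

    Undetected samples get no RQ (NaN).  An assay detected in a single
    sample trivially gets RQ = 1 there and is flagged in the attrs.
    """
    values = cq.cq
    mean_ct = values.mean(axis=1)
    # rsub: mean_ct - Ct_x per cell
    rq = np.exp2(values.rsub(mean_ct, axis=0))
    single = values.notna().sum(axis=1) == 1
    rq.attrs["single_sample_assays"] = list(values.index[single])
    return rq


def cohort_significance(
    cq: CqMatrix,
    cohort: str,
    alpha: float = 0.05,
    detection_threshold: float = DETECTION_THRESHOLD,
    group_policy: str = "arithmetic",
) -> list[RqResult]:
    """Paired RQ and significance per assay for one validation cohort.

    ``group_policy`` chooses the group-level average of per-pair RQ:
    ``arithmetic`` (default; fold distributions here are heavy-tailed and the
    arithmetic mean preserves the large surges) or ``geometric``.
    """
    if group_policy not in ("arithmetic", "geometric"):
        raise ValueError(f"unknown group_policy {group_policy!r}")
    samples = cq.samples[cq.samples["cohort"] == cohort]
    pairs = pairs_of(samples)
    results = []
    for assay in cq.cq.index:
        delta, censored = _pair_delta_ct(cq, assay, pairs, detection_threshold)
        defined = delta.dropna()
        rq = np.exp2(delta)
        if len(defined) < 2:
            results.append(
                RqResult(
                    assay=assay, cohort=cohort, per_pair_rq=rq, censored=censored,
                    group_rq=float("nan"), p_value=float("nan"),
                    n_pairs=int(len(defined)),
                )
            )
            continue
        d = defined.to_numpy()
        if np.allclose(d - d[0], 0.0):
            # no within-pair variance (incl. all-zero): t undefined, report p = 1
            t, p, zero_var = 0.0, 1.0, True
        else:
            t, p = stats.ttest_rel(d, np.zeros_like(d))
            zero_var = False
        if group_policy == "arithmetic":
            group_rq = float(rq.dropna().mean())
        else:
            group_rq = float(np.exp2(defined.mean()))
        results.append(
            RqResult(
                assay=assay, cohort=cohort, per_pair_rq=rq, censored=censored,
                group_rq=group_rq, p_value=float(p), n_pairs=int(len(defined)),
                zero_variance=zero_var, validated=bool(p < alpha),
            )
        )
    return results


def rq_table(results: list[RqResult]) -> pd.DataFrame:
    """Per-assay, per-cohort summary table (group RQ, p, validation verdict)."""
    rows = [
        {
            "assay": r.assay,
            "cohort": r.cohort,
            "group_rq": r.group_rq,
            "p_value": r.p_value,
            "n_pairs": r.n_pairs,
            "validated": r.validated,
            "zero_variance": r.zero_variance,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index(["assay", "cohort"])


def unblind(samples: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Replace blinded sample codes by real ids at report stage.

    ``mapping`` has columns ``code`` and ``sample_id``; cohorts are coded
    independently, so codes must be unique within the mapping supplied.
    """
    if mapping["code"].duplicated().any():
        raise ValueError("blinding codes must be unique within a cohort mapping")
    lookup = dict(zip(mapping["code"], mapping["sample_id"]))
    out = samples.rename(index=lookup)
    return out
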