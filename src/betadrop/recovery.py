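"""Spike-in recovery scoring: does an assay respond linearly to beta-cell lysate?

Human beta-cell lysate is spiked into control plasma at 0, 5, 50 and
250 thousand cells/mL ("K cells/mL").  A genuinely graft-derived microRNA
should amplify earlier (lower Cq) the more lysate is present.  An assay
passes when all of the following hold:

* slope of Cq versus log10(K cells/mL) over the positive levels < -1.5
  (perfect doubling per cycle gives -log2(10) = -3.32),
* R^2 of that fit > 0.9,
* at least 4 of 6 monotonicity criteria: Cq(0)>Cq(5), Cq(5)>Cq(50),
  Cq(50)>Cq(250) and NRQ(0)<NRQ(5), NRQ(5)<NRQ(50), NRQ(50)<NRQ(250),
* the Cq values progressively decline across spiked levels, with a drop of
  at least 1 cycle between subsequent spiked levels (5->50 and 50->250).

The unspiked (0) level enters only the monotonicity criteria, since
log10(0) is undefined; non-detection at the 0 level counts in the assay's
favour there (absence in unspiked plasma is ideal biomarker behaviour).
At most one missing value is tolerated per assay across the series.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_types import CqMatrix, NrqMatrix

__all__ = ["RecoveryVerdict", "score_recovery", "recovery_panel"]

SLOPE_THRESHOLD = -1.5
R2_THRESHOLD = 0.9
MIN_CRITERIA = 4
MIN_DELTA_CQ = 1.0


@dataclasses.dataclass
class RecoveryVerdict:
    """Per-assay linearity verdict against the spiking dilution series."""

    assay: str
    slope: float  # Cq per log10(K cells/mL), over positive levels
    r_squared: float
    criteria_met: tuple  # 6 booleans, Cq then NRQ ordering as in the module docstring
    delta_cq_ok: bool
    progressive_decline: bool
    passed: bool
    reason: str = ""

    @property
    def n_criteria_met(self) -> int:
        return int(sum(self.criteria_met))


def _isnum(v: float) -> bool:
    return v is not None and math.isfinite(v)


def _fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on x (>= 2 points)."""
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def score_recovery(
    cq_series: Mapping[float, float],
    nrq_series: Mapping[float, float],
    levels: Sequence[float] = (0.0, 5.0, 50.0, 250.0),
    assay: str = "",
) -> RecoveryVerdict:
    """Score one assay's Cq/NRQ response to the spiking series.

    ``cq_series`` and ``nrq_series`` map spike level (K cells/mL) to the
    measured value, NaN marking non-detection.  The verdict is invariant to
    the ordering of ``levels`` and to a common rescaling of all levels
    (which shifts only the fit's intercept).
    """
    levels = sorted(levels)
    positive = [lv for lv in levels if lv > 0]
    if len(positive) < 3:
        raise ValueError("need at least 3 positive spike levels")

    cq = {lv: float(cq_series.get(lv, np.nan)) for lv in levels}
    nrq = {lv: float(nrq_series.get(lv, np.nan)) for lv in levels}

    n_missing = sum(not _isnum(cq[lv]) for lv in levels)
    if sum(not _isnum(cq[lv]) for lv in positive) > 1 or n_missing > 1:
        return RecoveryVerdict(
            assay=assay, slope=float("nan"), r_squared=float("nan"),
            criteria_met=(False,) * 6, delta_cq_ok=False,
            progressive_decline=False, passed=False, reason="insufficient data",
        )

    obs = [(lv, cq[lv]) for lv in positive if _isnum(cq[lv])]
    x = np.log10([lv for lv, _ in obs])
    y = np.array([v for _, v in obs])
    slope, r2 = _fit(x, y)

    # six monotonicity criteria over consecutive levels (incl. the 0 level)
    steps = list(zip(levels[:-1], levels[1:]))
    cq_crit = []
    for lo, hi in steps:
        if lo == 0 and not _isnum(cq[lo]):
            cq_crit.append(True)  # undetected in unspiked plasma: ideal
        elif _isnum(cq[lo]) and _isnum(cq[hi]):
            cq_crit.append(cq[lo] > cq[hi])
        else:
            cq_crit.append(False)
    nrq_crit = []
    for lo, hi in steps:
        if lo == 0 and not _isnum(nrq[lo]) and _isnum(nrq[hi]):
            nrq_crit.append(True)
        elif _isnum(nrq[lo]) and _isnum(nrq[hi]):
            nrq_crit.append(nrq[lo] < nrq[hi])
        else:
            nrq_crit.append(False)
    criteria = tuple(cq_crit + nrq_crit)

    # delta-Cq rule over the spiked steps only (5->50, 50->250)
    spiked_steps = [(lo, hi) for lo, hi in zip(positive[:-1], positive[1:])]
    deltas = [
        cq[lo] - cq[hi] if _isnum(cq[lo]) and _isnum(cq[hi]) else float("nan")
        for lo, hi in spiked_steps
    ]
    delta_cq_ok = all(_isnum(d) and d >= MIN_DELTA_CQ for d in deltas)
    progressive = all(_isnum(d) and d > 0 for d in deltas)

    passed = (
        slope < SLOPE_THRESHOLD
        and r2 > R2_THRESHOLD
        and sum(criteria) >= MIN_CRITERIA
        and delta_cq_ok
        and progressive
    )
    return RecoveryVerdict(
        assay=assay, slope=slope, r_squared=r2, criteria_met=criteria,
        delta_cq_ok=delta_cq_ok, progressive_decline=progressive, passed=passed,
    )


def recovery_panel(
    cq: CqMatrix,
    nrq: NrqMatrix,
    levels: Sequence[float] = (0.0, 5.0, 50.0, 250.0),
) -> tuple[list[str], dict[str, RecoveryVerdict]]:
    """Score every assay of a spiking-series matrix; return passers + verdicts.

    Samples must carry ``spike_level`` annotations; replicate samples at one
    level are averaged (Cq arithmetically, NRQ geometrically).
    """
    sample_levels = cq.samples["spike_level"].astype(float)
    if sample_levels.isna().any():
        raise ValueError("every spiking-series sample needs a spike_level annotation")

    def per_level(df: pd.DataFrame, geometric: bool) -> pd.DataFrame:
        out = {}
        for lv in levels:
            cols = sample_levels.index[sample_levels == lv]
            block = df[list(cols)]
            if geometric:
                out[lv] = np.exp2(np.log2(block).mean(axis=1))
            else:
                out[lv] = block.mean(axis=1)
        return pd.DataFrame(out)

    cq_by_level = per_level(cq.cq, geometric=False)
    nrq_by_level = per_level(nrq.nrq.reindex(cq.cq.index), geometric=True)

    verdicts = {
        assay: score_recovery(
            cq_by_level.loc[assay].to_dict(),
            nrq_by_level.loc[assay].to_dict(),
            levels=levels,
            assay=assay,
        )
        for assay in cq.cq.index
    }
    passing = [a for a, v in verdicts.items() if v.passed]
    return passing, verdicts


def verdicts_table(verdicts: Mapping[str, RecoveryVerdict]) -> pd.DataFrame:
    """Flatten verdicts into a per-assay results table."""
    rows = []
    for v in verdicts.values():
        rows.append(
            {
                "assay": v.assay,
                "slope": v.slope,
                "r_squared": v.r_squared,
                "n_criteria_met": v.n_criteria_met,
                "delta_cq_ok": v.delta_cq_ok,
                "progressive_decline": v.progressive_decline,
                "passed": v.passed,
                "reason": v.reason,
            }
        )
    return pd.DataFrame(rows).set_index("assay")
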