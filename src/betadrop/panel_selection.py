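"""Candidate-panel prioritization: from the up-regulated set to the validation panel.

An up-regulated assay makes the panel when it shows a significant Spearman
correlation with an anchor biomarker of beta-cell lysis (plasma GAD65 or
calibrated molar miR-375) and/or passed the beta-cell-lysate recovery
experiment, and is not significantly correlated with an exclusion marker
(the duct-cell microRNA miR-197-3p by default — correlation with it flags
provenance from contaminating duct cells rather than beta cells).

The original selection was partly expert judgment; that judgment is confined
to an explicit, logged override list so the rule-determined panel stays
reproducible (audit mode: drop the overrides and the panel is strictly
rule-derived).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PanelDecision", "spearman", "anchor_correlations", "build_panel", "panel_table"]


@dataclasses.dataclass
class PanelDecision:
    """Per-assay ledger of the selection evidence and the verdict."""

    assay: str
    in_up_set: bool
    fold: float
    spearman_vs_gad65: tuple  # (r, p)
    spearman_vs_mir375: tuple  # (r, p)
    recovery_passed: bool
    excluded_by: str  # "duct_marker_correlation" | "none"
    manual_override: str  # "include" | "exclude" | "none"
    override_reason: str
    included: bool
    rank: int = -1


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and a two-tailed p.

    Pairs with a missing value are dropped.  The p-value uses the usual t
    approximation; ``exact=True`` switches to an exact permutation test
    (sensible for n <= 9).  A constant vector has no defined rank
    correlation and returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("Spearman correlation needs at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    if exact:
        res = stats.permutation_test(
            (x,),
            lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=np.inf,
        )
        r = float(stats.spearmanr(x, y).statistic)
        return r, float(res.pvalue)
    r, p = stats.spearmanr(x, y)
    return float(r), float(p)


def anchor_correlations(
    marker_values: pd.DataFrame,
    anchors: pd.DataFrame,
    anchor_cols: Sequence[str] = ("gad65", "mir375_molar"),
) -> pd.DataFrame:
    """Spearman r and p of each assay (rows) against each anchor column.

    ``marker_values``: assays × samples (e.g. post-transplant NRQ);
    ``anchors``: samples × anchor concentrations, indexed like the columns.
    """
    anchors = anchors.loc[list(marker_values.columns)]
    out = {}
    for col in anchor_cols:
        rs, ps = [], []
        for assay in marker_values.index:
            r, p = spearman(marker_values.loc[assay], anchors[col])
            rs.append(r)
            ps.append(p)
        out[f"r_{col}"] = rs
        out[f"p_{col}"] = ps
    return pd.DataFrame(out, index=marker_values.index)


def build_panel(
    diff_results: Sequence,
    up_set: Sequence[str],
    anchor_corr: pd.DataFrame,
    recovery_passing: Sequence[str],
    exclusion_corr: pd.DataFrame | None = None,
    alpha: float = 0.05,
    manual_overrides: Mapping[str, Mapping[str, str]] | None = None,
) -> list[PanelDecision]:
    """Evaluate the inclusion rules for every differential result.

    ``exclusion_corr``: per-assay Spearman p against each exclusion marker
    (columns ``p_<marker>``); a significant correlation (p < alpha) excludes
    the assay.  ``manual_overrides`` maps assay id to
    ``{"action": "include"|"exclude", "reason": str}``; a reason is
    mandatory.  Inclusion requires membership in the up set plus a
    significant positive anchor correlation or recovery passage (or an
    include override), and no
    exclusion flag.  Ranking: recovery passers first, then by best anchor r,
    then fold, descending.
    """
    overrides = dict(manual_overrides or {})
    known = {r.assay for r in diff_results}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"manual override references unknown assay(s): {sorted(unknown)}")
    for assay, ov in overrides.items():
        if ov.get("action") not in ("include", "exclude"):
            raise ValueError(f"override for {assay!r} needs action include/exclude")
        if not ov.get("reason"):
            raise ValueError(f"override for {assay!r} needs a reason")

    up = set(up_set)
    rec = set(recovery_passing)
    decisions = []
    for r in diff_results:
        a = r.assay
        r_g, p_g = (
            (float(anchor_corr.loc[a, "r_gad65"]), float(anchor_corr.loc[a, "p_gad65"]))
            if a in anchor_corr.index and "r_gad65" in anchor_corr
            else (float("nan"), float("nan"))
        )
        r_m, p_m = (
            (float(anchor_corr.loc[a, "r_mir375_molar"]), float(anchor_corr.loc[a, "p_mir375_molar"]))
            if a in anchor_corr.index and "r_mir375_molar" in anchor_corr
            else (float("nan"), float("nan"))
        )
        # the anchors rise with beta-cell lysis, so only a positive
        # correlation is evidence of graft provenance
        anchor_ok = (np.isfinite(p_g) and p_g < alpha and r_g > 0) or (
            np.isfinite(p_m) and p_m < alpha and r_m > 0
        )

        excluded_by = "none"
        if exclusion_corr is not None and a in exclusion_corr.index:
            pcols = [c for c in exclusion_corr.columns if c.startswith("p_")]
            ps = exclusion_corr.loc[a, pcols].astype(float)
            if (ps < alpha).any():
                excluded_by = "duct_marker_correlation"

        ov = overrides.get(a, {})
        action = ov.get("action", "none")
        reason = ov.get("reason", "")

        rule_included = a in up and (anchor_ok or a in rec) and excluded_by == "none"
        if action == "include":
            included = a in up and excluded_by == "none"
        elif action == "exclude":
            included = False
        else:
            included = rule_included

        decisions.append(
            PanelDecision(
                assay=a,
                in_up_set=a in up,
                fold=float(r.mean_fold),
                spearman_vs_gad65=(r_g, p_g),
                spearman_vs_mir375=(r_m, p_m),
                recovery_passed=a in rec,
                excluded_by=excluded_by,
                manual_override=action,
                override_reason=reason,
                included=included,
            )
        )

    def sort_key(d: PanelDecision):
        best_r = np.nanmax(
            [d.spearman_vs_gad65[0], d.spearman_vs_mir375[0], -np.inf]
        )
        if not np.isfinite(best_r):
            best_r = -np.inf
        return (not d.included, not d.recovery_passed, -best_r, -d.fold, d.assay)

    decisions.sort(key=sort_key)
    for i, d in enumerate(decisions, start=1):
        d.rank = i
    return decisions


def panel_table(decisions: Sequence[PanelDecision]) -> pd.DataFrame:
    """Flatten PanelDecisions into the results-ledger table."""
    rows = []
    for d in decisions:
        rows.append(
            {
                "assay": d.assay,
                "rank": d.rank,
                "included": d.included,
                "in_up_set": d.in_up_set,
                "fold": d.fold,
                "r_gad65": d.spearman_vs_gad65[0],
                "p_gad65": d.spearman_vs_gad65[1],
                "r_mir375": d.spearman_vs_mir375[0],
                "p_mir375": d.spearman_vs_mir375[1],
                "recovery_passed": d.recovery_passed,
                "excluded_by": d.excluded_by,
                "manual_override": d.manual_override,
                "override_reason": d.override_reason,
            }
        )
    return pd.DataFrame(rows).set_index("assay")
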