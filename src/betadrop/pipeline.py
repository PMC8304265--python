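"""End-to-end orchestration of the discovery stage.

Chains detection filtering, global-mean normalization, imputation,
differential testing, anchor correlations, spike-in recovery scoring and
panel selection, so callers (tests, the CLI, analysis scripts) can run the
whole discovery arm with one call and inspect every intermediate.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from . import differential, normalization, panel_selection, recovery
from .io_types import CqMatrix, NrqMatrix, pairs_of
from .normalization import FilterReport

__all__ = ["DiscoveryResult", "run_discovery"]


@dataclasses.dataclass
class DiscoveryResult:
    """All intermediates of the discovery arm."""

    filter_report: FilterReport
    nrq: NrqMatrix
    nrq_imputed: NrqMatrix
    diff_results: list
    up_set: list
    down_set: list
    anchor_corr: pd.DataFrame | None
    recovery_passing: list
    recovery_verdicts: dict
    panel: list  # PanelDecision, ranked


def run_discovery(
    cq: CqMatrix,
    anchors: pd.DataFrame | None = None,
    spiking_cq: CqMatrix | None = None,
    exclusion_markers: tuple = (),
    detection_threshold: float = 35.0,
    fold_threshold: float = 4.0,
    alpha: float = 0.05,
    fold_policy: str = "ratio_of_means",
    manual_overrides: dict | None = None,
) -> DiscoveryResult:
    """Run the complete discovery arm on a paired pre/post cohort.

    ``anchors``: per-sample GAD65 / molar miR-375 concentrations (optional —
    without them the anchor-correlation criterion never fires and panel
    membership rests on recovery alone).  ``spiking_cq``: the spiking-series
    matrix for recovery scoring.  ``exclusion_markers``: assay ids whose
    correlated assays are dropped (duct-cell provenance).
    """
    detected = normalization.apply_detection_threshold(cq, detection_threshold)
    filtered, report = normalization.group_missingness_filter(detected)
    nrq = normalization.global_mean_normalize(filtered)
    nrq_imp = normalization.impute_missing_log_nrq(nrq)

    pairs = pairs_of(cq.samples)
    diff_results = differential.paired_ttest_log_nrq(nrq_imp, pairs, fold_policy=fold_policy)
    up_set, down_set = differential.select_changed(
        diff_results, fold_threshold=fold_threshold, alpha=alpha
    )

    anchor_corr = pd.DataFrame(index=nrq_imp.nrq.index)
    if anchors is not None:
        post_samples = list(pairs["post"])
        anchor_corr = panel_selection.anchor_correlations(
            nrq_imp.nrq[post_samples], anchors
        )

    recovery_passing: list = []
    verdicts: dict = {}
    if spiking_cq is not None:
        spike_detected = normalization.apply_detection_threshold(spiking_cq, detection_threshold)
        spike_filtered, _ = normalization.spiking_missingness_filter(spike_detected)
        spike_nrq = normalization.global_mean_normalize(spike_filtered)
        recovery_passing, verdicts = recovery.recovery_panel(spike_filtered, spike_nrq)

    exclusion_corr = None
    if exclusion_markers:
        post_samples = list(pairs["post"])
        post = nrq_imp.nrq[post_samples]
        cols = {}
        for marker in exclusion_markers:
            rs, ps = [], []
            for assay in post.index:
                if assay == marker:
                    rs.append(float("nan"))
                    ps.append(float("nan"))
                    continue
                r, p = panel_selection.spearman(post.loc[assay], post.loc[marker])
                rs.append(r)
                ps.append(p)
            cols[f"r_{marker}"] = rs
            cols[f"p_{marker}"] = ps
        exclusion_corr = pd.DataFrame(cols, index=post.index)

    panel = panel_selection.build_panel(
        diff_results,
        up_set,
        anchor_corr,
        recovery_passing,
        exclusion_corr=exclusion_corr,
        alpha=alpha,
        manual_overrides=manual_overrides,
    )
    return DiscoveryResult(
        filter_report=report,
        nrq=nrq,
        nrq_imputed=nrq_imp,
        diff_results=diff_results,
        up_set=up_set,
        down_set=down_set,
        anchor_corr=anchor_corr,
        recovery_passing=recovery_passing,
        recovery_verdicts=verdicts,
        panel=panel,
    )
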