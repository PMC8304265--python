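"""Clinical validation of the biomarker panel against graft outcome.

Post-transplant marker levels are related to (i) the cellular composition of
the infused graft (Spearman correlations and univariable linear regression),
(ii) excessive-destruction outliers (one-sided Tukey fences on the marker
distribution, or externally studentized residuals of the marker-vs-graft
regression), and (iii) the dichotomized 2-month secretory outcome: ROC
analysis with DeLong confidence intervals, a Spearman correlogram of panel
redundancy, and backward stepwise multiple regression to find independent
predictors.

The AUC here is the probability that a randomly chosen poor-outcome patient
shows a higher marker level than a randomly chosen good-outcome patient
(ties get half credit); its standard error follows DeLong's structural
components, so no distributional assumption is made about the marker.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .panel_selection import spearman

__all__ = [
    "RocResult",
    "OutlierFlag",
    "graft_correlations",
    "flag_outliers",
    "roc_delong",
    "correlogram",
    "stepwise_multiple_regression",
]


@dataclasses.dataclass
class RocResult:
    """AUC with DeLong standard error and normal-approximation 95% CI."""

    assay: str
    auc: float
    se_delong: float
    ci95: tuple
    n_pos: int
    n_neg: int
    direction: str = "higher marker => poor outcome"

    @property
    def significant(self) -> bool:
        """Diagnostic power: the 95% CI excludes the chance AUC of 0.5."""
        lo, hi = self.ci95
        return lo > 0.5 or hi < 0.5


@dataclasses.dataclass
class OutlierFlag:
    pair_id: str
    assay: str
    method: str  # distribution_tukey | regression_residual
    threshold: float
    flagged: bool


def graft_correlations(
    rq: pd.DataFrame,
    graft: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    regression_vars: Sequence[str] = ("cpeptide_content",),
) -> pd.DataFrame:
    """Spearman p per (assay, graft variable), plus univariable regression p.

    ``rq``: assays × transplants (columns = pair ids); ``graft``: transplants
    × composition variables.  For variables in ``regression_vars`` (and the
    C-peptide increment when ``outcomes`` is given) an ordinary
    least-squares p for the marker coefficient is reported as well.
    Constant variables are flagged undefined (NaN).
    """
    if rq.shape[1] < 5:
        raise ValueError("graft correlation analysis needs at least 5 transplants")
    graft = graft.loc[list(rq.columns)]
    rows = []
    targets = dict(graft.items())
    if outcomes is not None:
        targets["cpeptide_increment_2mo"] = outcomes.loc[
            list(rq.columns), "cpeptide_increment_2mo"
        ]
    for assay in rq.index:
        x = rq.loc[assay].to_numpy(dtype=float)
        row: dict[str, float | str] = {"assay": assay}
        for var, values in targets.items():
            y = np.asarray(values, dtype=float)
            if np.all(y == y[0]) or np.all(x == x[0]):
                row[f"spearman_p_{var}"] = np.nan
                continue
            _, p = spearman(x, y)
            row[f"spearman_p_{var}"] = p
            if var in regression_vars or var == "cpeptide_increment_2mo":
                model = sm.OLS(y, sm.add_constant(x)).fit()
                row[f"regression_p_{var}"] = float(model.pvalues[1])
        rows.append(row)
    return pd.DataFrame(rows).set_index("assay")


def flag_outliers(
    values: pd.Series,
    method: str = "distribution_tukey",
    k: float = 1.5,
    covariate: pd.Series | None = None,
    assay: str = "",
    residual_cutoff: float = 2.0,
) -> list[OutlierFlag]:
    """Flag disproportionately elevated marker values.

    ``distribution_tukey``: one-sided upper fence Q3 + k*IQR — only surges
    are of interest (they indicate excessive destruction).
    ``regression_residual``: externally studentized residuals beyond
    ``residual_cutoff`` from the regression of the marker on ``covariate``
    (typically graft C-peptide content, the proxy for infused beta-cell mass).
    """
    values = values.dropna()
    if len(values) < 5:
        raise ValueError("outlier flagging needs at least 5 values")
    if method == "distribution_tukey":
        q1, q3 = np.percentile(values, [25, 75])
        fence = q3 + k * (q3 - q1)
        return [
            OutlierFlag(pair_id=str(i), assay=assay, method=method,
                        threshold=float(fence), flagged=bool(v > fence))
            for i, v in values.items()
        ]
    if method == "regression_residual":
        if covariate is None:
            raise ValueError("regression_residual mode needs a covariate")
        cov = covariate.loc[values.index].astype(float)
        model = sm.OLS(values.to_numpy(), sm.add_constant(cov.to_numpy())).fit()
        resid = OLSInfluence(model).resid_studentized_external
        return [
            OutlierFlag(pair_id=str(i), assay=assay, method=method,
                        threshold=residual_cutoff, flagged=bool(abs(r) > residual_cutoff))
            for i, r in zip(values.index, resid)
        ]
    raise ValueError(f"unknown outlier method {method!r}")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative marker values.

    Structural components: for each positive the fraction of negatives it
    exceeds (ties half), and vice versa; the variance combines the two
    empirical component variances, var = S10/m + S01/n.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = _midrank(allv)
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    # V10_i = (rank of pos_i among all - rank among positives) / n
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_delong(marker: pd.Series, outcomes: pd.Series, assay: str = "",
               positive_label: str = "poor") -> RocResult:
    """ROC AUC of a marker for the dichotomized outcome, with DeLong 95% CI.

    ``positive_label`` names the event class (higher marker expected); the
    CI is AUC ± 1.96·SE truncated to [0, 1].
    """
    aligned = pd.concat([marker, outcomes], axis=1, keys=["x", "y"]).dropna()
    pos = aligned.loc[aligned["y"] == positive_label, "x"].to_numpy(dtype=float)
    neg = aligned.loc[aligned["y"] != positive_label, "x"].to_numpy(dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("ROC analysis needs both outcome classes present")
    auc, var = delong_auc_variance(pos, neg)
    se = float(np.sqrt(var))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return RocResult(assay=assay, auc=auc, se_delong=se, ci95=(lo, hi),
                     n_pos=len(pos), n_neg=len(neg))


def correlogram(rq: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman matrix of the panel (symmetric, unit diagonal)."""
    if rq.shape[1] < 5:
        raise ValueError("correlogram needs at least 5 samples")
    assays = list(rq.index)
    out = pd.DataFrame(np.eye(len(assays)), index=assays, columns=assays)
    for i, a in enumerate(assays):
        for b in assays[i + 1:]:
            r, _ = spearman(rq.loc[a], rq.loc[b])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def plot_correlogram(corr: pd.DataFrame, path=None):
    """Convenience blue→red rendering of the correlogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(corr),) * 2)
    im = ax.imshow(corr.to_numpy(), cmap="coolwarm", vmin=-1, vmax=1)
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="Spearman r")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def stepwise_multiple_regression(
    markers: pd.DataFrame,
    outcome: pd.Series,
    p_remove: float = 0.05,
) -> dict:
    """Backward-elimination OLS of the outcome on candidate markers.

    Starts from the full model and repeatedly drops the predictor with the
    largest p-value above ``p_remove`` until all remaining predictors are
    significant (possibly none).  Perfectly collinear predictors are resolved
    by dropping the later-ranked (later-column) ones up front.  Returns the
    retained set, their coefficients and p-values, the elimination order, and
    the fitted final model.

    ``markers``: samples × predictors; ``outcome``: continuous response
    (C-peptide increment) or a 0/1 encoding of the dichotomous outcome — the
    same linear framework handles both.
    """
    if len(markers) < 10:
        raise ValueError("stepwise regression needs at least 10 observations")
    if markers.shape[1] < 2:
        raise ValueError("stepwise regression needs at least 2 candidate predictors")
    y = np.asarray(outcome.loc[markers.index], dtype=float)

    predictors = list(markers.columns)
    dropped_collinear = []
    X = markers.to_numpy(dtype=float)
    # greedy rank check: drop later columns that add no rank
    keep_idx: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep_idx + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), trial])) == len(keep_idx) + 2:
            keep_idx.append(j)
        else:
            dropped_collinear.append(predictors[j])
    predictors = [predictors[j] for j in keep_idx]

    eliminated = []
    while predictors:
        design = sm.add_constant(markers[predictors].to_numpy(dtype=float))
        fit = sm.OLS(y, design).fit()
        pvals = pd.Series(fit.pvalues[1:], index=predictors)
        worst = pvals.idxmax()
        if pvals[worst] > p_remove:
            eliminated.append((worst, float(pvals[worst])))
            predictors.remove(worst)
        else:
            break

    if predictors:
        design = sm.add_constant(markers[predictors].to_numpy(dtype=float))
        final = sm.OLS(y, design).fit()
        coefs = pd.Series(final.params[1:], index=predictors)
        pvals = pd.Series(final.pvalues[1:], index=predictors)
    else:
        final = sm.OLS(y, np.ones((len(y), 1))).fit()
        coefs = pd.Series(dtype=float)
        pvals = pd.Series(dtype=float)
    return {
        "retained": predictors,
        "coefficients": coefs,
        "p_values": pvals,
        "eliminated": eliminated,
        "dropped_collinear": dropped_collinear,
        "model": final,
    }
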