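"""Reference-microRNA selection: SD prefilter, geNorm M ranking and V analysis.

Candidate normalizers are microRNAs whose normalized level barely varies
across samples and that are detected almost everywhere (at least 15 of 16
discovery-cohort samples).  The shortlist is ranked by the geNorm stability
measure M: for genes j and k, V_jk is the standard deviation across samples
of log2(a_j/a_k), and M_j is the mean of V_jk over all k != j.  Lower M =
more stable.  Canonical geNorm iteratively drops the least stable gene and
recomputes M until two remain.

The optimal number of references follows geNorm's pairwise-variation
analysis: NF_n(sample) is the geometric mean of the n best genes, and
V(n, n+1) is the SD across samples of log2(NF_n / NF_{n+1}); the smallest n
with V(n, n+1) below 0.15 suffices.  If no n qualifies, all candidates are
retained with a no-stable-set flag — the degradation path the pipeline must
support, since reference assays can fail outright in later cohorts,
restricting analysis to plain RQ values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_types import NrqMatrix

__all__ = ["GeNormResult", "sd_prefilter", "genorm_m", "genorm_rank", "genorm_v"]

V_CUTOFF = 0.15


@dataclasses.dataclass
class GeNormResult:
    """Stability ranking and pairwise-variation analysis of candidate references."""

    m_values: pd.Series  # final single-pass M per assay, on the full candidate set
    ranked: list[str]  # ascending stability rank (most stable first)
    v_curve: pd.Series  # index n (2..N-1), value V(n, n+1)
    n_selected: int
    selected: list[str]
    no_stable_set: bool = False


def sd_prefilter(
    nrq: NrqMatrix,
    min_detected: int = 15,
    of_samples: int = 16,
    top_k: int = 15,
) -> list[str]:
    """Shortlist stably expressed assays by ascending NRQ standard deviation.

    Only assays detected in at least ``min_detected`` of ``of_samples``
    (generalized as a fraction of the actual sample count) are eligible.
    Returns up to ``top_k`` assay ids, ties broken by assay id.
    """
    frac = min_detected / of_samples
    need = int(np.ceil(frac * nrq.nrq.shape[1]))
    detected_counts = nrq.nrq.notna().sum(axis=1)
    eligible = nrq.nrq.index[detected_counts >= need]
    sds = nrq.nrq.loc[eligible].std(axis=1, ddof=1)
    ranked = sorted(eligible, key=lambda a: (sds[a], a))
    return ranked[:top_k]


def _log2_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    complete = expr.dropna(axis=1)
    if complete.shape[1] < 2:
        raise ValueError("geNorm needs at least 2 complete-case samples")
    if (complete.to_numpy() <= 0).any():
        raise ValueError("geNorm expression values must be positive")
    return np.log2(complete)


def genorm_m(expr: pd.DataFrame) -> pd.Series:
    """geNorm M per assay on a linear-scale candidates × samples matrix.

    Uses complete-case samples only (pairwise log-ratios are undefined with
    missing values).  Requires at least 3 candidates.
    """
    if expr.shape[0] < 3:
        raise ValueError("geNorm M requires at least 3 candidate assays")
    log2a = _log2_matrix(expr).to_numpy()
    n = log2a.shape[0]
    m = np.empty(n)
    for j in range(n):
        ratios = log2a[j] - log2a  # broadcasting: row k = log2(a_j / a_k) per sample
        sds = ratios.std(axis=1, ddof=1)
        m[j] = np.delete(sds, j).mean()
    return pd.Series(m, index=expr.index, name="M")


def genorm_rank(expr: pd.DataFrame, iterative: bool = True) -> tuple[list[str], pd.Series]:
    """Rank candidates by ascending stability.

    ``iterative`` (canonical geNorm) repeatedly removes the assay with the
    highest M and recomputes; the two survivors share the top and are
    ordered by their final M, ties by assay id.  Single-pass mode ranks by
    one M computation.  Returns (ranking most-stable-first, single-pass M).
    """
    m_all = genorm_m(expr)
    if not iterative:
        return list(m_all.sort_values(kind="stable").index), m_all

    remaining = list(expr.index)
    eliminated: list[str] = []
    while len(remaining) > 2:
        m = genorm_m(expr.loc[remaining])
        worst = max(remaining, key=lambda a: (m[a], a))
        eliminated.append(worst)
        remaining.remove(worst)
    # order the final pair by pairwise SD context: use single-pass M, tie-break by id
    final_pair = sorted(remaining, key=lambda a: (m_all[a], a))
    return final_pair + eliminated[::-1], m_all


def genorm_v(
    ranked: list[str],
    expr: pd.DataFrame,
    cutoff: float = V_CUTOFF,
) -> GeNormResult:
    """Pairwise-variation analysis over increasingly large reference sets."""
    log2a = _log2_matrix(expr.loc[ranked])
    n_total = len(ranked)
    v_values = {}
    for n in range(2, n_total):
        nf_n = log2a.iloc[:n].mean(axis=0)  # log2 of geometric mean
        nf_n1 = log2a.iloc[: n + 1].mean(axis=0)
        v_values[n] = float((nf_n - nf_n1).std(ddof=1))
    v_curve = pd.Series(v_values, name="V")

    below = [n for n, v in v_values.items() if v < cutoff]
    if below:
        n_selected = min(below)
        no_stable = False
    else:
        n_selected = n_total
        no_stable = True
    return GeNormResult(
        m_values=genorm_m(expr.loc[ranked]),
        ranked=list(ranked),
        v_curve=v_curve,
        n_selected=n_selected,
        selected=list(ranked[:n_selected]),
        no_stable_set=no_stable,
    )
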