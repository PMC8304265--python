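"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the study design end to end so every stage is
testable without the original raw data:

* a transplant cohort of paired pre/post plasma samples profiled on a
  733-assay card, of which ~220 assays are reliably detectable; a small
  planted set of graft-derived microRNAs surges post-transplant in
  proportion to a latent per-patient "destroyed beta-cell mass" signal,
  while anchor measurements (GAD65, molar miR-375) track the same signal;
* optionally, planted confounder assays that surge with a second latent
  duct-cell signal shared with a designated duct-marker assay (these should
  be caught by the panel-selection exclusion rule);
* a 4-level beta-cell-lysate spiking series (0/5/50/250 K cells/mL) where
  planted assays amplify earlier the more lysate is present and background
  assays stay flat;
* a clinical cohort in which the post-transplant marker level rises with
  the destruction signal while the 2-month C-peptide increment falls with
  it (and rises with implanted beta-cell mass), giving a dichotomized
  graft outcome the clinical stage must predict.

Noise model: additive Gaussian on the Cq scale (the standard qPCR error
model) plus a per-sample random intercept emulating input-amount and
extraction shifts — exactly the nuisance global-mean normalization must
remove.  Latent signals are lognormal across patients: plasma biomarker
surges span orders of magnitude.  All randomness flows through one
``numpy.random.default_rng(seed)`` (PCG64), so identical config + seed give
identical outputs across runs and platforms.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_types import CqMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_transplant_cohort",
    "gen_spiking_series",
    "gen_clinical_cohort",
]

#: Names of the validated core-panel markers used in the clinical cohort.
CORE_PANEL = (
    "miR-375",
    "miR-132-3p",
    "miR-204-5p",
    "miR-410-3p",
    "miR-200a-3p",
    "miR-429",
    "miR-125b-5p",
    "miR-216b-5p",
)


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults reproduce the study's structure: 8 transplant pairs on a
    733-assay card with ~220 detectable assays, 20 planted graft-derived
    markers surging at least 4-fold, Cq noise of 0.25 cycles, doubling
    amplification, detection ceiling at 35 cycles.
    """

    n_patients: int = 8
    n_assays: int = 733
    n_detectable: int = 220
    n_planted: int = 20
    n_confounders: int = 0
    #: per-cell abundance weight of planted markers: post/pre fold is
    #: weight × latent destruction signal (lognormal, median 1); the range
    #: emulates the observed heavy-tailed post-transplant surge spectrum
    planted_weight_range: tuple = (32.0, 2048.0)
    confounder_weight_range: tuple = (32.0, 2048.0)
    #: lognormal latent destroyed-cell signal, parameters in log10 units
    release_log10_mu: float = 0.0
    release_log10_sd: float = 0.35
    baseline_cq_mean: float = 28.0
    baseline_cq_sd: float = 2.0
    planted_baseline_cq: float = 31.0
    undetectable_cq_mean: float = 38.0
    undetectable_cq_sd: float = 1.5
    noise_sd: float = 0.25  # cycles, per well (technical)
    #: per-assay biological fluctuation of circulating levels between draws
    biological_sd: float = 1.0  # cycles
    sample_shift_sd: float = 0.5  # cycles, per-sample random intercept
    detection_ceiling: float = 35.0
    instrument_ceiling: float = 40.0
    pcr_efficiency: float = 2.0
    #: anchor assays: multiplicative lognormal noise (log10 SD) around the
    #: destruction signal; pre-transplant baseline near the assay LoD
    anchor_noise_log10_sd: float = 0.08
    gad65_scale: float = 10.0  # pmol/L per unit destruction signal
    mir375_scale: float = 6.0
    # clinical-cohort outcome model
    clinical_n: int = 46
    beta_mass_mean: float = 2.9  # 1e6 insulin-positive cells/kg BW
    beta_mass_sd: float = 0.5
    outcome_intercept: float = 0.9  # ng/mL
    outcome_mass_coef: float = 0.25  # ng/mL per 1e6 beta cells/kg
    outcome_destruction_coef: float = 0.62  # ng/mL per log10 destruction unit
    outcome_noise_sd: float = 0.35  # ng/mL
    outlier_fraction: float = 0.15
    outlier_boost_log10: float = 0.8
    marker_signal_weights: Mapping[str, float] | None = None
    clinical_marker_noise_sd: float = 0.5  # cycles on post-transplant Cq
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_detectable <= self.n_assays:
            raise ValueError("need 0 < n_detectable <= n_assays")
        if self.noise_sd < 0 or self.sample_shift_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 1.0 < self.pcr_efficiency <= 2.0:
            raise ValueError("PCR efficiency must lie in (1, 2]")
        if self.n_planted + self.n_confounders + 1 > self.n_detectable:
            raise ValueError("planted sets exceed the detectable assay count")


@dataclasses.dataclass
class SimTruth:
    """Ground truth recorded for every generated cohort."""

    destroyed_signal: pd.Series  # per patient
    duct_signal: pd.Series | None
    planted_markers: dict  # assay_id -> abundance weight
    confounders: dict
    duct_marker: str | None
    true_folds: pd.DataFrame  # assay × patient post/pre fold (planted rows only)
    outcome_coefficients: dict


def _assay_frame(ids: Sequence[str], roles: Mapping[str, str] | None = None) -> pd.DataFrame:
    roles = roles or {}
    return pd.DataFrame(
        {
            "mirna_name": list(ids),
            "role": [roles.get(a, "candidate") for a in ids],
        },
        index=pd.Index(ids, name="assay_id"),
    )


def _baselines(config: SimConfig, rng: np.random.Generator) -> tuple[list, np.ndarray]:
    """Assay ids and baseline Cq values; detectable assays first."""
    ids = [f"mir-{i:04d}" for i in range(1, config.n_assays + 1)]
    base = np.empty(config.n_assays)
    nd = config.n_detectable
    base[:nd] = np.clip(
        rng.normal(config.baseline_cq_mean, config.baseline_cq_sd, nd),
        20.0,
        config.detection_ceiling - 2.0,
    )
    base[nd:] = rng.normal(
        config.undetectable_cq_mean, config.undetectable_cq_sd, config.n_assays - nd
    )
    return ids, base


def _censor(cq: np.ndarray, config: SimConfig) -> np.ndarray:
    out = cq.copy()
    out[out > config.detection_ceiling] = np.nan
    return out


def gen_transplant_cohort(
    config: SimConfig,
    planted_markers: Mapping[str, float] | None = None,
    cohort: str = "discovery",
) -> tuple[CqMatrix, pd.DataFrame, SimTruth]:
    """Paired pre/post transplant cohort with planted graft-derived markers.

    Returns the Cq matrix (samples annotated with pairing), per-sample anchor
    measurements (GAD65 and molar miR-375 tracking the same latent
    destruction signal), and the ground truth.  ``planted_markers`` may
    override the assay→weight mapping; ids must exist on the card.
    """
    rng = np.random.default_rng(config.seed)
    ids, base = _baselines(config, rng)
    log2e = np.log2(config.pcr_efficiency)

    if planted_markers is not None:
        unknown = set(planted_markers) - set(ids)
        if unknown:
            raise ValueError(f"planted assay(s) not on the card: {sorted(unknown)}")
        planted = dict(planted_markers)
    else:
        lo, hi = config.planted_weight_range
        weights = np.exp2(rng.uniform(np.log2(lo), np.log2(hi), config.n_planted))
        planted = dict(zip(ids[: config.n_planted], weights))
    # planted markers: consistently low but detectable pre-transplant baseline
    for a in planted:
        base[ids.index(a)] = config.planted_baseline_cq + rng.normal(0.0, 0.5)

    confounders: dict[str, float] = {}
    duct_marker = None
    duct_signal = None
    if config.n_confounders > 0:
        start = config.n_planted
        lo, hi = config.confounder_weight_range
        cw = np.exp2(rng.uniform(np.log2(lo), np.log2(hi), config.n_confounders))
        confounders = dict(zip(ids[start : start + config.n_confounders], cw))
        duct_marker = ids[start + config.n_confounders]
        for a in list(confounders) + [duct_marker]:
            base[ids.index(a)] = config.planted_baseline_cq + rng.normal(0.0, 0.5)

    n = config.n_patients
    patients = [f"P{i:02d}" for i in range(1, n + 1)]
    s = 10.0 ** rng.normal(config.release_log10_mu, config.release_log10_sd, n)
    destroyed = pd.Series(s, index=patients, name="destroyed_signal")
    if duct_marker is not None:
        d = 10.0 ** rng.normal(config.release_log10_mu, config.release_log10_sd, n)
        duct_signal = pd.Series(d, index=patients, name="duct_signal")

    sample_ids = [f"{p}_{ph}" for p in patients for ph in ("pre", "post")]
    shifts = rng.normal(0.0, config.sample_shift_sd, len(sample_ids))

    cq = np.empty((config.n_assays, len(sample_ids)))
    fold_rows = {}
    for j, sid in enumerate(sample_ids):
        patient = sid.rsplit("_", 1)[0]
        is_post = sid.endswith("post")
        col = base + shifts[j]
        if is_post:
            for a, w in planted.items():
                fold = w * destroyed[patient]
                col[ids.index(a)] -= np.log2(fold) / log2e
            for a, w in confounders.items():
                fold = w * duct_signal[patient]
                col[ids.index(a)] -= np.log2(fold) / log2e
            if duct_marker is not None:
                col[ids.index(duct_marker)] -= np.log2(64.0 * duct_signal[patient]) / log2e
        if config.biological_sd > 0:
            col = col + rng.normal(0.0, config.biological_sd, config.n_assays)
        if config.noise_sd > 0:
            col = col + rng.normal(0.0, config.noise_sd, config.n_assays)
        cq[:, j] = col
    for a, w in planted.items():
        fold_rows[a] = w * destroyed
    true_folds = pd.DataFrame(fold_rows).T if fold_rows else pd.DataFrame()

    cq = _censor(cq, config)

    samples = pd.DataFrame(
        {
            "cohort": cohort,
            "patient_id": [sid.rsplit("_", 1)[0] for sid in sample_ids],
            "phase": ["pre_tx" if sid.endswith("pre") else "post_tx" for sid in sample_ids],
            "pair_id": [sid.rsplit("_", 1)[0] for sid in sample_ids],
            "spike_level": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # anchors: pre-transplant near the LoD, post-transplant proportional to
    # the destruction signal with multiplicative noise
    gad, m375 = [], []
    for sid in sample_ids:
        patient = sid.rsplit("_", 1)[0]
        if sid.endswith("post"):
            noise = 10.0 ** rng.normal(0.0, config.anchor_noise_log10_sd, 2)
            gad.append(config.gad65_scale * destroyed[patient] * noise[0])
            m375.append(config.mir375_scale * destroyed[patient] * noise[1])
        else:
            gad.append(abs(rng.normal(0.05, 0.02)))
            m375.append(abs(rng.normal(0.03, 0.01)))
    anchors = pd.DataFrame(
        {"gad65": gad, "mir375_molar": m375},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    roles = {duct_marker: "anchor"} if duct_marker else {}
    matrix = CqMatrix(
        cq=pd.DataFrame(cq, index=pd.Index(ids, name="assay_id"), columns=samples.index),
        assays=_assay_frame(ids, roles),
        samples=samples,
    )
    truth = SimTruth(
        destroyed_signal=destroyed,
        duct_signal=duct_signal,
        planted_markers=planted,
        confounders=confounders,
        duct_marker=duct_marker,
        true_folds=true_folds,
        outcome_coefficients={},
    )
    return matrix, anchors, truth


def gen_spiking_series(
    config: SimConfig,
    planted_markers: Mapping[str, float] | None = None,
    levels: Sequence[float] = (0.0, 5.0, 50.0, 250.0),
) -> tuple[CqMatrix, SimTruth]:
    """Beta-cell-lysate spiking series: planted assays dose-dependent, rest flat.

    Planted assays follow Cq = intercept − log(level·abundance)/log(E) at the
    positive levels and are absent (undetected) in unspiked plasma;
    background assays keep their plasma baseline at every level.
    """
    positive = [lv for lv in levels if lv > 0]
    if 0.0 not in levels or len(positive) < 3:
        raise ValueError("levels must include 0 and at least 3 positive levels")
    rng = np.random.default_rng(config.seed + 1)
    ids, base = _baselines(config, rng)
    log2e = np.log2(config.pcr_efficiency)

    if planted_markers is None:
        lo, hi = config.planted_weight_range
        weights = np.exp2(rng.uniform(np.log2(lo), np.log2(hi), config.n_planted))
        planted = dict(zip(ids[: config.n_planted], weights))
    else:
        unknown = set(planted_markers) - set(ids)
        if unknown:
            raise ValueError(f"planted assay(s) not on the card: {sorted(unknown)}")
        planted = dict(planted_markers)

    intercepts = {a: rng.normal(34.0, 0.5) for a in planted}

    sample_ids = [f"spike_{int(lv)}K" for lv in levels]
    cq = np.empty((config.n_assays, len(levels)))
    for j, lv in enumerate(levels):
        col = base.copy()
        for a in planted:
            i = ids.index(a)
            if lv == 0:
                col[i] = config.instrument_ceiling + 1.0  # absent in unspiked plasma
            else:
                # abundance weight rescaled so weight 64 ~ one extra cycle head start
                col[i] = intercepts[a] - np.log2(lv * planted[a] / 64.0) / log2e
        if config.noise_sd > 0:
            col = col + rng.normal(0.0, config.noise_sd, config.n_assays)
        cq[:, j] = col
    cq = _censor(cq, config)

    samples = pd.DataFrame(
        {
            "cohort": "control",
            "patient_id": "spike_pool",
            "phase": "spike",
            "pair_id": None,
            "spike_level": list(levels),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = CqMatrix(
        cq=pd.DataFrame(cq, index=pd.Index(ids, name="assay_id"), columns=samples.index),
        assays=_assay_frame(ids),
        samples=samples,
    )
    truth = SimTruth(
        destroyed_signal=pd.Series(dtype=float),
        duct_signal=None,
        planted_markers=planted,
        confounders={},
        duct_marker=None,
        true_folds=pd.DataFrame(),
        outcome_coefficients={},
    )
    return matrix, truth


def gen_clinical_cohort(
    config: SimConfig,
    n: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CqMatrix, SimTruth]:
    """Clinical cohort: paired Cq of the core panel, graft data and outcomes.

    The 2-month C-peptide increment rises with implanted beta-cell mass and
    falls with the latent destruction signal; a configurable fraction of
    patients are excessive-destruction outliers.  Outcome is dichotomized at
    an increment of 0.5 ng/mL (poor below).  Marker post-transplant Cq
    tracks the destruction signal per assay according to
    ``marker_signal_weights`` (weight 0 = pure noise marker).
    """
    n = config.clinical_n if n is None else n
    if n < 10:
        raise ValueError("clinical cohort needs at least 10 patients")
    rng = np.random.default_rng(config.seed + 2)
    log2e = np.log2(config.pcr_efficiency)

    weights = dict(config.marker_signal_weights or {a: 1.0 for a in CORE_PANEL})
    assays = list(weights)

    patients = [f"C{i:03d}" for i in range(1, n + 1)]
    mass = np.clip(rng.normal(config.beta_mass_mean, config.beta_mass_sd, n), 0.5, None)
    log_destruction = rng.normal(config.release_log10_mu, config.release_log10_sd, n)
    is_outlier = rng.random(n) < config.outlier_fraction
    log_destruction = log_destruction + is_outlier * config.outlier_boost_log10
    destruction = 10.0 ** log_destruction

    increment = (
        config.outcome_intercept
        + config.outcome_mass_coef * (mass - config.beta_mass_mean)
        - config.outcome_destruction_coef * log_destruction
        + rng.normal(0.0, config.outcome_noise_sd, n)
    )
    outcome = np.where(increment < 0.5, "poor", "good")

    # graft composition around the reported cohort averages
    beta_frac = np.clip(rng.normal(0.32, 0.03, n), 0.05, 0.6)
    alpha_frac = np.clip(rng.normal(0.12, 0.025, n), 0.01, 0.4)
    exo_frac = np.clip(rng.normal(0.02, 0.015, n), 0.0, 0.1)
    dead_frac = np.clip(rng.normal(0.10, 0.02, n), 0.0, 0.3)
    duct_frac = np.clip(1.0 - beta_frac - alpha_frac - exo_frac - dead_frac, 0.0, 1.0)
    cpep_content = mass * 10.0 ** rng.normal(0.0, 0.1, n)

    graft = pd.DataFrame(
        {
            "beta_cells": mass,
            "cpeptide_content": cpep_content,
            "alpha_cells": alpha_frac * mass / beta_frac,
            "exocrine_cells": exo_frac,
            "dead_cells": dead_frac,
            "duct_cells": duct_frac,
        },
        index=pd.Index(patients, name="pair_id"),
    )
    clinical = pd.DataFrame(
        {
            "cpeptide_increment_2mo": increment,
            "outcome": outcome,
        },
        index=pd.Index(patients, name="pair_id"),
    )

    # paired Cq for the panel: post-transplant surge = 64^weight-scaled signal
    sample_ids = [f"{p}_{ph}" for p in patients for ph in ("pre", "post")]
    baseline = {a: rng.normal(31.0, 0.5) for a in assays}
    cq = np.empty((len(assays), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        patient = sid.rsplit("_", 1)[0]
        k = patients.index(patient)
        for i, a in enumerate(assays):
            val = baseline[a]
            if sid.endswith("post"):
                # fold = 64 * destruction^weight: weight 0 -> constant 64x surge
                fold = 64.0 * destruction[k] ** weights[a]
                val = val - np.log2(fold) / log2e
            val += rng.normal(0.0, config.clinical_marker_noise_sd)
            cq[i, j] = val
    cq = _censor(cq, config)

    samples = pd.DataFrame(
        {
            "cohort": "clinical",
            "patient_id": [sid.rsplit("_", 1)[0] for sid in sample_ids],
            "phase": ["pre_tx" if sid.endswith("pre") else "post_tx" for sid in sample_ids],
            "pair_id": [sid.rsplit("_", 1)[0] for sid in sample_ids],
            "spike_level": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = CqMatrix(
        cq=pd.DataFrame(cq, index=pd.Index(assays, name="assay_id"), columns=samples.index),
        assays=_assay_frame(assays),
        samples=samples,
    )
    truth = SimTruth(
        destroyed_signal=pd.Series(destruction, index=patients),
        duct_signal=None,
        planted_markers={a: w for a, w in weights.items() if w > 0},
        confounders={},
        duct_marker=None,
        true_folds=pd.DataFrame(),
        outcome_coefficients={
            "intercept": config.outcome_intercept,
            "mass_coef": config.outcome_mass_coef,
            "destruction_coef": config.outcome_destruction_coef,
            "noise_sd": config.outcome_noise_sd,
            "outlier_fraction": config.outlier_fraction,
        },
    )
    return clinical, graft, matrix, truth
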