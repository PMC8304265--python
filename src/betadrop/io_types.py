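"""Domain types and text-table readers/writers for the qPCR biomarker pipeline.

The pipeline's raw substrate is a matrix of quantification-cycle (Cq, a.k.a.
Ct) values, assays as rows and samples as columns, exported from 384-well
TaqMan array cards as CSV/TSV.  Non-detection ("Undetermined" wells, or any
Cq the instrument refused to call) is a first-class state: it is carried as
NaN inside the matrices and never replaced by a numeric placeholder, so no
arithmetic can silently use it.

Sample annotations (cohort, patient, pre/post phase, transplant pairing,
spike-in level) live in a sidecar table keyed by sample id, matching how
instrument exports and LIMS systems usually separate data from design.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UNDETECTED_TOKENS",
    "CqMatrix",
    "NrqMatrix",
    "read_cq_table",
    "read_sample_metadata",
    "read_graft_compositions",
    "read_anchor_measurements",
    "read_clinical_records",
    "write_cq_table",
    "write_results",
]

#: Tokens in instrument exports that denote a non-detected well.
UNDETECTED_TOKENS = frozenset({"Undetermined", "undetermined", "NA", "", ">40"})

#: Detection limits of the two calibrated anchor assays (pmol/L).
GAD65_LOD = 0.121
GAD65_LOQ = 0.288
MIR375_LOD = 0.049
MIR375_LOQ = 0.102

_COHORTS = {"discovery", "validation1", "validation2", "clinical", "control"}
_PHASES = {"pre_tx", "post_tx", "healthy", "spike"}
_SPIKE_LEVELS = (0.0, 5.0, 50.0, 250.0)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclasses.dataclass
class CqMatrix:
    """Assays × samples grid of quantification-cycle values.

    Parameters
    ----------
    cq
        DataFrame indexed by assay id with sample ids as columns.  NaN marks
        an undetected (censored) well; every numeric entry is a finite,
        positive cycle number.
    assays
        Per-assay metadata indexed by assay id with columns ``mirna_name``
        and ``role`` (``candidate`` | ``reference`` | ``anchor``).
    samples
        Per-sample metadata indexed by sample id with columns ``cohort``,
        ``patient_id``, ``phase``, ``pair_id``, ``spike_level``.
    discordant
        Pairs ``(assay_id, sample_id)`` whose duplicate wells disagreed by
        more than the discordance threshold on load.
    """

    cq: pd.DataFrame
    assays: pd.DataFrame
    samples: pd.DataFrame
    discordant: frozenset = frozenset()

    def __post_init__(self) -> None:
        values = self.cq.to_numpy(dtype=float)
        valid = np.isnan(values) | (np.isfinite(values) & (values > 0))
        _require(bool(valid.all()), "numeric Cq values must be finite and > 0")
        _require(self.cq.index.is_unique, "assay identifiers must be unique")
        _require(self.cq.columns.is_unique, "sample identifiers must be unique")
        _require(
            list(self.cq.index) == list(self.assays.index),
            "cq rows and assay metadata must agree",
        )
        _require(
            list(self.cq.columns) == list(self.samples.index),
            "cq columns and sample metadata must agree",
        )
        validate_sample_metadata(self.samples)

    @property
    def n_assays(self) -> int:
        return self.cq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.cq.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected (numeric) cells."""
        return self.cq.notna()

    def subset_assays(self, assay_ids: Iterable[str]) -> "CqMatrix":
        ids = list(assay_ids)
        return CqMatrix(
            cq=self.cq.loc[ids],
            assays=self.assays.loc[ids],
            samples=self.samples,
            discordant=self.discordant,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "CqMatrix":
        ids = list(sample_ids)
        return CqMatrix(
            cq=self.cq[ids],
            assays=self.assays,
            samples=self.samples.loc[ids],
            discordant=self.discordant,
        )


@dataclasses.dataclass
class NrqMatrix:
    """Linear-scale normalized relative quantities per assay/sample.

    NaN marks a missing value (propagated non-detection).  ``imputed`` flags
    cells filled by the group-level imputation rule; those cells are numeric
    in ``nrq`` but must only feed group-level fold computation.
    """

    nrq: pd.DataFrame
    assays: pd.DataFrame
    samples: pd.DataFrame
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        values = self.nrq.to_numpy(dtype=float)
        finite = np.isfinite(values)
        _require(bool((values[finite] > 0).all()), "NRQ values must be positive")
        if self.imputed is None:
            self.imputed = pd.DataFrame(
                False, index=self.nrq.index, columns=self.nrq.columns
            )

    @property
    def log10_nrq(self) -> pd.DataFrame:
        return np.log10(self.nrq)

    def subset_assays(self, assay_ids: Iterable[str]) -> "NrqMatrix":
        ids = list(assay_ids)
        return NrqMatrix(
            nrq=self.nrq.loc[ids],
            assays=self.assays.loc[ids],
            samples=self.samples,
            imputed=self.imputed.loc[ids],
        )


def validate_sample_metadata(samples: pd.DataFrame) -> None:
    """Enforce the sample-annotation invariants.

    Each ``pair_id`` must link exactly one pre-transplant and one
    post-transplant sample, and ``spike_level`` is set iff the sample is a
    spike-in (level in {0, 5, 50, 250} thousand cells/mL).
    """
    bad_cohort = set(samples["cohort"]) - _COHORTS
    _require(not bad_cohort, f"unknown cohort labels: {sorted(bad_cohort)}")
    bad_phase = set(samples["phase"]) - _PHASES
    _require(not bad_phase, f"unknown phase labels: {sorted(bad_phase)}")

    paired = samples[samples["pair_id"].notna() & (samples["pair_id"] != "")]
    for pair_id, grp in paired.groupby("pair_id"):
        phases = sorted(grp["phase"])
        _require(
            phases == ["post_tx", "pre_tx"],
            f"pair {pair_id!r} must have exactly one pre_tx and one post_tx sample, got {phases}",
        )

    is_spike = samples["phase"] == "spike"
    has_level = samples["spike_level"].notna()
    _require(bool((is_spike == has_level).all()), "spike_level must be set iff phase == spike")
    levels = set(samples.loc[is_spike, "spike_level"].astype(float))
    _require(
        levels <= set(_SPIKE_LEVELS),
        f"spike levels must be in {_SPIKE_LEVELS} K cells/mL, got {sorted(levels)}",
    )


def pairs_of(samples: pd.DataFrame) -> pd.DataFrame:
    """Table of transplant pairs: index pair_id, columns pre/post sample ids."""
    paired = samples[samples["pair_id"].notna() & (samples["pair_id"] != "")]
    rows = {}
    for pair_id, grp in paired.groupby("pair_id"):
        pre = grp.index[grp["phase"] == "pre_tx"][0]
        post = grp.index[grp["phase"] == "post_tx"][0]
        rows[pair_id] = {"pre": pre, "post": post}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("pair_id")


def _parse_cq_cell(token: object, assay: str, sample: str) -> float:
    if isinstance(token, float):
        if np.isnan(token):
            return np.nan
        return float(token)
    text = str(token).strip()
    if text in UNDETECTED_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(
            f"unexpected non-numeric token {text!r} in cell (assay {assay!r}, sample {sample!r})"
        ) from None


def read_cq_table(
    path: str | Path,
    dialect: str | None = None,
    *,
    samples: pd.DataFrame | None = None,
    assay_roles: Mapping[str, str] | None = None,
    discordance_threshold: float = 1.0,
) -> CqMatrix:
    """Read a wide Cq table (one row per assay, one column per sample).

    The first column holds assay ids (optionally a second column
    ``mirna_name``); an optional ``well`` column marks duplicate wells of the
    same assay, which are averaged per sample (arithmetic mean of Cq).
    Duplicate-well pairs disagreeing by more than ``discordance_threshold``
    cycles are flagged discordant (kept, not dropped).  Without a ``well``
    column a repeated assay id is a hard error.

    ``dialect`` selects the delimiter (``csv``/``tsv``); by default it is
    inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = {"csv": ",", "tsv": "\t"}.get(
        dialect or ("csv" if path.suffix.lower() == ".csv" else "tsv")
    )
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    _require(len(cols) >= 2, "Cq table needs an assay-id column and at least one sample")
    id_col = cols[0]
    meta_cols = [c for c in ("mirna_name", "well") if c in cols]
    sample_cols = [c for c in cols[1:] if c not in meta_cols]

    parsed = pd.DataFrame(
        {
            s: [_parse_cq_cell(v, a, s) for a, v in zip(raw[id_col], raw[s])]
            for s in sample_cols
        }
    )
    parsed.index = pd.Index(raw[id_col], name="assay_id")

    names = raw["mirna_name"] if "mirna_name" in raw else raw[id_col]
    name_of = dict(zip(raw[id_col], names))

    discordant: set[tuple[str, str]] = set()
    if "well" in raw.columns:
        grouped = parsed.groupby(level=0, sort=False)
        means = grouped.mean()
        spans = grouped.max() - grouped.min()
        counts = grouped.count()
        for assay in means.index:
            for s in sample_cols:
                n = counts.loc[assay, s]
                if n >= 2 and spans.loc[assay, s] > discordance_threshold:
                    discordant.add((assay, s))
                if n == 1 and (parsed.loc[[assay], s].isna().any()):
                    # one numeric + one undetected well: discordant pair
                    discordant.add((assay, s))
        cq = means
    else:
        dup = parsed.index[parsed.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicated assay id(s) in {path.name}: {sorted(dup)}")
        cq = parsed

    assay_ids = list(cq.index)
    roles = {a: (assay_roles or {}).get(a, "candidate") for a in assay_ids}
    assays = pd.DataFrame(
        {"mirna_name": [name_of[a] for a in assay_ids], "role": [roles[a] for a in assay_ids]},
        index=pd.Index(assay_ids, name="assay_id"),
    )
    if samples is None:
        samples = pd.DataFrame(
            {
                "cohort": "discovery",
                "patient_id": list(cq.columns),
                "phase": "pre_tx",
                "pair_id": pd.NA,
                "spike_level": np.nan,
            },
            index=pd.Index(cq.columns, name="sample_id"),
        )
        # placeholder annotations; pairing left empty
        samples["pair_id"] = None
    else:
        samples = samples.loc[list(cq.columns)]
    return CqMatrix(cq=cq, assays=assays, samples=samples, discordant=frozenset(discordant))


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sidecar sample-annotation TSV keyed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "patient_id": str})
    df = df.set_index("sample_id")
    for col in ("pair_id",):
        if col in df:
            df[col] = df[col].where(df[col].notna(), None)
    if "spike_level" not in df:
        df["spike_level"] = np.nan
    validate_sample_metadata(df)
    return df


def read_graft_compositions(path: str | Path) -> pd.DataFrame:
    """Per-transplant graft composition keyed by pair_id.

    Columns: beta_cells (10^6 insulin-positive cells/kg BW), cpeptide_content,
    alpha_cells, exocrine_cells, dead_cells, duct_cells (fractions in [0,1]).
    """
    df = pd.read_csv(path, sep="\t").set_index("pair_id")
    for col in ("exocrine_cells", "dead_cells", "duct_cells"):
        if col in df:
            vals = df[col].dropna()
            _require(bool(((vals >= 0) & (vals <= 1)).all()), f"{col} fractions must lie in [0,1]")
    for col in ("beta_cells", "cpeptide_content", "alpha_cells"):
        if col in df:
            vals = df[col].dropna()
            _require(bool((vals >= 0).all()), f"{col} must be non-negative")
    return df


def read_anchor_measurements(path: str | Path) -> pd.DataFrame:
    """Anchor-marker concentrations per sample: GAD65 and molar miR-375 (pmol/L).

    Values below the assay limit of detection are kept but flagged censored.
    """
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    for col in ("gad65", "mir375_molar"):
        if col in df:
            vals = df[col].dropna()
            _require(bool((vals >= 0).all()), f"{col} must be non-negative")
    df["gad65_censored"] = df.get("gad65", np.nan) < GAD65_LOD
    df["mir375_censored"] = df.get("mir375_molar", np.nan) < MIR375_LOD
    return df


def read_clinical_records(path: str | Path, poor_threshold: float = 0.5) -> pd.DataFrame:
    """Clinical outcomes keyed by pair_id.

    ``outcome`` (poor/good) must be consistent with the 2-month C-peptide
    increment and the stated threshold (poor ⇔ increment < threshold ng/mL);
    if the column is absent it is derived.
    """
    df = pd.read_csv(path, sep="\t").set_index("pair_id")
    derived = np.where(df["cpeptide_increment_2mo"] < poor_threshold, "poor", "good")
    if "outcome" in df:
        _require(
            bool((df["outcome"] == derived).all()),
            f"outcome labels inconsistent with the {poor_threshold} ng/mL increment threshold",
        )
    else:
        df["outcome"] = derived
    return df


def write_cq_table(cq_matrix: CqMatrix, path: str | Path, undetected_token: str = "Undetermined") -> None:
    """Write a CqMatrix back to a wide TSV/CSV (round-trips read_cq_table)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    out = cq_matrix.cq.copy()
    formatted = out.map(lambda v: undetected_token if pd.isna(v) else repr(float(v)))
    formatted.insert(0, "mirna_name", cq_matrix.assays["mirna_name"])
    formatted.to_csv(path, sep=sep, index=True, index_label="assay_id")


def write_sample_metadata(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=True, index_label="sample_id")


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write result tables as TSVs plus a run-metadata YAML.

    Output is byte-stable for identical inputs: floats are rendered with
    ``repr`` (shortest round-trip form) and metadata keys are sorted.
    Returns the list of files written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, table in tables.items():
        target = out_dir / f"{name}.tsv"
        formatted = table.copy()
        for col in formatted.columns:
            if pd.api.types.is_float_dtype(formatted[col]):
                formatted[col] = formatted[col].map(
                    lambda v: "" if pd.isna(v) else repr(float(v))
                )
        formatted.to_csv(target, sep="\t", index=bool(table.index.name))
        written.append(target)
    meta = dict(metadata or {})
    meta.setdefault("package", "betadrop")
    meta_path = out_dir / "run_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    written.append(meta_path)
    return written
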