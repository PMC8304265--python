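import numpy as np
import pandas as pd
import pytest

from betadrop.io_types import CqMatrix, NrqMatrix


def make_samples(sample_ids, phases=None, pair_ids=None, cohort="discovery",
                 spike_levels=None):
    n = len(sample_ids)
    phases = phases or ["pre_tx"] * n
    return pd.DataFrame(
        {
            "cohort": cohort,
            "patient_id": [s.split("_")[0] for s in sample_ids],
            "phase": phases,
            "pair_id": pair_ids if pair_ids is not None else [None] * n,
            "spike_level": spike_levels if spike_levels is not None else [np.nan] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )


def make_cq(values, assay_ids=None, sample_ids=None, samples=None, **sample_kwargs):
    """Build a CqMatrix from a 2D array (NaN = undetected)."""
    values = np.asarray(values, dtype=float)
    n_assays, n_samples = values.shape
    assay_ids = assay_ids or [f"a{i}" for i in range(n_assays)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    assays = pd.DataFrame(
        {"mirna_name": assay_ids, "role": "candidate"},
        index=pd.Index(assay_ids, name="assay_id"),
    )
    if samples is None:
        samples = make_samples(sample_ids, **sample_kwargs)
    cq = pd.DataFrame(values, index=assays.index, columns=samples.index)
    return CqMatrix(cq=cq, assays=assays, samples=samples)


def make_paired_cq(values, n_pairs):
    """CqMatrix whose samples are n_pairs pre/post transplant pairs."""
    sample_ids = [f"P{i}_{ph}" for i in range(n_pairs) for ph in ("pre", "post")]
    phases = ["pre_tx", "post_tx"] * n_pairs
    pair_ids = [f"P{i}" for i in range(n_pairs) for _ in range(2)]
    samples = make_samples(sample_ids, phases=phases, pair_ids=pair_ids)
    return make_cq(values, sample_ids=sample_ids, samples=samples)


def make_nrq(values, assay_ids=None, sample_ids=None, samples=None, **sample_kwargs):
    values = np.asarray(values, dtype=float)
    n_assays, n_samples = values.shape
    assay_ids = assay_ids or [f"a{i}" for i in range(n_assays)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    assays = pd.DataFrame(
        {"mirna_name": assay_ids, "role": "candidate"},
        index=pd.Index(assay_ids, name="assay_id"),
    )
    if samples is None:
        samples = make_samples(sample_ids, **sample_kwargs)
    nrq = pd.DataFrame(values, index=assays.index, columns=samples.index)
    return NrqMatrix(nrq=nrq, assays=assays, samples=samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
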