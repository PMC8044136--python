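import json

import numpy as np
import pandas as pd
import pytest

from ckdphen.astage_training import PairedDataset, fit_ordinal
from ckdphen.synthetic import (
    GeneratorParams,
    pairs_to_dataset,
    simulate_cohort,
    simulate_paired_urine,
)


@pytest.fixture(scope="session")
def zero_noise():
    """Small noiseless cohort with complete coding and no AKI."""
    params = GeneratorParams(
        n_patients=200, creatinine_cv=0.0, code_capture=1.0, aki_episode_prob=0.0
    )
    return simulate_cohort(params, seed=11)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort under the default (noisy) study conditions."""
    return simulate_cohort(GeneratorParams(n_patients=300), seed=5)


@pytest.fixture(scope="session")
def paired_default():
    return simulate_paired_urine(GeneratorParams(), n=5000, seed=21)


@pytest.fixture(scope="session")
def upcr_model(paired_default):
    return fit_ordinal(pairs_to_dataset(paired_default, "upcr"))


@pytest.fixture(scope="session")
def dsp_models(paired_default):
    return {
        scale: fit_ordinal(pairs_to_dataset(paired_default, scale))
        for scale in ("dsp_scale1", "dsp_scale2")
    }


def make_cohort_files(tmp_path, demo_rows, lab_rows, code_rows, config):
    """Write the three extracts + config JSON; returns the four paths."""
    demo = tmp_path / "demographics.csv"
    labs = tmp_path / "labs.csv"
    codes = tmp_path / "codes.csv"
    cfg = tmp_path / "config.json"
    pd.DataFrame(demo_rows).to_csv(demo, index=False)
    pd.DataFrame(lab_rows, columns=["patient_id", "date", "code", "value", "units"]).to_csv(
        labs, index=False
    )
    pd.DataFrame(code_rows, columns=["patient_id", "date", "code", "system", "kind"]).to_csv(
        codes, index=False
    )
    cfg.write_text(json.dumps(config))
    return demo, labs, codes, cfg


BASIC_CONFIG = {
    "concept_map": {
        "2160-0": "serum_creatinine",
        "14959-1": "uacr",
        "2890-2": "upcr",
        "2965-2": "specific_gravity",
        "5804-0": {"concept": "dsp", "scale": "scale1"},
        "8302-2": "height",
    },
    "unit_map": {
        "serum_creatinine": {"mg/dL": 1.0, "umol/L": 1.0 / 88.4},
        "uacr": {"mg/g": 1.0},
        "upcr": {"mg/g": 1.0},
        "height": {"cm": 1.0},
    },
    "code_dictionary": {
        "ckd_diagnosis": [["ICD10CM", "N18*"], ["ICD9CM", "585*"]],
        "kidney_transplant": [["ICD10CM", "Z94.0"], ["CPT4", "50360"]],
        "dialysis": [["ICD10CM", "Z99.2"]],
        "acute_kidney_injury": [["ICD10CM", "N17*"]],
        "volume_depletion": [["ICD10CM", "E86*"]],
        "critical_illness": [["ICD10CM", "R57*"]],
    },
}
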