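"""Per-patient CKD phenotyping and placement on the A-by-G grid.

Order of decisions per patient: ESRD first (transplant, then dialysis,
from procedure/diagnosis codes alone), then G-staging from the latest
qualifying eGFR with the chronicity requirement, then A-staging from the
best available urine test. Normal-function patients without CKD codes
become G1A1 controls (urine confirms no albuminuria) or G1 controls (no
urine available); mildly reduced eGFR without a damage marker is not CKD.
Every decision is recorded in a JSON-lines evidence log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .astage import (
    AStageResult,
    OrdinalModel,
    albuminuria_positive_dates,
    stage_a,
)
from .config import DEFAULT_CONFIG, PhenotypeConfig
from .ehr_model import CodeDictionary, Cohort
from .gstage import GStageResult, stage_g

CATEGORIES = (
    "esrd_dialysis",
    "esrd_transplant",
    "ckd_case",
    "g1a1_control",
    "g1_control",
    "non_ckd_other",
    "unstageable",
)

G_ORDER = ("G1", "G2", "G3a", "G3b", "G4", "G5")
A_ORDER = ("A1", "A2", "A3")

_NKF_FROM_G = {"G3a": "3a", "G3b": "3b", "G4": "4", "G5": "5"}


@dataclass
class PhenotypeResult:
    patient_id: str
    category: str
    g_stage: str | None = None
    a_stage: str | None = None
    nkf_stage: str | None = None
    egfr_used: float | None = None
    egfr_date: pd.Timestamp | None = None
    a_source: str | None = None
    a_date: pd.Timestamp | None = None
    evidence: dict[str, Any] = field(default_factory=dict)


def nkf_stage(g_stage: str, a_stage: str | None, chronic_damage: bool) -> str | None:
    """Clinical CKD stage label, or None when the patient is not a case.

    Stages 3-5 follow from the G-stage alone; stages 1-2 additionally
    require a chronic damage marker (albuminuria or a CKD diagnosis code).
    """
    if g_stage in _NKF_FROM_G:
        return _NKF_FROM_G[g_stage]
    if g_stage in ("G1", "G2") and chronic_damage:
        return "1" if g_stage == "G1" else "2"
    return None


def _has_ckd_code(codes: pd.DataFrame, dictionary: CodeDictionary) -> bool:
    return any(
        "ckd_diagnosis" in dictionary.match(r.system, r.code)
        for r in codes.itertuples()
    )


def _esrd_category(
    codes: pd.DataFrame, dictionary: CodeDictionary, config: PhenotypeConfig
) -> tuple[str | None, list[str]]:
    hit_tx, hit_dial = [], []
    for r in codes.itertuples():
        cats = dictionary.match(r.system, r.code)
        if "kidney_transplant" in cats:
            hit_tx.append(r.code)
        if "dialysis" in cats:
            hit_dial.append(r.code)
    if hit_tx and (config.transplant_over_dialysis or not hit_dial):
        return "esrd_transplant", hit_tx
    if hit_dial:
        return "esrd_dialysis", hit_dial
    if hit_tx:
        return "esrd_transplant", hit_tx
    return None, []


def _damage_chronic(
    labs: pd.DataFrame,
    codes: pd.DataFrame,
    dictionary: CodeDictionary,
    a_result: AStageResult,
    models: Mapping[str, OrdinalModel] | None,
    config: PhenotypeConfig,
) -> bool:
    """90-day chronicity of the albuminuria damage marker itself.

    Satisfied by a CKD diagnosis code dated before the staging urine test,
    or an earlier albuminuria-positive result at least ``chronicity_days``
    before it.
    """
    ref_date = a_result.test_date
    for r in codes.itertuples():
        if r.date < ref_date and "ckd_diagnosis" in dictionary.match(r.system, r.code):
            return True
    for date in albuminuria_positive_dates(labs, models, config):
        if (ref_date - date).days >= config.chronicity_days:
            return True
    return False


def phenotype_patient(
    patient: pd.Series,
    labs: pd.DataFrame,
    codes: pd.DataFrame,
    dictionary: CodeDictionary,
    models: Mapping[str, OrdinalModel] | None = None,
    config: PhenotypeConfig = DEFAULT_CONFIG,
) -> PhenotypeResult:
    """Run the full decision flow for one patient."""
    pid = patient["patient_id"]
    evidence: dict[str, Any] = {}

    esrd, esrd_codes = _esrd_category(codes, dictionary, config)
    if esrd is not None:
        evidence["esrd_codes"] = esrd_codes
        return PhenotypeResult(
            patient_id=pid, category=esrd, nkf_stage=esrd, evidence=evidence
        )

    gres: GStageResult | None = stage_g(patient, labs, codes, dictionary, config)
    if gres is None:
        evidence["reason"] = "no qualifying eGFR"
        return PhenotypeResult(patient_id=pid, category="unstageable", evidence=evidence)
    evidence["chronicity"] = gres.chronicity_evidence
    evidence["n_excluded_egfrs"] = 0  # filled below when available

    ares = stage_a(patient, labs, models, config)
    a_label = None if ares.stage == "unknown" else ares.stage

    g = gres.stage
    has_code = _has_ckd_code(codes, dictionary)
    if g in _NKF_FROM_G:  # G3a..G5
        if gres.chronic:
            category = "ckd_case"
            nkf = nkf_stage(g, a_label, chronic_damage=True)
        else:
            category = "non_ckd_other"
            nkf = None
            evidence["reason"] = "chronicity not met"
    elif a_label in ("A2", "A3") and _damage_chronic(
        labs, codes, dictionary, ares, models, config
    ):
        category = "ckd_case"
        nkf = nkf_stage(g, a_label, chronic_damage=True)
    elif g == "G1" and not has_code and gres.egfr_used.value.egfr >= config.control_egfr_min:
        category = "g1a1_control" if a_label == "A1" else (
            "g1_control" if a_label is None else "non_ckd_other"
        )
        nkf = None
    else:
        category = "non_ckd_other"
        nkf = None

    if ares.class_probabilities is not None:
        evidence["a_probabilities"] = list(ares.class_probabilities)
        evidence["a_model"] = ares.model_id

    return PhenotypeResult(
        patient_id=pid,
        category=category,
        g_stage=g,
        a_stage=a_label,
        nkf_stage=nkf,
        egfr_used=gres.egfr_used.value.egfr,
        egfr_date=gres.egfr_used.value.date,
        a_source=ares.source_test,
        a_date=ares.test_date,
        evidence=evidence,
    )


def run_phenotyping(
    cohort: Cohort,
    dictionary: CodeDictionary,
    models: Mapping[str, OrdinalModel] | None = None,
    config: PhenotypeConfig = DEFAULT_CONFIG,
    log_path: str | Path | None = None,
) -> pd.DataFrame:
    """Phenotype every patient; returns one result row per patient.

    When ``log_path`` is given, a JSON-lines evidence log (one record per
    patient, including excluded eGFRs and the chronicity branch) is written
    alongside the results.
    """
    labs_by_pid = dict(tuple(cohort.labs.groupby("patient_id"))) if len(cohort.labs) else {}
    codes_by_pid = dict(tuple(cohort.codes.groupby("patient_id"))) if len(cohort.codes) else {}
    empty_labs = cohort.labs.iloc[0:0]
    empty_codes = cohort.codes.iloc[0:0]

    rows = []
    log_records = []
    for _, patient in cohort.patients.iterrows():
        pid = patient["patient_id"]
        res = phenotype_patient(
            patient,
            labs_by_pid.get(pid, empty_labs),
            codes_by_pid.get(pid, empty_codes),
            dictionary,
            models,
            config,
        )
        rows.append(
            {
                "patient_id": res.patient_id,
                "category": res.category,
                "g_stage": res.g_stage,
                "a_stage": res.a_stage,
                "nkf_stage": res.nkf_stage,
                "egfr_used": res.egfr_used,
                "egfr_date": res.egfr_date,
                "a_source": res.a_source,
                "a_date": res.a_date,
            }
        )
        if log_path is not None:
            log_records.append(
                {"patient_id": res.patient_id, "category": res.category, **{
                    k: (str(v) if isinstance(v, pd.Timestamp) else v)
                    for k, v in res.evidence.items()
                }}
            )
    results = pd.DataFrame(rows)
    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in log_records:
                fh.write(json.dumps(rec, default=str) + "\n")
    return results


@dataclass
class GridCounts:
    """Patient counts on the 3x6 A-by-G grid plus category tallies."""

    grid: pd.DataFrame  # index A1..A3, columns G1..G5
    category_counts: dict[str, int]

    @property
    def total(self) -> int:
        return int(sum(self.category_counts.values()))

    def row_margins(self) -> pd.Series:
        return self.grid.sum(axis=1)

    def col_margins(self) -> pd.Series:
        return self.grid.sum(axis=0)


def place_on_grid(results: pd.DataFrame) -> GridCounts:
    """Count patients per A-by-G cell (both stages known) and per category."""
    grid = pd.DataFrame(
        np.zeros((3, 6), dtype=int), index=list(A_ORDER), columns=list(G_ORDER)
    )
    staged = results.dropna(subset=["g_stage", "a_stage"]) if len(results) else results
    for row in staged.itertuples():
        grid.loc[row.a_stage, row.g_stage] += 1
    counts = {cat: 0 for cat in CATEGORIES}
    for cat, n in results["category"].value_counts().items() if len(results) else []:
        counts[cat] = int(n)
    return GridCounts(grid=grid, category_counts=counts)
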