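"""G-staging: qualifying eGFR selection, chronicity, threshold staging.

A creatinine drawn during an acute perturbation of steady-state clearance
(acute kidney injury, volume depletion, critical illness) does not reflect
chronic kidney function, so any eGFR within the acute window of such a code
is excluded. The latest non-excluded ("qualifying") eGFR is then staged on
the KDIGO G thresholds, and chronicity demands evidence of abnormality at
least 90 days earlier (prior CKD code, prior abnormal qualifying eGFR, or
prior albuminuria).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import DEFAULT_CONFIG, PhenotypeConfig
from .egfr import EgfrValue, egfr_series
from .ehr_model import CodeDictionary

G_STAGES = ("G1", "G2", "G3a", "G3b", "G4", "G5")

#: lower eGFR bound of each stage, descending
_G_THRESHOLDS = (("G1", 90.0), ("G2", 60.0), ("G3a", 45.0), ("G3b", 30.0), ("G4", 15.0))

ACUTE_CATEGORIES = ("acute_kidney_injury", "volume_depletion", "critical_illness")


@dataclass(frozen=True)
class QualifyingEgfr:
    """An eGFR annotated with its acute-exclusion status."""

    value: EgfrValue
    excluded: bool
    exclusion_reasons: tuple[tuple[str, str, pd.Timestamp], ...] = ()

    def __post_init__(self) -> None:
        if self.excluded != bool(self.exclusion_reasons):
            raise ValueError("excluded flag inconsistent with reasons")


@dataclass(frozen=True)
class GStageResult:
    stage: str
    egfr_used: QualifyingEgfr
    chronic: bool
    chronicity_evidence: str  # prior_ckd_code | prior_abnormal_egfr | prior_albuminuria | none


def classify_g(egfr: float) -> str:
    """KDIGO G-stage from eGFR; half-open, lower-inclusive bands.

    G1 >= 90, G2 [60, 90), G3a [45, 60), G3b [30, 45), G4 [15, 30), G5 < 15.
    """
    if not egfr > 0:
        raise ValueError(f"eGFR must be positive, got {egfr}")
    for stage, lower in _G_THRESHOLDS:
        if egfr >= lower:
            return stage
    return "G5"


def _acute_code_dates(
    codes: pd.DataFrame, dictionary: CodeDictionary
) -> list[tuple[str, str, pd.Timestamp]]:
    out = []
    for row in codes.itertuples():
        cats = dictionary.match(row.system, row.code)
        for cat in cats:
            if cat in ACUTE_CATEGORIES:
                out.append((cat, row.code, row.date))
    return out


def qualifying_egfrs(
    patient: pd.Series,
    labs: pd.DataFrame,
    codes: pd.DataFrame,
    dictionary: CodeDictionary,
    config: PhenotypeConfig = DEFAULT_CONFIG,
) -> list[QualifyingEgfr]:
    """All eGFRs with exclusion annotations, sorted by date descending.

    An eGFR is excluded when any acute-category code falls within
    ``config.acute_window_days`` calendar days (either side) of its date.
    """
    series = egfr_series(patient, labs, config)
    acute = _acute_code_dates(codes, dictionary)
    out = []
    for ev in series:
        reasons = tuple(
            (cat, code, date)
            for cat, code, date in acute
            if abs((date - ev.date).days) <= config.acute_window_days
        )
        out.append(
            QualifyingEgfr(value=ev, excluded=bool(reasons), exclusion_reasons=reasons)
        )
    return out


def chronicity_met(
    patient: pd.Series,
    index: QualifyingEgfr,
    labs: pd.DataFrame,
    codes: pd.DataFrame,
    dictionary: CodeDictionary,
    config: PhenotypeConfig = DEFAULT_CONFIG,
    all_egfrs: list[QualifyingEgfr] | None = None,
    models=None,
) -> tuple[bool, str]:
    """Whether the abnormality at the index eGFR is chronic, with evidence.

    True when any of: (a) a CKD diagnosis code strictly before the index
    date; (b) a non-excluded eGFR dated at least ``chronicity_days`` before
    the index (abnormal, < 60, when ``strict_chronicity``); (c) an
    albuminuria-positive urine result (A2/A3) at least ``chronicity_days``
    before the index.
    """
    index_date = index.value.date

    for row in codes.itertuples():
        if row.date < index_date and "ckd_diagnosis" in dictionary.match(
            row.system, row.code
        ):
            return True, "prior_ckd_code"

    if all_egfrs is None:
        all_egfrs = qualifying_egfrs(patient, labs, codes, dictionary, config)
    for q in all_egfrs:
        if q.excluded:
            continue
        if (index_date - q.value.date).days >= config.chronicity_days:
            if not config.strict_chronicity or q.value.egfr < 60.0:
                return True, "prior_abnormal_egfr"

    # circular-import-free local lookup of albuminuria-positive urine results
    from .astage import albuminuria_positive_dates

    for date in albuminuria_positive_dates(labs, models, config):
        if (index_date - date).days >= config.chronicity_days:
            return True, "prior_albuminuria"

    return False, "none"


def stage_g(
    patient: pd.Series,
    labs: pd.DataFrame,
    codes: pd.DataFrame,
    dictionary: CodeDictionary,
    config: PhenotypeConfig = DEFAULT_CONFIG,
) -> GStageResult | None:
    """Latest qualifying eGFR staged with chronicity; None if unstageable."""
    annotated = qualifying_egfrs(patient, labs, codes, dictionary, config)
    index = next((q for q in annotated if not q.excluded), None)
    if index is None:
        return None
    chronic, evidence = chronicity_met(
        patient, index, labs, codes, dictionary, config, all_egfrs=annotated
    )
    return GStageResult(
        stage=classify_g(index.value.egfr),
        egfr_used=index,
        chronic=chronic,
        chronicity_evidence=evidence,
    )
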