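"""Raw-EHR data model: cohort container, file I/O, units, code dictionary.

Three flat extracts (demographics, lab observations, clinical codes) are
loaded into a :class:`Cohort` of pandas DataFrames with all lab values in
canonical units. Unit conversion happens here and only here, so downstream
staging logic never sees institution-local units.

Canonical units: serum creatinine mg/dL; UACR and UPCR mg/g creatinine;
A24 and P24 mg/24 h; height cm; specific gravity unitless; dipstick protein
as an ordinal grade index on its declared scale.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

CONCEPTS = (
    "serum_creatinine",
    "uacr",
    "a24",
    "upcr",
    "p24",
    "dsp",
    "specific_gravity",
    "height",
)

#: urine tests that can carry an albuminuria stage
URINE_CONCEPTS = ("uacr", "a24", "upcr", "p24", "dsp")

CODE_SYSTEMS = ("ICD9CM", "ICD10CM", "SNOMED", "CPT4", "ICD9PCS", "ICD10PCS")

CATEGORIES = (
    "ckd_diagnosis",
    "kidney_transplant",
    "dialysis",
    "acute_kidney_injury",
    "volume_depletion",
    "critical_illness",
)

#: code systems admissible for each record kind
KIND_SYSTEMS = {
    "diagnosis": {"ICD9CM", "ICD10CM", "SNOMED"},
    "procedure": {"CPT4", "ICD9PCS", "ICD10PCS"},
}

# Dipstick grade vocabularies. Scale 1 is the +/- scale, Scale 2 the
# mg/dL-labelled scale; "trace" is its own level on both, never negative.
DSP_SCALE_LEVELS = {
    "scale1": ("negative", "trace", "1+", "2+", "3+", "4+"),
    "scale2": ("negative", "trace", "10", "30", "100", "300", ">=300"),
}

_DSP_ALIASES = {
    "neg": "negative",
    "-": "negative",
    "tr": "trace",
    "300+": ">=300",
    "≥300": ">=300",
    ">= 300": ">=300",
}


def dsp_level(scale: str, grade: str | int | float) -> int:
    """Ordinal index of a dipstick grade on its declared scale.

    Accepts either the textual grade (``"trace"``, ``"2+"``, ``"30"``, ...)
    or an already-numeric level index.
    """
    levels = DSP_SCALE_LEVELS.get(scale)
    if levels is None:
        raise ValueError(f"unknown dipstick scale: {scale!r}")
    if isinstance(grade, (int, float, np.integer, np.floating)):
        level = int(grade)
        if not 0 <= level < len(levels):
            raise ValueError(f"dipstick level {level} out of range for {scale}")
        return level
    text = str(grade).strip().lower()
    text = _DSP_ALIASES.get(text, text)
    if text not in levels:
        raise ValueError(f"grade {grade!r} not valid on {scale}")
    return levels.index(text)


# ---------------------------------------------------------------------------
# Code dictionary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeDictionary:
    """Category -> {(system, code-or-prefix)} mapping.

    A trailing ``*`` on an entry marks explicit prefix matching: ``N18*``
    matches ``N18`` and ``N18.4``. Matching is exact otherwise.
    """

    entries: Mapping[str, frozenset[tuple[str, str]]]

    def __post_init__(self) -> None:
        unknown = set(self.entries) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown code categories: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[Iterable[str]]]) -> "CodeDictionary":
        entries = {
            cat: frozenset((str(sys), str(code)) for sys, code in pairs)
            for cat, pairs in d.items()
        }
        return cls(entries=entries)

    def to_dict(self) -> dict[str, list[list[str]]]:
        return {
            cat: sorted([sys, code] for sys, code in pairs)
            for cat, pairs in self.entries.items()
        }

    def match(self, system: str, code: str) -> set[str]:
        """All categories containing the code exactly or by declared prefix."""
        out: set[str] = set()
        for cat, pairs in self.entries.items():
            for sys, entry in pairs:
                if sys != system:
                    continue
                if entry.endswith("*"):
                    if code.startswith(entry[:-1]):
                        out.add(cat)
                        break
                elif code == entry:
                    out.add(cat)
                    break
        return out


def match_category(code: str, system: str, dictionary: CodeDictionary) -> set[str]:
    """Categories a clinical code belongs to (empty set when unmatched)."""
    return dictionary.match(system, code)


# Illustrative starter dictionary. Any real deployment must substitute the
# locally reviewed code lists; these cover the common ICD-9/10 and CPT codes
# for each category so the pipeline is runnable out of the box.
DEFAULT_CODE_DICTIONARY = CodeDictionary.from_dict(
    {
        "ckd_diagnosis": [
            ("ICD9CM", "585*"),
            ("ICD10CM", "N18*"),
        ],
        "kidney_transplant": [
            ("ICD10CM", "Z94.0"),
            ("ICD9CM", "V42.0"),
            ("CPT4", "50360"),
            ("CPT4", "50365"),
            ("CPT4", "50380"),
        ],
        "dialysis": [
            ("CPT4", "90935*"),
            ("CPT4", "90937"),
            ("ICD10CM", "Z99.2"),
            ("ICD9CM", "V45.11"),
        ],
        "acute_kidney_injury": [
            ("ICD9CM", "584*"),
            ("ICD10CM", "N17*"),
        ],
        "volume_depletion": [
            ("ICD9CM", "276.5*"),
            ("ICD10CM", "E86*"),
        ],
        "critical_illness": [
            ("ICD10CM", "R57*"),
            ("ICD10CM", "A41*"),
            ("ICD9CM", "785.5*"),
            ("ICD9CM", "038*"),
        ],
    }
)


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------

@dataclass
class LoadReport:
    """Row accounting from a cohort load."""

    n_patients: int = 0
    n_lab_rows_read: int = 0
    n_lab_rows_kept: int = 0
    n_lab_rows_unmapped: int = 0
    n_lab_rows_rejected: int = 0
    rejected_reasons: list[dict[str, Any]] = field(default_factory=list)
    n_code_rows: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_patients": self.n_patients,
            "n_lab_rows_read": self.n_lab_rows_read,
            "n_lab_rows_kept": self.n_lab_rows_kept,
            "n_lab_rows_unmapped": self.n_lab_rows_unmapped,
            "n_lab_rows_rejected": self.n_lab_rows_rejected,
            "rejected_reasons": self.rejected_reasons,
            "n_code_rows": self.n_code_rows,
        }


@dataclass
class Cohort:
    """In-memory cohort: demographics, lab observations, clinical codes.

    ``patients``: patient_id, sex ('male'/'female'), birth_date
    (datetime64), race_black (nullable boolean), ethnicity.
    ``labs``: patient_id, date, concept, value, scale (dipstick scale or
    NA). Values are canonical units.
    ``codes``: patient_id, date, code, system, kind.
    """

    patients: pd.DataFrame
    labs: pd.DataFrame
    codes: pd.DataFrame
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.patients["patient_id"])
        for name, df in (("labs", self.labs), ("codes", self.codes)):
            if len(df):
                stray = set(df["patient_id"]) - known
                if stray:
                    raise ValueError(
                        f"{name} reference unknown patients: {sorted(stray)[:5]}"
                    )

    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    def labs_for(self, patient_id: str) -> pd.DataFrame:
        return self.labs[self.labs["patient_id"] == patient_id]

    def codes_for(self, patient_id: str) -> pd.DataFrame:
        return self.codes[self.codes["patient_id"] == patient_id]


_PATIENT_COLS = ["patient_id", "sex", "birth_date", "race", "ethnicity"]
_LAB_COLS = ["patient_id", "date", "code", "value", "units"]
_CODE_COLS = ["patient_id", "date", "code", "system", "kind"]

EMPTY_LABS = pd.DataFrame(
    columns=["patient_id", "date", "concept", "value", "scale"]
)
EMPTY_CODES = pd.DataFrame(columns=_CODE_COLS)


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file is missing required column(s): {missing}")


def _parse_sex(raw: str) -> str:
    s = str(raw).strip().lower()
    if s in ("male", "m"):
        return "male"
    if s in ("female", "f"):
        return "female"
    raise ValueError(f"unrecognized sex value: {raw!r}")


def load_cohort(
    demographics_path: str | Path,
    labs_path: str | Path,
    codes_path: str | Path,
    config: Mapping[str, Any] | str | Path,
) -> tuple[Cohort, LoadReport]:
    """Load the three flat extracts into a canonical-unit :class:`Cohort`.

    ``config`` is the JSON config document (or its path) holding
    ``concept_map`` (local lab code -> {concept, scale?}), ``unit_map``
    (concept -> {unit label -> multiplicative factor to canonical}) and
    ``code_dictionary``.

    Rows whose lab code has no concept mapping are dropped and counted;
    negative mass values are rejected with a logged reason; an unknown unit
    label is a hard error.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    concept_map: Mapping[str, Any] = config["concept_map"]
    unit_map: Mapping[str, Mapping[str, float]] = config.get("unit_map", {})
    code_dict = CodeDictionary.from_dict(config.get("code_dictionary", {}))

    report = LoadReport()

    demo = pd.read_csv(demographics_path, dtype=str)
    _require_columns(demo, ["patient_id", "sex", "birth_date"], "demographics")
    patients = pd.DataFrame(
        {
            "patient_id": demo["patient_id"].astype(str),
            "sex": demo["sex"].map(_parse_sex),
            "birth_date": pd.to_datetime(demo["birth_date"]),
            "race": demo["race"] if "race" in demo else pd.Series([None] * len(demo)),
            "ethnicity": demo["ethnicity"]
            if "ethnicity" in demo
            else pd.Series([None] * len(demo)),
        }
    )
    patients["race_black"] = (
        patients["race"].str.strip().str.lower().eq("black")
    ).where(patients["race"].notna())
    if patients["patient_id"].duplicated().any():
        dupes = patients.loc[patients["patient_id"].duplicated(), "patient_id"]
        raise ValueError(f"duplicate patient_id(s): {sorted(set(dupes))[:5]}")
    report.n_patients = len(patients)

    labs_raw = pd.read_csv(labs_path, dtype=str)
    if len(labs_raw) == 0 and labs_raw.columns.tolist() == []:
        labs_raw = pd.DataFrame(columns=_LAB_COLS)
    _require_columns(labs_raw, ["patient_id", "date", "code", "value"], "labs")
    report.n_lab_rows_read = len(labs_raw)

    rows: list[dict[str, Any]] = []
    for rec in labs_raw.itertuples(index=False):
        mapping = concept_map.get(str(rec.code))
        if mapping is None:
            report.n_lab_rows_unmapped += 1
            continue
        if isinstance(mapping, str):
            mapping = {"concept": mapping}
        concept = mapping["concept"]
        if concept not in CONCEPTS:
            raise ValueError(f"concept_map targets unknown concept {concept!r}")
        scale = mapping.get("scale")
        if concept == "dsp":
            if scale not in DSP_SCALE_LEVELS:
                raise ValueError(
                    f"dsp concept mapping for code {rec.code!r} must declare "
                    "scale 'scale1' or 'scale2'"
                )
            try:
                value = float(dsp_level(scale, rec.value))
            except ValueError as exc:
                report.n_lab_rows_rejected += 1
                report.rejected_reasons.append(
                    {"patient_id": rec.patient_id, "code": rec.code, "reason": str(exc)}
                )
                continue
        else:
            value = float(rec.value)
            units = getattr(rec, "units", None)
            if units is not None and not pd.isna(units) and str(units).strip():
                factors = unit_map.get(concept, {})
                if str(units) not in factors:
                    raise ValueError(
                        f"unknown unit {units!r} for concept {concept!r}; "
                        "declare it in unit_map"
                    )
                value *= float(factors[str(units)])
            if value < 0:
                report.n_lab_rows_rejected += 1
                report.rejected_reasons.append(
                    {
                        "patient_id": rec.patient_id,
                        "code": rec.code,
                        "reason": f"negative value {value}",
                    }
                )
                continue
            if concept == "specific_gravity" and not 1.0 <= value <= 1.060:
                report.n_lab_rows_rejected += 1
                report.rejected_reasons.append(
                    {
                        "patient_id": rec.patient_id,
                        "code": rec.code,
                        "reason": f"specific gravity {value} outside [1.000, 1.060]",
                    }
                )
                continue
        rows.append(
            {
                "patient_id": str(rec.patient_id),
                "date": pd.Timestamp(rec.date),
                "concept": concept,
                "value": value,
                "scale": scale,
            }
        )
    labs = pd.DataFrame(rows, columns=EMPTY_LABS.columns.tolist())
    if len(labs):
        labs["date"] = pd.to_datetime(labs["date"])
    report.n_lab_rows_kept = len(labs)

    codes_raw = pd.read_csv(codes_path, dtype=str)
    if len(codes_raw) == 0 and codes_raw.columns.tolist() == []:
        codes_raw = pd.DataFrame(columns=_CODE_COLS)
    _require_columns(codes_raw, _CODE_COLS, "codes")
    codes = codes_raw.copy()
    codes["date"] = pd.to_datetime(codes["date"])
    bad_sys = ~codes["system"].isin(CODE_SYSTEMS)
    if bad_sys.any():
        raise ValueError(
            f"unknown code system(s): {sorted(set(codes.loc[bad_sys, 'system']))}"
        )
    for kind, allowed in KIND_SYSTEMS.items():
        bad = (codes["kind"] == kind) & ~codes["system"].isin(allowed)
        if bad.any():
            raise ValueError(
                f"system/kind mismatch for kind={kind!r}: "
                f"{sorted(set(codes.loc[bad, 'system']))}"
            )
    report.n_code_rows = len(codes)

    cohort = Cohort(
        patients=patients,
        labs=labs,
        codes=codes,
        meta={
            "source_files": {
                "demographics": str(demographics_path),
                "labs": str(labs_path),
                "codes": str(codes_path),
            },
            "load_timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
            "code_dictionary": code_dict.to_dict(),
        },
    )
    cohort.meta["code_dictionary_obj"] = code_dict
    return cohort, report


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Dump a cohort to the canonical CSV layout (lossless round trip)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "demographics": out / "demographics.csv",
        "labs": out / "labs.csv",
        "codes": out / "codes.csv",
    }
    demo = cohort.patients.copy()
    demo["birth_date"] = demo["birth_date"].dt.strftime("%Y-%m-%d")
    demo[["patient_id", "sex", "birth_date", "race", "ethnicity"]].to_csv(
        paths["demographics"], index=False
    )
    labs = cohort.labs.copy()
    if len(labs):
        labs["date"] = labs["date"].dt.strftime("%Y-%m-%d")
    labs.to_csv(paths["labs"], index=False, float_format="%.17g")
    codes = cohort.codes.copy()
    if len(codes):
        codes["date"] = codes["date"].dt.strftime("%Y-%m-%d")
    codes.to_csv(paths["codes"], index=False)
    return paths


def read_canonical_cohort(in_dir: str | Path) -> Cohort:
    """Reload a cohort written by :func:`write_cohort`."""
    d = Path(in_dir)
    patients = pd.read_csv(d / "demographics.csv", dtype={"patient_id": str})
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])
    patients["race_black"] = (
        patients["race"].astype("string").str.strip().str.lower().eq("black")
    ).where(patients["race"].notna())
    labs = pd.read_csv(d / "labs.csv", dtype={"patient_id": str})
    if len(labs):
        labs["date"] = pd.to_datetime(labs["date"])
    else:
        labs = EMPTY_LABS.copy()
    codes = pd.read_csv(d / "codes.csv", dtype={"patient_id": str})
    if len(codes):
        codes["date"] = pd.to_datetime(codes["date"])
    else:
        codes = EMPTY_CODES.copy()
    return Cohort(patients=patients, labs=labs, codes=codes)


def age_years(birth_date: pd.Timestamp, at: pd.Timestamp) -> float:
    """Age in years as a calendar-day difference over the mean year length."""
    return (pd.Timestamp(at) - pd.Timestamp(birth_date)).days / 365.25
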