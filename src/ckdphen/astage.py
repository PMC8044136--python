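"""A-staging: albuminuria stage from the best available urine test.

UACR and 24-h urine albumin map directly onto the KDIGO albuminuria bands.
Total-protein measures (UPCR, 24-h protein) and semi-quantitative dipstick
protein need a fitted proportional-odds classifier; the dipstick one also
takes same-day urine specific gravity, because a dipstick grade on dilute
urine means more true albuminuria than the same grade on concentrated
urine. Tests are ranked by how directly they measure albumin: albumin
measures first, then protein ratios, then dipstick + specific gravity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PhenotypeConfig
from .ehr_model import DSP_SCALE_LEVELS

A_STAGES = ("A1", "A2", "A3")

#: preference tiers, best first
PREFERENCE_TIERS = (("uacr", "a24"), ("upcr", "p24"), ("dsp",))


def classify_a_direct(value: float) -> str:
    """KDIGO albuminuria stage from UACR (mg/g) or A24 (mg/24 h).

    A1 < 30, A2 in [30, 300] (ties at 300 resolve low), A3 > 300.
    """
    if value < 0:
        raise ValueError(f"albumin measure must be non-negative, got {value}")
    if value < 30.0:
        return "A1"
    if value <= 300.0:
        return "A2"
    return "A3"


# ---------------------------------------------------------------------------
# Proportional-odds model container
# ---------------------------------------------------------------------------

_TRANSFORMS = {
    "identity": lambda v: float(v),
    # floor at 1 mg/g keeps zero measurements finite; 1 mg/g is below any
    # clinically meaningful proteinuria
    "log_floor_1": lambda v: math.log(max(float(v), 1.0)),
    # (SG - 1.000) * 1000 for numeric conditioning
    "sg_milliunits": lambda v: (float(v) - 1.0) * 1000.0,
}


@dataclass
class OrdinalModel:
    """Fitted proportional-odds A-stage classifier.

    Cumulative model P(Y <= k | x) = logistic(theta_k - beta . x) over the
    ordered stages A1 < A2 < A3, with strictly increasing cutpoints.
    ``feature_spec`` maps raw inputs to model features and makes serialized
    models self-describing.
    """

    model_id: str
    scale: str  # "upcr" | "dsp_scale1" | "dsp_scale2"
    feature_spec: list[dict[str, str]]
    thetas: list[float]  # [theta1, theta2], strictly increasing
    betas: list[float]  # one per feature
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.thetas) != 2 or not self.thetas[0] < self.thetas[1]:
            raise ValueError("cutpoints must satisfy theta1 < theta2")
        if len(self.betas) != len(self.feature_spec):
            raise ValueError("one coefficient per feature required")
        for spec in self.feature_spec:
            if spec["transform"] not in _TRANSFORMS:
                raise ValueError(f"unknown transform {spec['transform']!r}")

    # -- feature handling ---------------------------------------------------
    def design(self, raw: Mapping[str, float]) -> np.ndarray:
        """Feature vector from raw inputs named by the feature spec."""
        try:
            return np.array(
                [
                    _TRANSFORMS[spec["transform"]](raw[spec["input"]])
                    for spec in self.feature_spec
                ]
            )
        except KeyError as exc:
            raise ValueError(
                f"missing input {exc} for model {self.model_id!r}"
            ) from exc

    def class_probabilities(self, raw: Mapping[str, float]) -> np.ndarray:
        x = self.design(raw)
        eta = float(np.dot(self.betas, x))
        from scipy.special import expit

        c1 = expit(self.thetas[0] - eta)
        c2 = expit(self.thetas[1] - eta)
        return np.array([c1, c2 - c1, 1.0 - c2])

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "model_id": self.model_id,
                "scale": self.scale,
                "feature_spec": self.feature_spec,
                "thetas": self.thetas,
                "betas": self.betas,
                "training_metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "OrdinalModel":
        d = json.loads(text)
        return cls(
            model_id=d["model_id"],
            scale=d["scale"],
            feature_spec=d["feature_spec"],
            thetas=d["thetas"],
            betas=d["betas"],
            metadata=d.get("training_metadata", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "OrdinalModel":
        return cls.from_json(Path(path).read_text())


UPCR_FEATURE_SPEC = [{"name": "log_upcr", "input": "upcr", "transform": "log_floor_1"}]
DSP_FEATURE_SPEC = [
    {"name": "dsp_grade", "input": "grade", "transform": "identity"},
    {"name": "sg_milli", "input": "sg", "transform": "sg_milliunits"},
]


def predict_a(model: OrdinalModel, features: Mapping[str, float]) -> tuple[str, np.ndarray]:
    """Most likely A-stage and the class probabilities.

    Argmax over the proportional-odds class probabilities; exact ties
    resolve to the lower stage.
    """
    probs = model.class_probabilities(features)
    return A_STAGES[int(np.argmax(probs))], probs


# ---------------------------------------------------------------------------
# Test selection and staging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AStageResult:
    stage: str  # "A1" | "A2" | "A3" | "unknown"
    source_test: str | None = None
    test_date: pd.Timestamp | None = None
    class_probabilities: tuple[float, float, float] | None = None
    model_id: str | None = None


def _sg_dates(labs: pd.DataFrame) -> set[pd.Timestamp]:
    return set(labs.loc[labs["concept"] == "specific_gravity", "date"])


def _candidate_rows(labs: pd.DataFrame) -> pd.DataFrame:
    """Urine-test rows usable for staging (dipstick needs same-day SG)."""
    urine = labs[labs["concept"].isin(("uacr", "a24", "upcr", "p24", "dsp"))]
    if len(urine) == 0:
        return urine
    sg_dates = _sg_dates(labs)
    ok = urine.apply(
        lambda r: r["concept"] != "dsp" or r["date"] in sg_dates, axis=1
    )
    return urine[ok]


def _tier_of(concept: str) -> int:
    for i, tier in enumerate(PREFERENCE_TIERS):
        if concept in tier:
            return i
    raise ValueError(f"not a urine concept: {concept}")


def select_urine_test(
    patient: pd.Series,
    labs: pd.DataFrame,
    policy: str = "preference-first",
) -> pd.Series | None:
    """Pick the urine observation to stage from, or None.

    ``preference-first`` (default): most recent observation within the
    highest-preference tier that has any usable observation. A dipstick
    only qualifies with a same-day specific gravity. ``recency-first``:
    strict most-recent usable test; tier rank breaks same-day ties.
    """
    cands = _candidate_rows(labs)
    if len(cands) == 0:
        return None
    cands = cands.assign(_tier=cands["concept"].map(_tier_of))
    if policy == "preference-first":
        best_tier = cands["_tier"].min()
        cands = cands[cands["_tier"] == best_tier]
    elif policy != "recency-first":
        raise ValueError(f"unknown preference policy {policy!r}")
    # most recent; ties broken by tier rank then concept order within tier
    cands = cands.sort_values(
        ["date", "_tier"], ascending=[False, True], kind="stable"
    )
    return cands.iloc[0].drop("_tier")


def albuminuria_positive_dates(
    labs: pd.DataFrame,
    models: Mapping[str, OrdinalModel] | None = None,
    config: PhenotypeConfig = DEFAULT_CONFIG,
) -> list[pd.Timestamp]:
    """Dates of urine results staging A2 or A3.

    Direct albumin measures always contribute; protein/dipstick results
    contribute when the matching fitted model is supplied.
    """
    out = []
    sg_by_date: dict[pd.Timestamp, float] = {}
    if models:
        sg = labs[labs["concept"] == "specific_gravity"]
        sg_by_date = dict(zip(sg["date"], sg["value"]))
    for row in labs.itertuples():
        if row.concept in ("uacr", "a24"):
            if classify_a_direct(row.value) != "A1":
                out.append(row.date)
        elif models and row.concept in ("upcr", "p24") and "upcr" in models:
            stage, _ = predict_a(models["upcr"], {"upcr": row.value})
            if stage != "A1":
                out.append(row.date)
        elif models and row.concept == "dsp" and row.date in sg_by_date:
            key = f"dsp_{row.scale}"
            if key in models:
                grade = _effective_grade(row.value, row.scale, config)
                stage, _ = predict_a(
                    models[key], {"grade": grade, "sg": sg_by_date[row.date]}
                )
                if stage != "A1":
                    out.append(row.date)
    return out


def _effective_grade(level: float, scale: str, config: PhenotypeConfig) -> float:
    if scale == "scale2" and config.merge_scale2_top:
        top = len(DSP_SCALE_LEVELS["scale2"]) - 2  # "300" and ">=300" collapse
        return float(min(int(level), top))
    return float(level)


def stage_a(
    patient: pd.Series,
    labs: pd.DataFrame,
    models: Mapping[str, OrdinalModel] | None = None,
    config: PhenotypeConfig = DEFAULT_CONFIG,
) -> AStageResult:
    """Stage albuminuria from the selected urine test.

    Routes by concept: UACR/A24 -> direct thresholds; UPCR/P24 -> the UPCR
    classifier on log-protein (P24 mg/24 h treated as numerically equal to
    UPCR mg/g); dipstick -> the scale's classifier on (grade, specific
    gravity). No usable test -> stage "unknown".
    """
    models = models or {}
    row = select_urine_test(patient, labs, config.preference_policy)
    if row is None:
        return AStageResult(stage="unknown")
    concept = row["concept"]
    if concept in ("uacr", "a24"):
        return AStageResult(
            stage=classify_a_direct(row["value"]),
            source_test=concept,
            test_date=row["date"],
        )
    if concept in ("upcr", "p24"):
        model = models.get("upcr")
        if model is None:
            raise ValueError(
                f"selected test {concept!r} needs a fitted 'upcr' model"
            )
        stage, probs = predict_a(model, {"upcr": row["value"]})
        return AStageResult(
            stage=stage,
            source_test=concept,
            test_date=row["date"],
            class_probabilities=tuple(float(p) for p in probs),
            model_id=model.model_id,
        )
    # dipstick path
    key = f"dsp_{row['scale']}"
    model = models.get(key)
    if model is None:
        raise ValueError(f"selected dipstick on {row['scale']} needs model {key!r}")
    sg = labs[
        (labs["concept"] == "specific_gravity") & (labs["date"] == row["date"])
    ]["value"].iloc[0]
    grade = _effective_grade(row["value"], row["scale"], config)
    stage, probs = predict_a(model, {"grade": grade, "sg": sg})
    return AStageResult(
        stage=stage,
        source_test="dsp",
        test_date=row["date"],
        class_probabilities=tuple(float(p) for p in probs),
        model_id=model.model_id,
    )
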