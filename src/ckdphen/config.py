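"""Run configuration shared by every staging module.

Every switch defaults to the guideline-faithful reading; alternatives that
the guidelines leave open are exposed here so a whole deployment profile is
one JSON document.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any


@dataclass
class PhenotypeConfig:
    """Thresholds and policy switches for CKD diagnosis and staging.

    Parameters
    ----------
    acute_window_days:
        Half-width (calendar days) of the exclusion window around an acute
        condition code; an eGFR within this many days of an acute-kidney-
        injury, volume-depletion, or critical-illness code is not a
        qualifying eGFR. "Within one month" read as +/- 30 days.
    chronicity_days:
        Minimum separation (days) between the staging value and the prior
        evidence of abnormality required to call the abnormality chronic.
    pediatric_cutoff_years:
        Age below which the Bedside Schwartz equation is used instead of
        CKD-EPI.
    strict_chronicity:
        If True (default), a prior eGFR only evidences chronicity when it is
        itself abnormal (< 60); if False, any prior qualifying eGFR counts.
    preference_policy:
        "preference-first" (default): pick the most recent test within the
        highest-preference tier that has any observation. "recency-first":
        strict most-recent test wins; tier breaks same-day ties.
    race_term:
        Whether the CKD-EPI race coefficient is applied. Default True.
    merge_scale2_top:
        Collapse the Scale 2 dipstick levels "300" and ">=300" into one
        ordinal level. Default False (keep the printed scale).
    max_height_gap_days:
        Staleness limit for carrying a height observation to a pediatric
        creatinine date.
    control_egfr_min:
        Lower eGFR bound for the "normal renal function" control
        definitions (G1 controls), mL/min/1.73 m^2.
    transplant_over_dialysis:
        When a patient carries both transplant and dialysis codes, label as
        ESRD-after-transplant. Default True.
    """

    acute_window_days: int = 30
    chronicity_days: int = 90
    pediatric_cutoff_years: float = 18.0
    strict_chronicity: bool = True
    preference_policy: str = "preference-first"
    race_term: bool = True
    merge_scale2_top: bool = False
    max_height_gap_days: int = 730
    control_egfr_min: float = 90.0
    transplant_over_dialysis: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.preference_policy not in ("preference-first", "recency-first"):
            raise ValueError(
                f"unknown preference_policy: {self.preference_policy!r}"
            )
        if self.acute_window_days < 0 or self.chronicity_days < 0:
            raise ValueError("window lengths must be non-negative")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PhenotypeConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


DEFAULT_CONFIG = PhenotypeConfig()
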