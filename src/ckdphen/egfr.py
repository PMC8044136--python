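"""GFR estimation from serum creatinine.

Adults use the 2009 CKD-EPI creatinine equation; pediatric patients
(age < 18 by default) use the Bedside Schwartz equation, which needs a
height concurrent with the creatinine. Height rarely coincides with the
blood draw, so a two-point straight-line interpolation/extrapolation
through the nearest height observations supplies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, PhenotypeConfig
from .ehr_model import age_years

__all__ = [
    "EgfrValue",
    "ckd_epi_egfr",
    "schwartz_egfr",
    "height_at_date",
    "invert_ckd_epi",
    "egfr_series",
]


@dataclass(frozen=True)
class EgfrValue:
    """One estimated GFR with its provenance."""

    patient_id: str
    egfr: float  # mL/min/1.73 m^2
    date: pd.Timestamp
    equation: str  # "ckd_epi_2009" | "schwartz_bedside"
    creatinine_used: float  # mg/dL
    height_used: float | None = None  # cm


def ckd_epi_egfr(
    creatinine: float,
    age: float,
    sex: str,
    race_black: bool = False,
    race_term: bool = True,
) -> float:
    """2009 CKD-EPI creatinine eGFR, mL/min/1.73 m^2.

    eGFR = 141 * min(Scr/k, 1)^alpha * max(Scr/k, 1)^-1.209
         * 0.993^age * 1.018 [female] * 1.159 [Black, if race_term]

    with k = 0.7 (female) / 0.9 (male) and alpha = -0.329 / -0.411.
    Strictly decreasing in creatinine at fixed covariates.
    """
    if creatinine <= 0 or not np.isfinite(creatinine):
        raise ValueError(f"creatinine must be positive, got {creatinine}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if sex == "female":
        kappa, alpha = 0.7, -0.329
    else:
        kappa, alpha = 0.9, -0.411
    ratio = creatinine / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209
    egfr *= 0.993 ** age
    if sex == "female":
        egfr *= 1.018
    if race_term and race_black:
        egfr *= 1.159
    return egfr


def schwartz_egfr(creatinine: float, height: float) -> float:
    """Bedside Schwartz pediatric eGFR = 0.413 * height[cm] / Scr[mg/dL]."""
    if creatinine <= 0:
        raise ValueError(f"creatinine must be positive, got {creatinine}")
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    return 0.413 * height / creatinine


def height_at_date(
    target_date: pd.Timestamp,
    height_observations: list[tuple[pd.Timestamp, float]],
) -> float:
    """Height (cm) at ``target_date`` from the nearest observations.

    With two or more observations, the straight line through the two
    observations nearest in time to the target is evaluated at the target
    (exact interpolation when the target lies between them). A single
    observation is carried forward/backward. Equidistant candidates on
    opposite sides are both used (bracketing preferred); among same-side
    ties the earlier record wins. The result is clamped to the nearer
    observed height if the fitted line would go non-positive.
    """
    if not height_observations:
        raise ValueError("no height observations: pediatric eGFR unavailable")
    target = pd.Timestamp(target_date)
    obs = sorted(
        ((pd.Timestamp(d), float(h)) for d, h in height_observations),
        key=lambda p: p[0],
    )
    if len(obs) == 1:
        return obs[0][1]

    # rank by |distance to target|; prefer a bracketing pair, then earlier
    def sort_key(pair: tuple[pd.Timestamp, float]):
        delta = (pair[0] - target).days
        return (abs(delta), 0 if delta <= 0 else 1, pair[0])

    ranked = sorted(obs, key=sort_key)
    (d1, h1), (d2, h2) = sorted(ranked[:2], key=lambda p: p[0])
    if d1 == d2:
        return h1
    frac = (target - d1).days / (d2 - d1).days
    value = h1 + (h2 - h1) * frac
    if value <= 0:
        # runaway extrapolation; fall back to the nearer observed height
        value = h1 if abs((target - d1).days) <= abs((target - d2).days) else h2
    return value


def invert_ckd_epi(
    target_egfr: float,
    age: float,
    sex: str,
    race_black: bool = False,
    race_term: bool = True,
    rel_tol: float = 1e-9,
) -> float:
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``target_egfr``.

    Bisection on the strictly monotone map; raises when the target exceeds
    the equation's supremum for the covariates (Scr -> 0).
    """
    if target_egfr <= 0:
        raise ValueError("target eGFR must be positive")
    lo, hi = 1e-4, 50.0
    f_lo = ckd_epi_egfr(lo, age, sex, race_black, race_term)
    if target_egfr > f_lo:
        raise ValueError(
            f"target eGFR {target_egfr} unattainable (max {f_lo:.1f} at Scr->0)"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ckd_epi_egfr(mid, age, sex, race_black, race_term) > target_egfr:
            lo = mid
        else:
            hi = mid
        if (hi - lo) / hi < rel_tol:
            break
    return 0.5 * (lo + hi)


def egfr_series(
    patient: pd.Series,
    labs: pd.DataFrame,
    config: PhenotypeConfig = DEFAULT_CONFIG,
) -> list[EgfrValue]:
    """Every estimable eGFR for one patient, most recent first.

    Same-day duplicate creatinines are averaged. Pediatric creatinines with
    no height within ``config.max_height_gap_days`` yield no eGFR.
    """
    scr = labs[labs["concept"] == "serum_creatinine"]
    if len(scr) == 0:
        return []
    scr = scr.groupby("date", as_index=False)["value"].mean()
    heights = [
        (row.date, row.value)
        for row in labs[labs["concept"] == "height"].itertuples()
    ]
    race_black = bool(patient.get("race_black") is True)
    out: list[EgfrValue] = []
    for row in scr.itertuples():
        if row.value <= 0:
            continue
        age = age_years(patient["birth_date"], row.date)
        if age >= config.pediatric_cutoff_years:
            value = ckd_epi_egfr(
                row.value, age, patient["sex"], race_black, config.race_term
            )
            out.append(
                EgfrValue(
                    patient_id=patient["patient_id"],
                    egfr=value,
                    date=row.date,
                    equation="ckd_epi_2009",
                    creatinine_used=row.value,
                )
            )
        else:
            usable = [
                (d, h)
                for d, h in heights
                if abs((pd.Timestamp(d) - row.date).days) <= config.max_height_gap_days
            ]
            if not usable:
                continue
            height = height_at_date(row.date, usable)
            out.append(
                EgfrValue(
                    patient_id=patient["patient_id"],
                    egfr=schwartz_egfr(row.value, height),
                    date=row.date,
                    equation="schwartz_bedside",
                    creatinine_used=row.value,
                    height_used=height,
                )
            )
    out.sort(key=lambda v: v.date, reverse=True)
    return out
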