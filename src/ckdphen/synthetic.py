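"""Synthetic EHR cohorts and paired urine datasets with known ground truth.

The generator emulates the raw material the staging pipeline consumes:
longitudinal serum creatinine series derived from a known true GFR (by
numeric inversion of the CKD-EPI equation, plus lognormal measurement
noise), transient acute-kidney-injury excursions with matching diagnosis
codes, CKD/dialysis/transplant codes with imperfect capture, and urine
albumin tests. Paired urine datasets additionally emulate the joint
distribution of UACR, UPCR, dipstick grade, and specific gravity through a
shared latent urine-concentration factor.

Every draw flows from one seeded generator with a named substream per
patient, so extending a cohort never perturbs earlier patients' data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .astage import classify_a_direct
from .astage_training import DSP_FEATURE_SPEC, UPCR_FEATURE_SPEC, PairedDataset
from .egfr import invert_ckd_epi
from .ehr_model import EMPTY_CODES, EMPTY_LABS, Cohort
from .gstage import classify_g

__all__ = [
    "GeneratorParams",
    "simulate_cohort",
    "simulate_paired_urine",
    "simulate_ordinal_responses",
    "pairs_to_dataset",
]

# G-stage bands for drawing a true GFR (upper bound for G1 is a soft cap).
# Band edges are padded half a unit inside the staging thresholds so the
# numeric creatinine inversion can never flip a stage at a boundary.
_G_BANDS = {
    "G1": (90.5, 120.0),
    "G2": (60.5, 89.5),
    "G3a": (45.5, 59.5),
    "G3b": (30.5, 44.5),
    "G4": (15.5, 29.5),
    "G5": (5.0, 14.5),
}
_A_BANDS = {"A1": (3.0, 29.0), "A2": (31.0, 299.0), "A3": (305.0, 3000.0)}
_G_ORDER = ("G1", "G2", "G3a", "G3b", "G4", "G5")
_A_ORDER = ("A1", "A2", "A3")

# Dipstick mg/dL bin edges (standard urinalysis conventions; a generator
# decision, not a claim about any particular institution's assay).
_SCALE1_EDGES = (15.0, 30.0, 100.0, 300.0, 1000.0)  # negative..4+
_SCALE2_EDGES = (5.0, 10.0, 30.0, 100.0, 300.0, 1000.0)  # negative..>=300


def _grade(conc: float, edges: tuple[float, ...]) -> int:
    return int(np.searchsorted(edges, conc, side="right"))


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic cohort.

    Defaults describe a realistic mixed nephrology/primary-care cohort:
    mostly normal or mildly reduced kidney function, 7% creatinine
    measurement CV, 90% probability that a true condition carries a code,
    visits every 120 days over two years.
    """

    n_patients: int = 500
    # A (rows: A1, A2, A3) by G (cols: G1..G5) mixture over the grid
    grid_weights: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.31, 0.20, 0.08, 0.04, 0.02, 0.01],
                [0.08, 0.06, 0.04, 0.03, 0.015, 0.01],
                [0.03, 0.025, 0.02, 0.015, 0.01, 0.005],
            ]
        )
    )
    p_esrd_dialysis: float = 0.02
    p_esrd_transplant: float = 0.01
    p_missing_urine: float = 0.15
    creatinine_cv: float = 0.07
    gfr_annual_slope: float = 0.0  # mL/min/1.73m^2 per year, applied to all
    # UPCR = UACR + non-albumin protein (lognormal, mean mg/g)
    nonalb_mean: float = 60.0
    nonalb_log_sd: float = 0.6
    # latent urine concentration factor c ~ lognormal(0, conc_log_sd)
    conc_log_sd: float = 0.5
    kappa_sg: float = 0.03  # SG = 1.000 + kappa_sg * c
    aki_episode_prob: float = 0.15
    aki_multiplier: float = 3.0
    code_capture: float = 0.9
    n_visits: int = 6
    visit_interval_days: int = 120
    age_min: float = 25.0
    age_max: float = 85.0
    p_female: float = 0.5
    p_black: float = 0.2
    # marginal A-stage mixture for paired urine rows
    a_mixture: tuple[float, float, float] = (0.60, 0.25, 0.15)

    def validate(self) -> None:
        w = np.asarray(self.grid_weights, dtype=float)
        if w.shape != (3, 6) or (w < 0).any() or w.sum() <= 0:
            raise ValueError("grid_weights must be a non-negative 3x6 matrix")
        for name in (
            "p_esrd_dialysis",
            "p_esrd_transplant",
            "p_missing_urine",
            "aki_episode_prob",
            "code_capture",
            "p_female",
            "p_black",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_esrd_dialysis + self.p_esrd_transplant > 1.0:
            raise ValueError("ESRD probabilities exceed 1")
        if self.creatinine_cv < 0 or self.conc_log_sd < 0 or self.nonalb_log_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if self.n_visits < 1 or self.visit_interval_days < 1:
            raise ValueError("visit schedule must be non-degenerate")
        a = np.asarray(self.a_mixture, dtype=float)
        if a.shape != (3,) or (a < 0).any() or a.sum() <= 0:
            raise ValueError("a_mixture must be 3 non-negative weights")

    def normalized_grid(self) -> np.ndarray:
        w = np.asarray(self.grid_weights, dtype=float)
        return w / w.sum()


_START = pd.Timestamp("2015-01-01")


def _lognormal_noise(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative noise with unit mean and coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _truth_nkf(g: str, a: str | None) -> str | None:
    if g in ("G3a", "G3b", "G4", "G5"):
        return {"G3a": "3a", "G3b": "3b", "G4": "4", "G5": "5"}[g]
    if a in ("A2", "A3"):
        return "1" if g == "G1" else "2"
    return None


def simulate_cohort(
    params: GeneratorParams, seed: int
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate a cohort and its ground truth.

    Returns the cohort (demographics, labs, codes) and a truth table with
    one row per patient: true category/stage labels as the direct staging
    rules applied to the noiseless true values, plus the latent state
    (true GFR, true UACR, AKI visit, urine availability).
    """
    params.validate()
    grid = params.normalized_grid()
    flat = grid.ravel()
    visit_days = np.arange(params.n_visits) * params.visit_interval_days
    span_days = visit_days[-1]

    pat_rows, lab_rows, code_rows, truth_rows = [], [], [], []
    for i in range(params.n_patients):
        rng = np.random.default_rng([seed, i])
        pid = f"P{i:05d}"
        sex = "female" if rng.random() < params.p_female else "male"
        black = bool(rng.random() < params.p_black)
        # quantize age to the whole-day birth date so downstream age
        # computations from birth_date reproduce the generator's ages exactly
        birth_days = round(float(rng.uniform(params.age_min, params.age_max)) * 365.25)
        age0 = birth_days / 365.25
        birth = _START - pd.Timedelta(days=birth_days)

        u = rng.random()
        esrd: str | None = None
        if u < params.p_esrd_dialysis:
            esrd = "esrd_dialysis"
        elif u < params.p_esrd_dialysis + params.p_esrd_transplant:
            esrd = "esrd_transplant"

        if esrd is None:
            cell = int(rng.choice(18, p=flat))
            a_true, g_true = _A_ORDER[cell // 6], _G_ORDER[cell % 6]
            gfr0 = float(rng.uniform(*_G_BANDS[g_true]))
            uacr = float(np.exp(rng.uniform(*np.log(_A_BANDS[a_true]))))
        else:
            a_true = g_true = None
            gfr0 = float(rng.uniform(5.0, 15.0))
            uacr = float(np.exp(rng.uniform(np.log(30.0), np.log(3000.0))))

        urine_observed = esrd is None and rng.random() >= params.p_missing_urine
        aki_visit = (
            int(rng.integers(params.n_visits))
            if esrd is None and rng.random() < params.aki_episode_prob
            else None
        )

        pat_rows.append(
            {
                "patient_id": pid,
                "sex": sex,
                "birth_date": birth,
                "race": "black" if black else "white",
                "ethnicity": None,
                "race_black": black,
            }
        )

        # longitudinal creatinine (and urine) per visit
        for v, day in enumerate(visit_days):
            date = _START + pd.Timedelta(days=int(day))
            age = age0 + day / 365.25
            gfr_v = max(gfr0 + params.gfr_annual_slope * day / 365.25, 2.0)
            scr = invert_ckd_epi(gfr_v, age, sex, black)
            scr *= _lognormal_noise(rng, params.creatinine_cv)
            if aki_visit is not None and v == aki_visit:
                scr *= params.aki_multiplier
                if rng.random() < params.code_capture:
                    code_rows.append(
                        {
                            "patient_id": pid,
                            "date": date,
                            "code": "N17.9",
                            "system": "ICD10CM",
                            "kind": "diagnosis",
                        }
                    )
            lab_rows.append(
                {
                    "patient_id": pid,
                    "date": date,
                    "concept": "serum_creatinine",
                    "value": scr,
                    "scale": None,
                }
            )
            if urine_observed:
                lab_rows.append(
                    {
                        "patient_id": pid,
                        "date": date,
                        "concept": "uacr",
                        "value": uacr,
                        "scale": None,
                    }
                )

        # true labels: the direct staging rules on the noiseless values
        if esrd is not None:
            category = esrd
            nkf = esrd
            if rng.random() < params.code_capture:
                code = ("Z99.2" if esrd == "esrd_dialysis" else "Z94.0", "ICD10CM")
                code_rows.append(
                    {
                        "patient_id": pid,
                        "date": _START + pd.Timedelta(days=int(span_days // 2)),
                        "code": code[0],
                        "system": code[1],
                        "kind": "diagnosis",
                    }
                )
            g_label = a_label = None
        else:
            g_label = classify_g(gfr0 + params.gfr_annual_slope * span_days / 365.25)
            a_label = classify_a_direct(uacr) if urine_observed else None
            detectable_case = g_label in ("G3a", "G3b", "G4", "G5") or (
                a_label in ("A2", "A3")
            )
            if detectable_case:
                category = "ckd_case"
                nkf = _truth_nkf(g_label, a_label)
                if rng.random() < params.code_capture:
                    code_rows.append(
                        {
                            "patient_id": pid,
                            "date": _START + pd.Timedelta(days=int(span_days // 2)),
                            "code": "N18.9",
                            "system": "ICD10CM",
                            "kind": "diagnosis",
                        }
                    )
            elif g_label == "G1":
                category = "g1a1_control" if a_label == "A1" else "g1_control"
                nkf = None
            else:
                category = "non_ckd_other"
                nkf = None

        truth_rows.append(
            {
                "patient_id": pid,
                "category": category,
                "g_stage": g_label,
                "a_stage": a_label,
                "nkf_stage": nkf,
                "true_gfr": gfr0,
                "true_uacr": uacr,
                "urine_observed": urine_observed,
                "aki_visit_day": None if aki_visit is None else int(visit_days[aki_visit]),
                "esrd": esrd,
            }
        )

    patients = pd.DataFrame(pat_rows)
    labs = pd.DataFrame(lab_rows) if lab_rows else EMPTY_LABS.copy()
    codes = pd.DataFrame(code_rows) if code_rows else EMPTY_CODES.copy()
    cohort = Cohort(
        patients=patients,
        labs=labs,
        codes=codes,
        meta={"generator": "ckdphen.synthetic", "seed": seed},
    )
    return cohort, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Paired urine datasets
# ---------------------------------------------------------------------------

def simulate_paired_urine(
    params: GeneratorParams, n: int, seed: int
) -> pd.DataFrame:
    """Same-day paired urine measurements with ground truth.

    Per row: a true UACR drawn from the A-stage mixture; UPCR = UACR plus a
    lognormal non-albumin protein component; a latent concentration factor
    c sets specific gravity (1.000 + kappa_sg * c, capped at 1.060) and the
    dipstick reading (UPCR * c on mg/dL bins for each reporting scale).
    The gold stage comes from the true UACR.
    """
    params.validate()
    rng = np.random.default_rng([seed, 10**6])
    a_w = np.asarray(params.a_mixture, dtype=float)
    a_w = a_w / a_w.sum()
    stages = rng.choice(3, size=n, p=a_w)
    lo = np.array([np.log(_A_BANDS[a][0]) for a in _A_ORDER])
    hi = np.array([np.log(_A_BANDS[a][1]) for a in _A_ORDER])
    uacr = np.exp(rng.uniform(lo[stages], hi[stages]))
    if params.nonalb_mean > 0:
        s = params.nonalb_log_sd
        nonalb = params.nonalb_mean * np.exp(rng.normal(-0.5 * s * s, s, size=n))
    else:
        nonalb = np.zeros(n)
    upcr = uacr + nonalb
    c = np.exp(rng.normal(0.0, params.conc_log_sd, size=n)) if params.conc_log_sd > 0 else np.ones(n)
    sg = np.minimum(1.0 + params.kappa_sg * c, 1.060)
    conc = upcr * c
    df = pd.DataFrame(
        {
            "uacr": uacr,
            "upcr": upcr,
            "conc_factor": c,
            "specific_gravity": sg,
            "dsp_scale1": [_grade(x, _SCALE1_EDGES) for x in conc],
            "dsp_scale2": [_grade(x, _SCALE2_EDGES) for x in conc],
            "gold_stage": stages,
        }
    )
    return df


def pairs_to_dataset(df: pd.DataFrame, scale: str) -> PairedDataset:
    """Convert a simulated paired table into a fit-ready dataset."""
    y = df["gold_stage"].to_numpy(int)
    if scale == "upcr":
        X = np.log(np.maximum(df["upcr"].to_numpy(float), 1.0))[:, None]
        return PairedDataset("upcr", X, y, UPCR_FEATURE_SPEC, raw=df)
    if scale in ("dsp_scale1", "dsp_scale2"):
        X = np.column_stack(
            [
                df[scale].to_numpy(float),
                (df["specific_gravity"].to_numpy(float) - 1.0) * 1000.0,
            ]
        )
        return PairedDataset(scale, X, y, DSP_FEATURE_SPEC, raw=df)
    raise ValueError(f"unknown scale {scale!r}")


def simulate_ordinal_responses(
    thetas: tuple[float, float],
    betas: float | np.ndarray,
    X: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Draw ordinal responses from a known proportional-odds model.

    Used for parameter-recovery and oracle-equivalence studies where the
    generating parameters must be known exactly.
    """
    from scipy.special import expit

    X = np.atleast_2d(np.asarray(X, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    eta = X @ betas
    c1 = expit(thetas[0] - eta)
    c2 = expit(thetas[1] - eta)
    rng = np.random.default_rng(seed)
    u = rng.random(len(eta))
    return np.where(u < c1, 0, np.where(u < c2, 1, 2)).astype(int)
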