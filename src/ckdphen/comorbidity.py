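"""Observational comorbidity analysis across the A-by-G grid.

For each comorbidity group (binary flags from an ICD code-set mapping, plus
the per-patient unique-code count), the independent severity gradients are
tested with a regression of the outcome on the ordinal A-stage and G-stage
with age and sex as covariates: logistic for binary outcomes, Poisson for
the code count, Wald tests per ordinal term, and a Bonferroni-adjusted
significance threshold across the test family. Cell prevalences are
age/sex standardized to the U.S. 2000 standard population by direct
standardization.

Stages enter the models as linear integer scores (A1..A3 -> 1..3,
G1..G5 -> 1..6 with the G3 split keeping its own levels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotype import A_ORDER, G_ORDER

__all__ = [
    "bonferroni_alpha",
    "build_comorbidity_table",
    "grid_gradient_test",
    "prevalence_heatmap",
    "GradientResult",
    "DEFAULT_COMORBIDITY_GROUPS",
    "US_2000_STANDARD_POPULATION",
]

A_SCORE = {a: i + 1 for i, a in enumerate(A_ORDER)}
G_SCORE = {g: i + 1 for i, g in enumerate(G_ORDER)}

# Illustrative code-set mapping (Elixhauser-style). Real analyses supply
# the full locally maintained category -> code-set JSON.
DEFAULT_COMORBIDITY_GROUPS: dict[str, list[list[str]]] = {
    "diabetes": [["ICD10CM", "E10*"], ["ICD10CM", "E11*"], ["ICD9CM", "250*"]],
    "hypertension": [["ICD10CM", "I10*"], ["ICD9CM", "401*"]],
    "congestive_heart_failure": [["ICD10CM", "I50*"], ["ICD9CM", "428*"]],
    "anemia": [["ICD10CM", "D64*"], ["ICD9CM", "285*"]],
    "obesity": [["ICD10CM", "E66*"], ["ICD9CM", "278.0*"]],
}

# U.S. 2000 standard population (Standard Million), 19 age groups.
# Columns: age_lo (inclusive), age_hi (exclusive), weight.
US_2000_STANDARD_POPULATION = pd.DataFrame(
    [
        (0, 1, 13818),
        (1, 5, 55317),
        (5, 10, 72533),
        (10, 15, 73032),
        (15, 20, 72169),
        (20, 25, 66478),
        (25, 30, 64529),
        (30, 35, 71044),
        (35, 40, 80762),
        (40, 45, 81851),
        (45, 50, 72118),
        (50, 55, 62716),
        (55, 60, 48454),
        (60, 65, 38793),
        (65, 70, 34264),
        (70, 75, 31773),
        (75, 80, 26999),
        (80, 85, 17842),
        (85, 200, 15508),
    ],
    columns=["age_lo", "age_hi", "weight"],
)


def bonferroni_alpha(
    family_alpha: float = 0.05, n_comorbidities: int = 40, tests_per: int = 2
) -> float:
    """Per-test alpha after Bonferroni correction over the test family."""
    return family_alpha / (n_comorbidities * tests_per)


def _matches(code: str, system: str, entries: list[list[str]]) -> bool:
    for sys, entry in entries:
        if sys != system:
            continue
        if entry.endswith("*"):
            if code.startswith(entry[:-1]):
                return True
        elif code == entry:
            return True
    return False


def build_comorbidity_table(
    codes: pd.DataFrame,
    patients: pd.DataFrame,
    groups: dict[str, list[list[str]]] | None = None,
    reference_date: pd.Timestamp | str = "2017-01-01",
) -> pd.DataFrame:
    """Per-patient comorbidity flags, unique-code count, age, and sex.

    Flags derive only from the codes table and the group dictionary; age is
    taken at ``reference_date``.
    """
    groups = groups if groups is not None else DEFAULT_COMORBIDITY_GROUPS
    ref = pd.Timestamp(reference_date)
    out = patients[["patient_id", "sex"]].copy()
    out["age"] = (ref - patients["birth_date"]).dt.days / 365.25
    counts = (
        codes.groupby("patient_id")["code"].nunique()
        if len(codes)
        else pd.Series(dtype=int)
    )
    out["unique_code_count"] = out["patient_id"].map(counts).fillna(0).astype(int)
    for name, entries in groups.items():
        if len(codes):
            hit = codes[
                codes.apply(lambda r: _matches(r["code"], r["system"], entries), axis=1)
            ]["patient_id"].unique()
        else:
            hit = []
        out[name] = out["patient_id"].isin(hit).astype(int)
    return out


@dataclass
class GradientResult:
    comorbidity: str
    model: str  # "logistic" | "poisson"
    coef_a: float
    se_a: float
    p_a: float
    coef_g: float
    se_g: float
    p_g: float
    alpha: float
    significant_a: bool
    significant_g: bool
    n: int
    covariates: tuple[str, ...] = ("age", "sex")


def fit_gradient_model(
    a_score: np.ndarray,
    g_score: np.ndarray,
    age: np.ndarray,
    female: np.ndarray,
    y: np.ndarray,
    family: str = "logistic",
) -> tuple[float, float, float, float, float, float]:
    """Age/sex-adjusted ordinal-gradient fit; returns per-term Wald results.

    Fits y ~ A + G + age + female with a logistic (binary y) or Poisson
    (count y) likelihood and returns (coef, se, Wald p) for the A and G
    ordinal terms.
    """
    X = sm.add_constant(
        np.column_stack([a_score, g_score, age, female]), has_constant="add"
    )
    fam = sm.families.Binomial() if family == "logistic" else sm.families.Poisson()
    fit = sm.GLM(y, X, family=fam).fit()
    return (
        float(fit.params[1]),
        float(fit.bse[1]),
        float(fit.pvalues[1]),
        float(fit.params[2]),
        float(fit.bse[2]),
        float(fit.pvalues[2]),
    )


def grid_gradient_test(
    results: pd.DataFrame,
    comorbidity_table: pd.DataFrame,
    family_alpha: float = 0.05,
    include_code_count: bool = True,
) -> list[GradientResult]:
    """Test every comorbidity for independent A- and G-stage gradients.

    Only patients with both stages known enter (ESRD and missing-urine
    patients are excluded by construction). The Bonferroni per-test alpha
    divides ``family_alpha`` by (number of comorbidities x 2 ordinal terms).
    Comorbidities with zero (or full) prevalence are skipped with a warning.
    Patients with missing sex are excluded with a warning.
    """
    staged = results.dropna(subset=["g_stage", "a_stage"])
    df = staged.merge(comorbidity_table, on="patient_id")
    if df["sex"].isna().any():
        warnings.warn("excluding patients with missing sex from adjusted models")
        df = df[df["sex"].notna()]
    a = df["a_stage"].map(A_SCORE).to_numpy(float)
    g = df["g_stage"].map(G_SCORE).to_numpy(float)
    age = df["age"].to_numpy(float)
    female = (df["sex"] == "female").to_numpy(float)

    meta_cols = {"patient_id", "sex", "age", "unique_code_count"}
    flag_cols = [c for c in comorbidity_table.columns if c not in meta_cols]
    outcomes: list[tuple[str, str]] = [(c, "logistic") for c in flag_cols]
    if include_code_count:
        outcomes.append(("unique_code_count", "poisson"))
    alpha = bonferroni_alpha(family_alpha, n_comorbidities=len(outcomes))

    out: list[GradientResult] = []
    for name, family in outcomes:
        y = df[name].to_numpy(float)
        if family == "logistic" and (y.sum() == 0 or y.sum() == len(y)):
            warnings.warn(f"comorbidity {name!r} has degenerate prevalence; skipped")
            continue
        ca, sa, pa, cg, sg_, pg = fit_gradient_model(a, g, age, female, y, family)
        out.append(
            GradientResult(
                comorbidity=name,
                model=family,
                coef_a=ca,
                se_a=sa,
                p_a=pa,
                coef_g=cg,
                se_g=sg_,
                p_g=pg,
                alpha=alpha,
                significant_a=pa < alpha,
                significant_g=pg < alpha,
                n=len(y),
            )
        )
    return out


def gradient_results_frame(results: list[GradientResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def prevalence_heatmap(
    results: pd.DataFrame,
    comorbidity_table: pd.DataFrame,
    comorbidity: str,
    standard_population: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Directly age/sex-standardized prevalence per A-by-G grid cell.

    Strata are standard-population age bands crossed with sex (sexes
    weighted equally within a band). Within each cell the stratum weights
    are renormalized over the strata actually present; an empty cell is
    reported as NaN, never zero.
    """
    std = (
        standard_population
        if standard_population is not None
        else US_2000_STANDARD_POPULATION
    )
    staged = results.dropna(subset=["g_stage", "a_stage"])
    df = staged.merge(comorbidity_table, on="patient_id")
    band = np.full(len(df), -1)
    for b, row in enumerate(std.itertuples()):
        in_band = (df["age"] >= row.age_lo) & (df["age"] < row.age_hi)
        band[in_band.to_numpy()] = b
    df = df.assign(_band=band)
    df = df[df["_band"] >= 0]
    weights = std["weight"].to_numpy(float)
    weights = weights / weights.sum()

    grid = pd.DataFrame(np.nan, index=list(A_ORDER), columns=list(G_ORDER))
    for a_st in A_ORDER:
        for g_st in G_ORDER:
            cell = df[(df["a_stage"] == a_st) & (df["g_stage"] == g_st)]
            if len(cell) == 0:
                continue
            num = 0.0
            denom = 0.0
            for (b, sex), grp in cell.groupby(["_band", "sex"]):
                w = weights[int(b)] * 0.5
                num += w * grp[comorbidity].mean()
                denom += w
            grid.loc[a_st, g_st] = num / denom
    return grid


def simulate_null_gradient_pvalues(
    n: int, seed: int, family: str = "logistic"
) -> tuple[float, float]:
    """One null replicate for Wald-test calibration.

    Stages, age and sex are drawn independently; the outcome depends on age
    and sex only, so both ordinal terms are truly null. Returns the Wald
    p-values for the A and G terms.
    """
    rng = np.random.default_rng(seed)
    a = rng.integers(1, 4, size=n).astype(float)
    g = rng.integers(1, 7, size=n).astype(float)
    age = rng.uniform(25, 85, size=n)
    female = rng.integers(0, 2, size=n).astype(float)
    eta = -1.0 + 0.01 * (age - 55.0) + 0.3 * female
    if family == "logistic":
        p = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(n) < p).astype(float)
    else:
        y = rng.poisson(np.exp(0.5 + 0.005 * (age - 55.0) + 0.1 * female)).astype(float)
    _, _, pa, _, _, pg = fit_gradient_model(a, g, age, female, y, family)
    return pa, pg
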