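"""Fitting and evaluating the proportional-odds A-stage classifiers.

Training data are same-day paired urine tests in which a direct albumin
measure (UACR) supplies the gold A-stage and the indirect test (UPCR, or
dipstick grade plus specific gravity) supplies the features. The model is
the cumulative-logit proportional-odds model

    P(Y <= k | x) = logistic(theta_k - beta . x),   theta1 < theta2,

fitted by maximum likelihood with an analytic gradient; the ordering
constraint is enforced by the reparameterization theta2 = theta1 +
exp(delta). Evaluation is k-fold cross-validation reporting per-stage
one-vs-rest accuracy/sensitivity/specificity and the fold-mean error, each
as mean +/- 1.96 * sd / sqrt(k) over the fold values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, log_expit

from .astage import (
    A_STAGES,
    DSP_FEATURE_SPEC,
    UPCR_FEATURE_SPEC,
    OrdinalModel,
    classify_a_direct,
)
from .config import DEFAULT_CONFIG, PhenotypeConfig

__all__ = [
    "PairedDataset",
    "build_pairs",
    "fit_ordinal",
    "cross_validate",
    "CVReport",
]


@dataclass
class PairedDataset:
    """Design matrix + gold stages for one classifier scale.

    ``X`` holds already-transformed model features (log-UPCR, or dipstick
    grade and SG milliunits); ``y`` holds gold stage indices 0/1/2 derived
    from same-day UACR by the direct thresholds.
    """

    scale: str  # "upcr" | "dsp_scale1" | "dsp_scale2"
    X: np.ndarray
    y: np.ndarray
    feature_spec: list[dict[str, str]] = field(default_factory=list)
    raw: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if len(self.y) and (self.y.min() < 0 or self.y.max() > 2):
            raise ValueError("gold stages must be indices in {0, 1, 2}")

    def __len__(self) -> int:
        return len(self.y)


def _stage_index(stage: str) -> int:
    return A_STAGES.index(stage)


def build_pairs(
    labs: pd.DataFrame,
    scale: str,
    config: PhenotypeConfig = DEFAULT_CONFIG,
) -> PairedDataset:
    """Same-day paired measurements for one classifier scale.

    ``scale='upcr'``: (patient, date) pairs holding both a UACR and a UPCR;
    the gold stage comes from the UACR, the feature is log-UPCR.
    ``scale='dsp_scale1'|'dsp_scale2'``: pairs holding a UACR, a dipstick
    on that scale, and a same-day specific gravity.
    Duplicate same-day measurements of a concept are averaged (dipstick:
    the maximum grade is kept).
    """
    if scale not in ("upcr", "dsp_scale1", "dsp_scale2"):
        raise ValueError(f"unknown classifier scale {scale!r}")
    key = ["patient_id", "date"]

    def pivot(concept: str, agg: str = "mean", dsp_scale: str | None = None) -> pd.DataFrame:
        sub = labs[labs["concept"] == concept]
        if dsp_scale is not None:
            sub = sub[sub["scale"] == dsp_scale]
        if len(sub) == 0:
            return pd.DataFrame(columns=key + [concept])
        return (
            sub.groupby(key, as_index=False)["value"].agg(agg).rename(columns={"value": concept})
        )

    gold = pivot("uacr")
    if scale == "upcr":
        merged = gold.merge(pivot("upcr"), on=key)
        if len(merged) == 0:
            return PairedDataset(scale, np.empty((0, 1)), np.empty(0, int), UPCR_FEATURE_SPEC)
        X = np.log(np.maximum(merged["upcr"].to_numpy(float), 1.0))[:, None]
        spec = UPCR_FEATURE_SPEC
    else:
        dsp_scale = scale.removeprefix("dsp_")
        merged = (
            gold.merge(pivot("dsp", agg="max", dsp_scale=dsp_scale), on=key)
            .merge(pivot("specific_gravity"), on=key)
        )
        if len(merged) == 0:
            return PairedDataset(scale, np.empty((0, 2)), np.empty(0, int), DSP_FEATURE_SPEC)
        grades = merged["dsp"].to_numpy(float)
        if dsp_scale == "scale2" and config.merge_scale2_top:
            grades = np.minimum(grades, 5.0)
        X = np.column_stack(
            [grades, (merged["specific_gravity"].to_numpy(float) - 1.0) * 1000.0]
        )
        spec = DSP_FEATURE_SPEC
    y = merged["uacr"].map(lambda v: _stage_index(classify_a_direct(v))).to_numpy(int)
    return PairedDataset(scale, X, y, spec, raw=merged)


# ---------------------------------------------------------------------------
# Maximum-likelihood fit
# ---------------------------------------------------------------------------

def _unpack(params: np.ndarray, m: int) -> tuple[np.ndarray, float, float]:
    betas = params[:m]
    theta1 = params[m]
    theta2 = theta1 + np.exp(params[m + 1])
    return betas, theta1, theta2


def ordinal_nll(params: np.ndarray, X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood of the 3-class cumulative-logit model + gradient.

    Parameter vector: (betas..., theta1, delta) with theta2 = theta1 + e^delta.
    """
    m = X.shape[1]
    betas, theta1, theta2 = _unpack(params, m)
    eta = X @ betas
    z1 = theta1 - eta
    z2 = theta2 - eta
    F1 = expit(z1)
    F2 = expit(z2)

    ll = np.empty(len(y))
    d1 = np.zeros(len(y))  # d loglik / d z1
    d2 = np.zeros(len(y))  # d loglik / d z2

    m0 = y == 0
    ll[m0] = log_expit(z1[m0])
    d1[m0] = 1.0 - F1[m0]

    m2 = y == 2
    ll[m2] = log_expit(-z2[m2])
    d2[m2] = -F2[m2]

    m1 = y == 1
    diff = np.maximum(F2[m1] - F1[m1], 1e-300)
    ll[m1] = np.log(diff)
    d1[m1] = -F1[m1] * (1.0 - F1[m1]) / diff
    d2[m1] = F2[m1] * (1.0 - F2[m1]) / diff

    # chain rule: z1 = theta1 - x.b ; z2 = theta1 + e^delta - x.b
    g_beta = -(X.T @ (d1 + d2))
    g_theta1 = np.sum(d1 + d2)
    g_delta = np.sum(d2) * np.exp(params[m + 1])
    grad = -np.concatenate([g_beta, [g_theta1, g_delta]])
    return -float(np.sum(ll)), grad


def _start_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = len(y)
    p1 = max(np.mean(y == 0), 1.0 / (n + 2))
    p12 = min(max(np.mean(y <= 1), p1 + 1.0 / (n + 2)), 1.0 - 1.0 / (n + 2))
    theta1 = np.log(p1 / (1 - p1))
    theta2 = np.log(p12 / (1 - p12))
    return np.concatenate(
        [np.zeros(X.shape[1]), [theta1, np.log(max(theta2 - theta1, 1e-3))]]
    )


def fit_ordinal(
    data: PairedDataset,
    ridge: float = 0.0,
    maxiter: int = 500,
    model_id: str | None = None,
) -> OrdinalModel:
    """Maximum-likelihood proportional-odds fit.

    Deterministic given the data; an optional ridge penalty on the slope
    coefficients (off by default) is available for separation pathologies.
    Complete separation leaves ``converged`` False in the metadata with the
    iteration-cap fit still returned.
    """
    X, y = data.X, data.y
    if len(np.unique(y)) < 2:
        raise ValueError("fitting requires at least two distinct stages")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    m = X.shape[1]

    def objective(p: np.ndarray) -> tuple[float, np.ndarray]:
        nll, grad = ordinal_nll(p, X, y)
        if ridge > 0:
            nll += 0.5 * ridge * float(np.sum(p[:m] ** 2))
            grad = grad.copy()
            grad[:m] += ridge * p[:m]
        return nll, grad

    res = minimize(
        objective,
        _start_values(X, y),
        jac=True,
        method="BFGS",
        options={"maxiter": maxiter, "gtol": 1e-8},
    )
    betas, theta1, theta2 = _unpack(res.x, m)
    converged = bool(res.success) or float(np.linalg.norm(res.jac)) < 1e-4
    diagnostic = None
    # diverging parameters mean the likelihood has no interior maximum
    # (complete or quasi-complete separation); the capped fit is returned
    # but flagged
    if max(abs(theta1), abs(theta2), *(abs(b) for b in betas)) > 30.0:
        converged = False
        diagnostic = "diverging parameters: possible complete separation"
    return OrdinalModel(
        model_id=model_id or f"{data.scale}-mle",
        scale=data.scale,
        feature_spec=list(data.feature_spec)
        or [{"name": f"x{i}", "input": f"x{i}", "transform": "identity"} for i in range(m)],
        thetas=[float(theta1), float(theta2)],
        betas=[float(b) for b in betas],
        metadata={
            "n": int(len(y)),
            "log_likelihood": -float(res.fun),
            "converged": converged,
            "n_iter": int(res.nit),
            "ridge": ridge,
            "diagnostic": diagnostic,
        },
    )


def predict_stages(model: OrdinalModel, X: np.ndarray) -> np.ndarray:
    """Vectorized argmax stage indices for a matrix of model features."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    eta = X @ np.asarray(model.betas)
    c1 = expit(model.thetas[0] - eta)
    c2 = expit(model.thetas[1] - eta)
    probs = np.column_stack([c1, c2 - c1, 1.0 - c2])
    return np.argmax(probs, axis=1)


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

@dataclass
class MetricSummary:
    mean: float
    halfwidth: float  # 1.96 * sd / sqrt(k)
    fold_values: list[float]

    @property
    def ci(self) -> tuple[float, float]:
        return (self.mean - self.halfwidth, self.mean + self.halfwidth)


@dataclass
class CVReport:
    """k-fold cross-validation metrics with fold-level 95% intervals."""

    scale: str
    k: int
    seed: int
    n: int
    fold_assignments: np.ndarray  # fold index per row
    per_stage: dict[str, dict[str, MetricSummary]]  # stage -> metric -> summary
    error_rate: MetricSummary  # fold-mean misclassification rate
    squared_stage_distance: MetricSummary  # fold-mean (pred - gold)^2
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        def s(ms: MetricSummary) -> dict[str, Any]:
            return {
                "mean": ms.mean,
                "ci95": list(ms.ci),
                "fold_values": ms.fold_values,
            }

        return {
            "scale": self.scale,
            "k": self.k,
            "seed": self.seed,
            "n": self.n,
            "per_stage": {
                st: {metric: s(ms) for metric, ms in metrics.items()}
                for st, metrics in self.per_stage.items()
            },
            "error_rate": s(self.error_rate),
            "squared_stage_distance": s(self.squared_stage_distance),
            "warnings": self.warnings,
        }


def _summarize(values: list[float], k: int) -> MetricSummary:
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    mean = float(np.mean(finite)) if len(finite) else float("nan")
    if len(finite) >= 2:
        hw = 1.96 * float(np.std(finite, ddof=1)) / np.sqrt(len(finite))
    else:
        hw = 0.0
    return MetricSummary(mean=mean, halfwidth=hw, fold_values=list(arr))


def cross_validate(
    data: PairedDataset,
    k: int = 10,
    seed: int = 0,
    stratified: bool = False,
    ridge: float = 0.0,
    predict_fn: Callable[[np.ndarray, np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    | None = None,
) -> CVReport:
    """Seeded k-fold cross-validation of the proportional-odds classifier.

    Folds are a seeded random partition (sizes differing by at most one),
    optionally stratified by gold stage. Per held-out fold the per-stage
    one-vs-rest accuracy, sensitivity and specificity plus the error rate
    and the squared stage distance are computed; each metric is summarized
    as fold-mean +/- 1.96 * sd / sqrt(k). A fold with no gold instances of
    a stage leaves that fold's sensitivity undefined; it is excluded from
    the stage's mean with a warning.

    ``predict_fn(X_train, y_train, X_test, y_test) -> predictions`` replaces
    the fitted classifier; it exists so the harness itself can be validated
    against degenerate predictors (e.g. a truth oracle).
    """
    n = len(data)
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratified:
        for cls in np.unique(data.y):
            idx = np.flatnonzero(data.y == cls)
            rng.shuffle(idx)
            for fold, chunk in enumerate(np.array_split(idx, k)):
                assignment[chunk] = fold
    else:
        perm = rng.permutation(n)
        for fold, chunk in enumerate(np.array_split(perm, k)):
            assignment[chunk] = fold

    stage_metrics: dict[str, dict[str, list[float]]] = {
        st: {"accuracy": [], "sensitivity": [], "specificity": []} for st in A_STAGES
    }
    err_rates: list[float] = []
    sq_dists: list[float] = []
    warns: list[str] = []

    for fold in range(k):
        test = assignment == fold
        train = ~test
        X_tr, y_tr = data.X[train], data.y[train]
        X_te, y_te = data.X[test], data.y[test]
        if predict_fn is not None:
            pred = np.asarray(predict_fn(X_tr, y_tr, X_te, y_te), dtype=int)
        else:
            model = fit_ordinal(
                PairedDataset(data.scale, X_tr, y_tr, data.feature_spec), ridge=ridge
            )
            pred = predict_stages(model, X_te)
        err_rates.append(float(np.mean(pred != y_te)))
        sq_dists.append(float(np.mean((pred - y_te) ** 2)))
        for s_idx, st in enumerate(A_STAGES):
            true_pos = (y_te == s_idx) & (pred == s_idx)
            true_neg = (y_te != s_idx) & (pred != s_idx)
            stage_metrics[st]["accuracy"].append(
                float(np.mean((pred == s_idx) == (y_te == s_idx)))
            )
            n_pos = int(np.sum(y_te == s_idx))
            n_neg = len(y_te) - n_pos
            if n_pos == 0:
                stage_metrics[st]["sensitivity"].append(float("nan"))
                msg = f"fold {fold}: no gold {st} instances, sensitivity undefined"
                warns.append(msg)
                warnings.warn(msg, stacklevel=2)
            else:
                stage_metrics[st]["sensitivity"].append(float(np.sum(true_pos)) / n_pos)
            if n_neg == 0:
                stage_metrics[st]["specificity"].append(float("nan"))
                warns.append(f"fold {fold}: no gold non-{st}, specificity undefined")
            else:
                stage_metrics[st]["specificity"].append(float(np.sum(true_neg)) / n_neg)

    return CVReport(
        scale=data.scale,
        k=k,
        seed=seed,
        n=n,
        fold_assignments=assignment,
        per_stage={
            st: {metric: _summarize(vals, k) for metric, vals in metrics.items()}
            for st, metrics in stage_metrics.items()
        },
        error_rate=_summarize(err_rates, k),
        squared_stage_distance=_summarize(sq_dists, k),
        warnings=warns,
    )
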