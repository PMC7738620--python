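"""Linear modelling of the orthostatic response and exhaustive subset search.

The stress-recovery status indexed by the orthostatic deltas (delta
mean-RR or delta LnRMSSD) is modelled as a linear combination of up to
eight candidate predictors: three training/physical-condition variables
(weekly km, VO2max, HRmax) and five stage-impact variables (RPE and the
four well-being items).  All 2^m subsets (the empty, intercept-only
model included) are fitted by ordinary least squares and ranked by AIC;
the lowest AIC wins, so at equal fit the smaller model is preferred.

The AIC convention used throughout is the full Gaussian log-likelihood
with the residual variance profiled out and counted as a parameter:

    AIC = n ln(2 pi RSS / n) + n + 2 (p + 1)

where p counts the mean parameters (intercept + predictors).  Any
constant offset in the convention cancels in rankings, which are the
only quantity compared across models.

The module also packages the published predictive equations and a
simple decision rule: a measured delta lower than the model prediction
(beyond a configurable margin) flags a stress-recovery imbalance worse
than perceived.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: The eight candidate predictors of the exhaustive search.
CANDIDATE_PREDICTORS = (
    "training_load",
    "vo2max",
    "hr_max",
    "rpe",
    "perceived_fatigue",
    "doms",
    "sleep_quality",
    "stress",
)


class RankDeficientError(ValueError):
    """The design matrix is rank-deficient (collinear columns)."""


@dataclass(frozen=True)
class LinearModelFit:
    """An OLS fit: coefficients (intercept first), inference, and fit metrics."""

    response_name: str
    predictor_names: tuple[str, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    r2: float
    adj_r2: float
    aic: float
    n: int
    rss: float

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[1 + self.predictor_names.index(name)])

    def predict(self, covariates) -> float | np.ndarray:
        return predict(self, covariates)


@dataclass(frozen=True)
class PublishedModel:
    """A predictive equation exactly as printed, immutable."""

    model_id: str
    response_name: str
    response_units: str
    intercept: float
    coefficients: dict[str, float]
    adj_r2: float
    aic: float
    notes: str = ""

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict(self, covariates) -> float | np.ndarray:
        return predict(self, covariates)

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "response_units": self.response_units,
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "adj_r2": self.adj_r2,
            "aic": self.aic,
            "notes": self.notes,
        }


def published_models() -> dict[str, PublishedModel]:
    """Load the packaged predictive equations (versioned JSON fixture)."""
    text = resources.files("orthohrv").joinpath("data/published_models.json").read_text()
    raw = json.loads(text)
    return {
        model_id: PublishedModel(model_id=model_id, **spec)
        for model_id, spec in raw.items()
    }


def get_published_model(model_id: str) -> PublishedModel:
    models = published_models()
    try:
        return models[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model {model_id!r}; available: {sorted(models)}"
        ) from None


def aic(rss: float, n: int, p_mean_params: int) -> float:
    """Gaussian AIC with profiled variance counted as a parameter.

    Undefined for a perfect fit (rss = 0): the profiled likelihood
    diverges, and a saturated model should never win a ranking by
    default.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rss <= 0:
        raise ValueError("AIC undefined for rss <= 0 (perfect fit)")
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * (p_mean_params + 1)


def _clean_design(
    response: np.ndarray, design: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(response, dtype=float)
    X = design.to_numpy(dtype=float)
    keep = ~np.isnan(y)
    if X.size:
        keep &= ~np.isnan(X).any(axis=1)
    return y[keep], X[keep]


def fit_ols(
    response,
    design: pd.DataFrame | Mapping[str, Sequence[float]] | None = None,
    response_name: str = "y",
) -> LinearModelFit:
    """Ordinary least squares with an always-included intercept.

    Rows with a missing response or predictor value are dropped listwise.
    Standard errors use the unbiased residual variance; p-values are
    two-sided t tests.  A rank-deficient design raises
    :class:`RankDeficientError` naming the collinear columns.
    """
    if design is None:
        design = pd.DataFrame(index=range(len(response)))
    elif not isinstance(design, pd.DataFrame):
        design = pd.DataFrame(design)
    names = tuple(str(c) for c in design.columns)
    y, X = _clean_design(response, design)
    n = y.size
    p = len(names)
    if n < p + 2:
        raise ValueError(
            f"need more observations than parameters: n={n}, predictors={p}"
        )
    Xd = np.column_stack([np.ones(n), X]) if p else np.ones((n, 1))
    beta, _, rank, _ = np.linalg.lstsq(Xd, y, rcond=None)
    if rank < p + 1:
        raise RankDeficientError(
            f"design matrix is rank-deficient ({rank} < {p + 1}); "
            f"collinear candidates among columns {_collinear_columns(design)}"
        )
    resid = y - Xd @ beta
    rss = float(resid @ resid)
    dof = n - p - 1
    sigma2 = rss / dof if dof > 0 else float("nan")
    xtx_inv = np.linalg.inv(Xd.T @ Xd)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    adj_r2 = (
        1.0 - (1.0 - r2) * (n - 1) / dof if tss > 0 and dof > 0 else float("nan")
    )
    model_aic = aic(rss, n, p + 1) if rss > 0 else float("-inf")
    return LinearModelFit(
        response_name=response_name,
        predictor_names=names,
        coefficients=beta,
        standard_errors=se,
        p_values=pvals,
        r2=r2,
        adj_r2=adj_r2,
        aic=model_aic,
        n=n,
        rss=rss,
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Heuristic identification of the columns driving rank deficiency."""
    suspects = [c for c in design.columns if design[c].nunique(dropna=True) <= 1]
    cols = list(design.columns)
    corr = design.corr().abs()
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if corr.loc[a, b] > 1 - 1e-10:
                suspects.extend([a, b])
    return sorted(set(str(s) for s in suspects)) or [str(c) for c in cols]


@dataclass(frozen=True)
class ModelTable:
    """All subset fits for one response, sorted ascending by AIC.

    Ties break toward fewer predictors, then lexicographic subset — a
    deterministic order that is invariant under any constant shift of
    the AIC convention.
    """

    response_name: str
    candidates: tuple[str, ...]
    fits: tuple[LinearModelFit, ...]

    def __len__(self) -> int:
        return len(self.fits)

    @property
    def best(self) -> LinearModelFit:
        return self.fits[0]

    def to_frame(self, top: int | None = None) -> pd.DataFrame:
        rows = []
        fits = self.fits if top is None else self.fits[:top]
        for rank, f in enumerate(fits, start=1):
            coef_txt = ";".join(
                f"{name}={value:.6g}"
                for name, value in zip(("intercept",) + f.predictor_names, f.coefficients)
            )
            pval_txt = ";".join(
                f"{name}={value:.4g}"
                for name, value in zip(("intercept",) + f.predictor_names, f.p_values)
            )
            rows.append(
                {
                    "rank": rank,
                    "subset": "+".join(f.predictor_names) or "(intercept only)",
                    "n_predictors": len(f.predictor_names),
                    "coefficients": coef_txt,
                    "p_values": pval_txt,
                    "r2": f.r2,
                    "adj_r2": f.adj_r2,
                    "aic": f.aic,
                    "n": f.n,
                }
            )
        return pd.DataFrame(rows)


def best_subset_search(
    cohort: pd.DataFrame,
    response: str,
    candidates: Sequence[str] = CANDIDATE_PREDICTORS,
) -> ModelTable:
    """Fit every predictor subset (2^m models) and rank by AIC.

    The intercept is always included; the empty subset is the
    intercept-only model.  Rows flagged ``rejected`` are excluded, and
    each model drops rows listwise over its own columns.  A candidate
    constant across all usable rows is excluded from the search with a
    warning.
    """
    candidates = list(dict.fromkeys(candidates))
    missing = [c for c in candidates + [response] if c not in cohort.columns]
    if missing:
        raise KeyError(f"unknown column(s): {missing}")
    df = cohort
    if "quality_flag" in df.columns:
        df = df[df["quality_flag"] != "rejected"]
    df = df[df[response].notna()]
    usable = []
    for c in candidates:
        if df[c].nunique(dropna=True) <= 1:
            warnings.warn(
                f"candidate {c!r} is constant across usable rows; "
                "excluded from all subsets",
                stacklevel=2,
            )
        else:
            usable.append(c)
    fits = []
    y_all = df[response].to_numpy(dtype=float)
    for size in range(len(usable) + 1):
        for subset in itertools.combinations(usable, size):
            try:
                fit = fit_ols(y_all, df[list(subset)], response_name=response)
            except RankDeficientError:
                # e.g. more athlete-level covariates than athletes
                warnings.warn(
                    f"subset {subset!r} is rank-deficient on these rows; skipped",
                    stacklevel=2,
                )
                continue
            fits.append(fit)
    fits.sort(key=lambda f: (f.aic, len(f.predictor_names), f.predictor_names))
    return ModelTable(
        response_name=response, candidates=tuple(usable), fits=tuple(fits)
    )


def predict(
    model: LinearModelFit | PublishedModel, covariates
) -> float | np.ndarray:
    """Evaluate a fitted or published linear model on named covariates.

    ``covariates`` may be a mapping of scalars (returns a float) or a
    DataFrame (returns an array).  Every model predictor must be present;
    extra covariates are ignored with a warning.
    """
    if isinstance(model, PublishedModel):
        names = model.predictor_names
        coefs = np.array([model.coefficients[k] for k in names])
        intercept = model.intercept
    else:
        names = model.predictor_names
        coefs = np.asarray(model.coefficients[1:], dtype=float)
        intercept = float(model.coefficients[0])
    if isinstance(covariates, pd.DataFrame):
        keys = list(covariates.columns)
    else:
        keys = list(covariates.keys())
    missing = [k for k in names if k not in keys]
    if missing:
        raise ValueError(f"missing required covariate(s): {missing}")
    extra = [k for k in keys if k not in names]
    if extra:
        warnings.warn(f"ignoring extra covariate(s): {extra}", stacklevel=2)
    if isinstance(covariates, pd.DataFrame):
        X = covariates[list(names)].to_numpy(dtype=float)
        return intercept + X @ coefs
    values = np.array([float(covariates[k]) for k in names])
    return float(intercept + values @ coefs)


def flag_recovery(
    measured_delta_rr: float, predicted_delta_rr: float, margin: float = 0.0
) -> str:
    """Classify a session: ``imbalance`` iff measured < predicted - margin.

    A measured orthostatic delta clearly below the model's expectation
    indicates a stress-recovery imbalance worse than the athlete
    perceives; the margin (e.g. a multiple of the model's residual SD)
    absorbs measurement noise.
    """
    if margin < 0:
        raise ValueError("margin must be non-negative")
    return (
        "imbalance"
        if measured_delta_rr < predicted_delta_rr - margin
        else "balanced"
    )
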