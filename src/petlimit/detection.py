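"""Lower limit of detection and detection-probability modelling.

The detection chain has four stages:

1. ordinary least-squares regression of CNR on specific activity and on
   cell number (:func:`fit_line`);
2. a noise-derived CNR threshold — either the upper 95 % confidence bound
   of the mean CNR response at vanishing specific activity (``ci95_upper``)
   or the classical Rose criterion CNR = 5 (``rose``) — inverted through
   both regressions to give the lower limit of detection in cells and in
   kBq/10⁶ cells (:func:`estimate_lld`);
3. binary detectability (CNR >= 5) summarised by a binomial logistic model
   of detection probability versus cell number (:func:`fit_logistic`);
4. a non-specific-background simulation that re-evaluates CNR when the
   background is a fraction f = 0.10 ... 0.80 of each well's concentration,
   with Poisson-scaled noise sigma_b = sqrt(k * mu_b), and refits the
   logistic model per fraction (:func:`simulate_background_levels`,
   :func:`detection_vs_background`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    InestimableError,
    NoFiniteLLDError,
    SingularFitError,
    ValidationError,
)

__all__ = [
    "RegressionFit",
    "LLDResult",
    "DetectionCurve",
    "ROSE_CNR_THRESHOLD",
    "DEFAULT_BACKGROUND_FRACTIONS",
    "fit_line",
    "estimate_lld",
    "rose_classify",
    "fit_logistic",
    "detection_probability",
    "cells_at_probability",
    "simulate_background_levels",
    "detection_vs_background",
]

#: Rose criterion: a signal is reliably visible when CNR >= 5.
ROSE_CNR_THRESHOLD = 5.0

#: Background fractions of the well concentration used in the non-specific
#: background simulation: 10-80 % in steps of 10 %.
DEFAULT_BACKGROUND_FRACTIONS = tuple(np.round(np.arange(0.1, 0.81, 0.1), 2))


@dataclass
class RegressionFit:
    """OLS fit of a straight line with mean-response confidence intervals."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    residual_sd: float
    n: int
    _result: object = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def mean_ci(self, x, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Two-sided (1-alpha) CI of the mean response at predictor value x,
        from the t distribution with n-2 degrees of freedom."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        X = sm.add_constant(x, has_constant="add")
        pred = self._result.get_prediction(X)
        ci = pred.conf_int(alpha=alpha)
        return ci[:, 0], ci[:, 1]


def fit_line(x, y) -> RegressionFit:
    """Ordinary least squares of y on x with n >= 3 and non-constant x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise SingularFitError("need at least 3 points for a line with CIs")
    if np.ptp(x) == 0:
        raise SingularFitError("predictor values are all equal")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.scale))
    return RegressionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        slope_se=float(res.bse[1]),
        intercept_se=float(res.bse[0]),
        residual_sd=resid_sd,
        n=int(x.size),
        _result=res,
    )


@dataclass
class LLDResult:
    """Lower limit of detection in cell number and specific activity."""

    cnr_threshold: float
    lld_cells: float
    lld_specific_activity: float
    rule: str
    fit_cnr_vs_sa: RegressionFit = field(repr=False, default=None)
    fit_cnr_vs_cells: RegressionFit = field(repr=False, default=None)


def _invert_threshold(fit: RegressionFit, threshold: float, what: str) -> float:
    if fit.slope <= 0:
        raise NoFiniteLLDError(
            f"non-positive slope in the CNR vs {what} regression; no finite LLD"
        )
    return (threshold - fit.intercept) / fit.slope


def estimate_lld(
    wells: pd.DataFrame,
    rule: str = "ci95_upper",
    lld_ci_at: float = 0.0,
    alpha: float = 0.05,
) -> LLDResult:
    """Estimate the lower limit of detection from a well table.

    ``wells`` needs columns ``cnr``, ``cell_number``,
    ``specific_activity_kBq_per_1e6`` and optionally ``qc_excluded``
    (flagged rows are dropped).  The procedure:

    1. regress CNR on specific activity (all included wells);
    2. take the CNR threshold — for ``rule="ci95_upper"`` the upper bound
       of the 95 % CI of the mean CNR response evaluated at
       SA = ``lld_ci_at`` (default 0, the most conservative reading:
       the largest CNR plausibly produced at vanishing label);
       for ``rule="rose"`` the fixed Rose value CNR = 5;
    3. solve threshold = intercept + slope x cells on the CNR vs cell
       number regression for the LLD in cells;
    4. solve the same threshold on the CNR vs SA regression for the LLD
       in specific activity.
    """
    if rule not in ("ci95_upper", "rose"):
        raise ValidationError(f"unknown LLD rule {rule!r}")
    df = wells
    if "qc_excluded" in df.columns:
        df = df[~df["qc_excluded"].astype(bool)]
    if len(df) < 3:
        raise SingularFitError("need >= 3 included wells to estimate an LLD")
    sa = df["specific_activity_kBq_per_1e6"].to_numpy(dtype=float)
    cells = df["cell_number"].to_numpy(dtype=float)
    y = df["cnr"].to_numpy(dtype=float)
    fit_sa = fit_line(sa, y)
    fit_cells = fit_line(cells, y)
    if rule == "ci95_upper":
        _, upper = fit_sa.mean_ci(lld_ci_at, alpha=alpha)
        threshold = float(upper[0])
    else:
        threshold = ROSE_CNR_THRESHOLD
    lld_cells = _invert_threshold(fit_cells, threshold, "cell number")
    lld_sa = _invert_threshold(fit_sa, threshold, "specific activity")
    return LLDResult(
        cnr_threshold=threshold,
        lld_cells=lld_cells,
        lld_specific_activity=lld_sa,
        rule=rule,
        fit_cnr_vs_sa=fit_sa,
        fit_cnr_vs_cells=fit_cells,
    )


def rose_classify(cnr_value, threshold: float = ROSE_CNR_THRESHOLD):
    """Rose-criterion detectability: detected iff CNR >= threshold
    (boundary inclusive)."""
    arr = np.asarray(cnr_value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("CNR values must be finite")
    out = arr >= threshold
    return bool(out) if np.isscalar(cnr_value) or arr.ndim == 0 else out


@dataclass
class DetectionCurve:
    """Logistic detection-probability model
    p(x) = 1 / (1 + exp(-(beta0 + beta1 x))) with x the cell number."""

    beta0: float
    beta1: float
    cov: np.ndarray = field(repr=False, default=None)
    n: int = 0
    ridge_fallback: bool = False  # True when separation forced a penalized fit


def fit_logistic(cell_numbers, detected, ridge_alpha: float = 1e-4) -> DetectionCurve:
    """Maximum-likelihood binomial logistic regression of detection on cell
    number.

    On complete (or quasi-) separation the unpenalized MLE diverges; the fit
    then falls back to a small L2 (ridge) penalty and flags the result via
    ``ridge_fallback``.  Single-class inputs are inestimable.
    """
    x = np.asarray(cell_numbers, dtype=float)
    d = np.asarray(detected).astype(float)
    if x.size != d.size:
        raise ValidationError("cell_numbers and detected must have equal length")
    if d.min() == d.max():
        raise InestimableError(
            "logistic fit needs both detected and undetected observations"
        )
    X = sm.add_constant(x)
    model = sm.Logit(d, X)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        params_ok = np.all(np.isfinite(res.params)) and np.all(
            np.isfinite(np.diag(res.cov_params()))
        )
        separated = np.all(np.abs(res.predict(X) - d) < 1e-8)
        if converged and params_ok and not separated:
            return DetectionCurve(
                beta0=float(res.params[0]),
                beta1=float(res.params[1]),
                cov=np.asarray(res.cov_params()),
                n=int(x.size),
            )
    except Exception:
        pass
    # Separation fallback: fixed small ridge penalty, flagged, never silent.
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit_regularized(
            alpha=ridge_alpha, L1_wt=0.0, disp=0, maxiter=500
        )
    return DetectionCurve(
        beta0=float(res.params[0]),
        beta1=float(res.params[1]),
        cov=None,
        n=int(x.size),
        ridge_fallback=True,
    )


def detection_probability(curve: DetectionCurve, x) -> np.ndarray | float:
    """Logistic detection probability at cell number x, strictly in (0, 1)."""
    eta = curve.beta0 + curve.beta1 * np.asarray(x, dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    # keep the open interval even at extreme linear predictors
    p = np.clip(p, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return float(p) if np.ndim(x) == 0 else p


def cells_at_probability(curve: DetectionCurve, p: float) -> float:
    """Cell number at which the fitted detection probability equals p:
    x = (logit(p) - beta0) / beta1, the exact inverse of
    :func:`detection_probability`."""
    if not (0.0 < p < 1.0):
        raise ValidationError("p must be strictly between 0 and 1")
    if curve.beta1 == 0:
        raise NoFiniteLLDError("beta1 = 0: detection probability is flat in x")
    return (np.log(p / (1.0 - p)) - curve.beta0) / curve.beta1


def simulate_background_levels(
    wells: pd.DataFrame,
    fractions=DEFAULT_BACKGROUND_FRACTIONS,
    k: float = 1.0,
    cnr_threshold: float = ROSE_CNR_THRESHOLD,
) -> pd.DataFrame:
    """Simulate non-specific background at fractions of each well's signal.

    For every included well (``mu_w`` > 0, not QC-excluded) and every
    fraction f the background mean is mu_b = f * mu_well and its noise is
    Poisson-scaled, sigma_b = sqrt(k * mu_b) with calibration constant k
    (variance of a voxel value per unit mean).  The CNR is recomputed as
    (mu_well - mu_b) / sigma_b and classified by the Rose criterion.  The
    output has exactly ``n_wells x n_fractions`` rows.
    """
    if k <= 0:
        raise ValidationError("Poisson calibration constant k must be > 0")
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions <= 0) | (fractions > 1)):
        raise ValidationError("background fractions must lie in (0, 1]")
    df = wells
    if "qc_excluded" in df.columns:
        df = df[~df["qc_excluded"].astype(bool)]
    mu = df["mu_w"].to_numpy(dtype=float)
    if np.any(mu <= 0):
        raise ValidationError("all included wells must have mu_w > 0")
    rows = []
    for _, rec in df.iterrows():
        for f in fractions:
            mu_b = f * rec["mu_w"]
            sigma_b = float(np.sqrt(k * mu_b))
            value = (rec["mu_w"] - mu_b) / sigma_b
            rows.append(
                {
                    "well_id": rec["well_id"],
                    "cell_number": rec.get("cell_number", np.nan),
                    "background_fraction": float(f),
                    "mu_w": rec["mu_w"],
                    "mu_b": mu_b,
                    "sigma_b": sigma_b,
                    "cnr": value,
                    "detected": bool(value >= cnr_threshold),
                }
            )
    return pd.DataFrame(rows)


def detection_vs_background(
    background_set: pd.DataFrame, p: float = 0.9
) -> pd.DataFrame:
    """Fit one logistic detection curve per background fraction.

    Returns a table with, per fraction: the logistic coefficients, the cell
    number at detection probability ``p`` (the 90 %-point by default), and
    flags for ridge fallback or inestimable (single-class) fractions.
    Single-class fractions carry NaN coefficients but still bound the
    p-point: if every well is detected it lies at or below the smallest
    observed cell number (``bound = "upper"``), if none is detected at or
    above the largest (``bound = "lower"``); ``cells_at_p_bound`` holds the
    estimate or that bound.
    """
    rows = []
    for f, grp in background_set.groupby("background_fraction"):
        row = {
            "background_fraction": float(f),
            "n": int(len(grp)),
            "n_detected": int(grp["detected"].sum()),
        }
        try:
            curve = fit_logistic(grp["cell_number"], grp["detected"])
            if curve.beta1 <= 0:
                raise InestimableError("non-positive slope in per-fraction fit")
            cp = cells_at_probability(curve, p)
            row.update(
                beta0=curve.beta0,
                beta1=curve.beta1,
                cells_at_p=cp,
                cells_at_p_bound=cp,
                bound="estimate",
                ridge_fallback=curve.ridge_fallback,
                estimable=True,
            )
        except InestimableError:
            all_detected = bool(grp["detected"].all())
            none_detected = bool(~grp["detected"].any())
            if all_detected:
                bound_value, bound = float(grp["cell_number"].min()), "upper"
            elif none_detected:
                bound_value, bound = float(grp["cell_number"].max()), "lower"
            else:  # mixed classes but degenerate fit
                bound_value, bound = np.nan, "degenerate"
            row.update(
                beta0=np.nan,
                beta1=np.nan,
                cells_at_p=np.nan,
                cells_at_p_bound=bound_value,
                bound=bound,
                ridge_fallback=False,
                estimable=False,
            )
        rows.append(row)
    return pd.DataFrame(rows).sort_values("background_fraction").reset_index(drop=True)
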