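"""Recovery coefficients and the log-linear partial-volume model.

The recovery coefficient (RC) of a well is the background-corrected image
activity divided by the known (well-counter) activity,

    RC = (measured_well - measured_background) / known_well,

with the known background fixed at 0 kBq.  RC < 1 reflects partial-volume
signal loss for objects small relative to the scanner resolution.  Across
wells, RC follows an approximately logarithmic law in the product of cell
density CD (10⁶ cells/mL) and specific activity SA (kBq/10⁶ cells) — CD·SA
is the activity concentration of the suspension in kBq/mL:

    RC_ij = a * ln(CD_ij * SA_ij) + gamma0 + u_i + eps_ij

with a shared slope a, population intercept gamma0 and a per-scanner random
intercept u_i.  The natural logarithm is used throughout; inverting the
fitted law at a target RC gives the cell density required for a given
quantification accuracy (``density_for_rc``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import NoFiniteLLDError, UndefinedRCError, ValidationError

__all__ = [
    "RCModelFit",
    "recovery_coefficient",
    "fit_rc_model",
    "predict_rc",
    "density_for_rc",
]


def recovery_coefficient(
    measured_well_kbq: float,
    measured_background_kbq: float,
    known_well_kbq: float,
) -> float:
    """RC = (measured_well - measured_background) / known_well.

    ``measured`` activities come from same-size image VOIs on the well and
    background; ``known`` is the well-counter truth (known background = 0).
    """
    if known_well_kbq <= 0:
        raise UndefinedRCError("known well activity must be > 0 for a defined RC")
    return (measured_well_kbq - measured_background_kbq) / known_well_kbq


@dataclass
class RCModelFit:
    """Fitted log-linear recovery model."""

    slope: float  # shared fixed-effect slope a
    intercept: float  # population intercept gamma0
    scanner_offsets: dict[str, float] = field(default_factory=dict)  # random u_i
    residual_sd: float = float("nan")
    n: int = 0
    method: str = "mixedlm"  # or "shrunken_intercepts" / "ols" fallback
    warnings_: list[str] = field(default_factory=list)


def _check_domain(cd, sa) -> np.ndarray:
    cd = np.asarray(cd, dtype=float)
    sa = np.asarray(sa, dtype=float)
    prod = cd * sa
    if np.any(prod <= 0):
        raise ValidationError("CD * SA must be > 0 for the logarithmic model")
    return prod


def fit_rc_model(observations: pd.DataFrame, reml: bool = False) -> RCModelFit:
    """Fit RC = a*ln(CD*SA) + gamma0 + u_i + eps over wells and scanners.

    ``observations`` needs columns ``rc``, ``cell_density``,
    ``specific_activity`` and ``scanner``.  The model is a linear
    mixed-effects fit (ML by default) with a random intercept per scanner.
    With only two scanner groups the variance component is weakly
    identified; if the mixed fit fails to converge the function falls back
    to pooled OLS plus shrunken per-scanner intercept deviations and
    records that in ``method``.  With a single scanner the model degrades
    to ordinary regression with a warning flag.
    """
    req = {"rc", "cell_density", "specific_activity", "scanner"}
    missing = req - set(observations.columns)
    if missing:
        raise ValidationError(f"observations missing columns: {sorted(missing)}")
    prod = _check_domain(
        observations["cell_density"], observations["specific_activity"]
    )
    x = np.log(prod)
    y = observations["rc"].to_numpy(dtype=float)
    groups = observations["scanner"].astype(str).to_numpy()
    uniq = sorted(set(groups))
    notes: list[str] = []

    counts = pd.Series(groups).value_counts()
    if len(uniq) >= 2 and counts.min() < 3:
        raise ValidationError("need >= 3 observations per scanner")

    X = sm.add_constant(x)
    if len(uniq) < 2:
        res = sm.OLS(y, X).fit()
        notes.append("single scanner group: ordinary regression, no random effects")
        return RCModelFit(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            scanner_offsets={uniq[0]: 0.0} if uniq else {},
            residual_sd=float(np.sqrt(res.scale)),
            n=len(y),
            method="ols",
            warnings_=notes,
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            md = sm.MixedLM(y, X, groups=groups)
            res = md.fit(reml=reml, method="lbfgs")
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError("non-finite mixed-model parameters")
        offsets = {g: float(res.random_effects[g].iloc[0]) for g in uniq}
        return RCModelFit(
            slope=float(res.fe_params[1]),
            intercept=float(res.fe_params[0]),
            scanner_offsets=offsets,
            residual_sd=float(np.sqrt(res.scale)),
            n=len(y),
            method="mixedlm",
            warnings_=notes,
        )
    except Exception as exc:
        notes.append(f"mixed model failed ({exc}); shrunken-intercept fallback")
    # Fallback: pooled OLS for (a, gamma0); per-scanner intercept deviations
    # shrunk toward zero by their estimation variance (empirical-Bayes style).
    res = sm.OLS(y, X).fit()
    resid = y - res.predict(X)
    sigma2 = float(res.scale)
    devs = {}
    for g in uniq:
        m = groups == g
        devs[g] = float(resid[m].mean())
    tau2 = max(np.mean([d**2 for d in devs.values()]) - sigma2 / max(counts.min(), 1), 0.0)
    offsets = {}
    for g in uniq:
        n_g = int((groups == g).sum())
        shrink = tau2 / (tau2 + sigma2 / n_g) if (tau2 + sigma2 / n_g) > 0 else 0.0
        offsets[g] = shrink * devs[g]
    return RCModelFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        scanner_offsets=offsets,
        residual_sd=float(np.sqrt(sigma2)),
        n=len(y),
        method="shrunken_intercepts",
        warnings_=notes,
    )


def predict_rc(
    fit: RCModelFit, cell_density, specific_activity, scanner: str | None = None
):
    """Predicted RC at the given CD and SA (population level, or one
    scanner's curve when ``scanner`` is given).  Values are not clipped:
    predictions above 1 or below 0 are returned as-is."""
    prod = _check_domain(cell_density, specific_activity)
    offset = 0.0
    if scanner is not None:
        if scanner not in fit.scanner_offsets:
            raise ValidationError(f"unknown scanner {scanner!r}")
        offset = fit.scanner_offsets[scanner]
    out = fit.slope * np.log(prod) + fit.intercept + offset
    return float(out) if np.ndim(prod) == 0 else out


def density_for_rc(
    fit: RCModelFit,
    target_rc: float,
    specific_activity: float,
    scanner: str | None = None,
) -> float:
    """Cell density (10⁶ cells/mL) at which the fitted model reaches a
    target RC for a given specific activity:
    CD = exp((target - intercept)/a) / SA.  Exact inverse of
    :func:`predict_rc`."""
    if fit.slope <= 0:
        raise NoFiniteLLDError("non-positive slope: RC target cannot be inverted")
    if specific_activity <= 0:
        raise ValidationError("specific_activity must be > 0")
    intercept = fit.intercept
    if scanner is not None:
        if scanner not in fit.scanner_offsets:
            raise ValidationError(f"unknown scanner {scanner!r}")
        intercept += fit.scanner_offsets[scanner]
    return float(np.exp((target_rc - intercept) / fit.slope) / specific_activity)
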