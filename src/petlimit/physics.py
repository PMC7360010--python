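"""⁸⁹Zr decay arithmetic and paired-measurement agreement statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateStatisticsError, ValidationError

__all__ = [
    "IsotopeConstants",
    "ZR89",
    "AgreementReport",
    "decay_factor",
    "decay_correct",
    "pearson",
    "bland_altman",
]


@dataclass(frozen=True)
class IsotopeConstants:
    """Physical constants of a radionuclide (half-life in hours)."""

    half_life_h: float

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValidationError("half_life must be > 0")


#: Zirconium-89, half-life 78.4 h.
ZR89 = IsotopeConstants(half_life_h=78.4)


def decay_factor(elapsed_h, constants: IsotopeConstants = ZR89):
    """Fraction of activity remaining after ``elapsed_h`` hours:
    2^(-t / t_half).  Negative times back-correct.  Multiplicative over
    consecutive intervals."""
    t = np.asarray(elapsed_h, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("elapsed time must be finite")
    out = np.exp2(-t / constants.half_life_h)
    return float(out) if np.ndim(elapsed_h) == 0 else out


def decay_correct(
    activity_kbq,
    t_measured_h,
    t_reference_h,
    constants: IsotopeConstants = ZR89,
):
    """Activity referred to ``t_reference_h``: measured activity divided by
    the decay factor over (t_measured - t_reference).  Exact inverse of
    applying that decay factor."""
    return np.asarray(activity_kbq, dtype=float) / decay_factor(
        np.asarray(t_measured_h, dtype=float) - np.asarray(t_reference_h, dtype=float),
        constants,
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateStatisticsError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticsError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AgreementReport:
    """Bland-Altman agreement: bias and 95 % limits of agreement."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int


def bland_altman(a, b) -> AgreementReport:
    """Bland-Altman analysis of paired measurements.

    Differences d = a - b; bias = mean(d); limits of agreement =
    bias +/- 1.96 * SD(d) (sample SD, n-1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValidationError("paired inputs must have equal length")
    if a.size < 2:
        raise DegenerateStatisticsError("Bland-Altman needs n >= 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementReport(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        sd_diff=sd,
        n=int(d.size),
    )
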