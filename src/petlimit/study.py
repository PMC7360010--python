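"""End-to-end analysis of a (synthetic or measured) detection-limit study.

Glue between the pipeline stages: quantify every scanned plate, then run
per-scanner detection analyses on the 6-well plates (correlation, LLD,
Rose classification, logistic detection curve, non-specific background
simulation) and the recovery-coefficient analysis on the cubic plate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import detection, recovery
from .errors import ValidationError
from .phantom import StudyDataset
from .physics import bland_altman, pearson
from .quantify import quantify_plate

__all__ = [
    "quantify_study",
    "ScannerDetectionReport",
    "analyze_detection",
    "analyze_recovery",
    "analyze_agreement",
    "estimate_poisson_k",
]

QUANT_COLUMNS = ["image_kBq", "cnr", "mu_w", "mu_b", "sigma_b", "voi_ml"]


def quantify_study(dataset: StudyDataset, clip_cnr_at_zero: bool = False) -> pd.DataFrame:
    """Quantify every (plate, scanner) image and merge with the well table.

    Returns the well table with image activity, CNR and background columns
    appended; one row per well per scanner arm.
    """
    frames = []
    for (plate_id, scanner_id), image in dataset.scan_images.items():
        plate = next(p for p in dataset.plates if p.plate_id == plate_id)
        scanner = dataset.scanners[scanner_id]
        table, _bg = quantify_plate(
            image,
            plate,
            psf_margin_mm=scanner.psf_fwhm_mm,
            clip_cnr_at_zero=clip_cnr_at_zero,
        )
        table["scanner"] = scanner_id
        frames.append(table)
    quant = pd.concat(frames, ignore_index=True)
    merged = dataset.well_table.merge(
        quant, on=["well_id", "plate_id", "scanner"], how="left", validate="1:1"
    )
    if merged[QUANT_COLUMNS].isna().any().any():
        raise ValidationError("quantification missing for some wells")
    return merged


def estimate_poisson_k(wells: pd.DataFrame) -> float:
    """Calibration constant k of the Poisson background model,
    sigma^2 = k * mu, estimated from the measured plate backgrounds as the
    mean of sigma_b^2 / mu_b over plates.  Falls back to 1.0 when the
    background mean is zero (no measurable background)."""
    per_plate = wells.drop_duplicates("plate_id")[["mu_b", "sigma_b"]]
    mu = per_plate["mu_b"].to_numpy(dtype=float)
    sd = per_plate["sigma_b"].to_numpy(dtype=float)
    ok = mu > 0
    if not ok.any():
        return 1.0
    return float(np.mean(sd[ok] ** 2 / mu[ok]))


@dataclass
class ScannerDetectionReport:
    """Detection analysis of the 6-well plates for one scanner arm."""

    scanner: str
    n_wells: int
    n_included: int
    pearson_image_vs_counter: tuple[float, float]
    pearson_cnr_vs_counter: tuple[float, float]
    cnr_range: tuple[float, float]
    lld: detection.LLDResult
    lld_rose: detection.LLDResult
    detection_curve: detection.DetectionCurve
    prob_at_lld: float
    poisson_k: float
    background_set: pd.DataFrame = field(repr=False, default=None)
    background_curves: pd.DataFrame = field(repr=False, default=None)


def analyze_detection(
    wells: pd.DataFrame,
    scanner: str,
    fractions=detection.DEFAULT_BACKGROUND_FRACTIONS,
    poisson_k: float | None = None,
) -> ScannerDetectionReport:
    """Run the full detection chain for one scanner's 6-well plates.

    Stages: Pearson correlations of image activity and CNR against the
    well-counter truth; LLD under both the ci95_upper and the Rose rule;
    Rose classification and the logistic detection-probability fit; the
    detection probability evaluated at the estimated LLD cell number; and
    the eight-fraction non-specific-background simulation with per-fraction
    logistic refits.
    """
    df = wells[(wells["scanner"] == scanner) & (wells["layout"] == "six_well")]
    if df.empty:
        raise ValidationError(f"no six-well rows for scanner {scanner!r}")
    inc = df[~df["qc_excluded"].astype(bool)]
    lld = detection.estimate_lld(inc, rule="ci95_upper")
    lld_rose = detection.estimate_lld(inc, rule="rose")
    detected = detection.rose_classify(inc["cnr"].to_numpy())
    curve = detection.fit_logistic(inc["cell_number"].to_numpy(), detected)
    prob_at_lld = detection.detection_probability(curve, lld.lld_cells)
    k = poisson_k if poisson_k is not None else estimate_poisson_k(inc)
    # The simulated non-specific background *replaces* the ambient plate
    # background, so the well term fed to the simulation is the
    # ambient-corrected well concentration, not the raw VOI mean.
    net = inc.copy()
    net["mu_w"] = inc["mu_w"] - inc["mu_b"]
    bg_set = detection.simulate_background_levels(net, fractions=fractions, k=k)
    bg_curves = detection.detection_vs_background(bg_set, p=0.9)
    return ScannerDetectionReport(
        scanner=scanner,
        n_wells=int(len(df)),
        n_included=int(len(inc)),
        pearson_image_vs_counter=pearson(inc["counter_kBq"], inc["image_kBq"]),
        pearson_cnr_vs_counter=pearson(inc["counter_kBq"], inc["cnr"]),
        cnr_range=(float(inc["cnr"].min()), float(inc["cnr"].max())),
        lld=lld,
        lld_rose=lld_rose,
        detection_curve=curve,
        prob_at_lld=float(prob_at_lld),
        poisson_k=k,
        background_set=bg_set,
        background_curves=bg_curves,
    )


def rc_observations(wells: pd.DataFrame) -> pd.DataFrame:
    """Build recovery-coefficient observations from the cubic-plate wells.

    The background term is the mean background concentration times the well
    VOI volume (a same-size background VOI).  Wells with zero counter
    activity are dropped (RC undefined)."""
    df = wells[wells["layout"] == "cubic_3x3"].copy()
    if df.empty:
        raise ValidationError("no cubic-plate rows in the well table")
    df = df[df["counter_kBq"] > 0]
    measured_bg = df["mu_b"] * df["voi_ml"]
    df["rc"] = [
        recovery.recovery_coefficient(m, b, k)
        for m, b, k in zip(df["image_kBq"], measured_bg, df["counter_kBq"])
    ]
    # cell density of a 1 cm^3 cubic well, in 1e6 cells/mL
    df["cell_density"] = df["cell_number"] / (1e6 * df["voi_ml"])
    df["specific_activity"] = df["specific_activity_kBq_per_1e6"]
    return df


def analyze_recovery(
    wells: pd.DataFrame,
    target_rc: float = 1.0,
    at_specific_activity: float | None = None,
) -> dict:
    """Fit the log-linear RC model to the cubic-plate data and invert it.

    Returns the fitted coefficients, per-scanner offsets and — when
    ``at_specific_activity`` is given — the cell density required to reach
    ``target_rc`` at that specific activity.
    """
    obs = rc_observations(wells)
    fit = recovery.fit_rc_model(obs)
    out = {
        "fit": fit,
        "observations": obs,
        "slope": fit.slope,
        "intercept": fit.intercept,
        "scanner_offsets": dict(fit.scanner_offsets),
    }
    if at_specific_activity is not None:
        out["target_rc"] = target_rc
        out["at_specific_activity"] = at_specific_activity
        if fit.slope > 0:
            out["density_at_target"] = recovery.density_for_rc(
                fit, target_rc, at_specific_activity
            )
        else:
            out["density_at_target"] = None
            fit.warnings_.append("non-positive slope: RC inversion skipped")
    return out


def analyze_agreement(wells: pd.DataFrame, scanner_a: str, scanner_b: str) -> dict:
    """Bland-Altman agreement of well activity and CNR between two scanner
    arms, paired on (plate_id, well_id) over included six-well wells."""
    df = wells[(wells["layout"] == "six_well") & (~wells["qc_excluded"].astype(bool))]
    a = df[df["scanner"] == scanner_a].set_index(["plate_id", "well_id"])
    b = df[df["scanner"] == scanner_b].set_index(["plate_id", "well_id"])
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise ValidationError("need >= 2 paired wells for agreement analysis")
    a, b = a.loc[common], b.loc[common]
    return {
        "n_pairs": int(len(common)),
        "activity": bland_altman(a["image_kBq"], b["image_kBq"]),
        "cnr": bland_altman(a["cnr"], b["cnr"]),
    }
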