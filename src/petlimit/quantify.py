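"""Volume-of-interest quantification and the CNR detectability statistic.

A well's total image activity is the mean concentration over its VOI times
the VOI volume; detectability is expressed as a contrast-to-noise ratio

    CNR = (mu_well - mu_background) / sigma_background

where the background mean and standard deviation are pooled over the voxel
values of the background VOIs (empty wells on a 6-well plate; margin regions
on the cubic plate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    DegenerateStatisticsError,
    GeometryError,
    UndefinedCNRError,
)
from .image import ActivityImage
from .phantom import Cube, Cylinder, PlateSpec, Shape, _shape_membership

__all__ = [
    "VOI",
    "WellMeasurement",
    "BackgroundEstimate",
    "make_voi",
    "voi_total_activity",
    "background_stats",
    "cnr",
    "quantify_plate",
]


@dataclass
class VOI:
    """A voxel membership set on a specific image grid."""

    shape: Shape
    center: tuple[float, float, float]
    mask: np.ndarray  # boolean, same shape as the target image

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def volume_ml(self, image: ActivityImage) -> float:
        return self.n_voxels * image.voxel_volume_ml


@dataclass
class WellMeasurement:
    well_id: str
    total_activity_kbq: float
    mean_concentration: float  # mu_well, kBq/mL
    voi_volume_ml: float


@dataclass
class BackgroundEstimate:
    mean: float  # mu_background, kBq/mL
    sd: float  # sigma_background, kBq/mL (sample SD, n-1)
    n_voxels: int


def make_voi(shape: Shape, center, image: ActivityImage) -> VOI:
    """Build a VOI of the given shape at a world-coordinate center.

    Cylinders are stacks of circular discs along the plate-normal (z) axis;
    cubes are axis-aligned.  Membership uses voxel centers.  An empty
    membership set (center outside the image, or shape smaller than a voxel)
    is a geometry error.
    """
    mask = _shape_membership(image, shape, center)
    if not mask.any():
        raise GeometryError(
            f"VOI at {tuple(center)} contains no voxel centers on this grid"
        )
    return VOI(shape=shape, center=tuple(center), mask=mask)


def voi_total_activity(image: ActivityImage, voi: VOI) -> float:
    """Total activity (kBq) in a VOI: mean concentration x VOI volume."""
    values = image.voxels[voi.mask]
    return float(values.mean() * voi.volume_ml(image))


def measure_well(image: ActivityImage, voi: VOI, well_id: str = "") -> WellMeasurement:
    values = image.voxels[voi.mask]
    mu = float(values.mean())
    vol = voi.volume_ml(image)
    return WellMeasurement(well_id, mu * vol, mu, vol)


def background_stats(
    image: ActivityImage, background_vois: list[VOI]
) -> BackgroundEstimate:
    """Pooled background mean and sample SD over all background VOIs."""
    if not background_vois:
        raise DegenerateStatisticsError("need at least one background VOI")
    values = np.concatenate([image.voxels[v.mask].ravel() for v in background_vois])
    if values.size < 2:
        raise DegenerateStatisticsError(
            "background statistics need at least 2 voxels"
        )
    return BackgroundEstimate(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n_voxels=int(values.size),
    )


def cnr(well: WellMeasurement, bg: BackgroundEstimate) -> float:
    """Contrast-to-noise ratio of one well against the plate background.

    Negative values are retained; pass the result through
    ``max(cnr, 0.0)`` (or ``clip_cnr_at_zero`` in :func:`quantify_plate`)
    to reproduce conventions that floor the statistic at zero.
    """
    if bg.sd <= 0:
        raise UndefinedCNRError("sigma_background is zero; CNR undefined")
    return (well.mean_concentration - bg.mean) / bg.sd


def _well_voi_shape(plate: PlateSpec, psf_margin_mm: float) -> Shape:
    """VOI shape per layout: 3.4-cm cylinders over the fill height plus a
    blur margin on 6-well plates; 1 cm³ cubes on the cubic plate."""
    if plate.layout_id == "six_well":
        base = plate.wells[0].shape if plate.wells else Cylinder(34.0, 5.0)
        assert isinstance(base, Cylinder)
        return Cylinder(diameter_mm=34.0, height_mm=base.height_mm + psf_margin_mm)
    return Cube(edge_mm=10.0)


def quantify_plate(
    image: ActivityImage,
    plate: PlateSpec,
    psf_margin_mm: float = 6.0,
    clip_cnr_at_zero: bool = False,
) -> tuple[pd.DataFrame, BackgroundEstimate]:
    """Quantify every loaded well of a plate on one image.

    Returns one row per loaded well with the total image activity (kBq),
    the VOI mean concentration and the CNR, plus the plate-level
    :class:`BackgroundEstimate`.  Background VOIs are placed automatically
    at the plate's background sites (empty wells for 6-well plates; the
    margin between the well grid and the case for the cubic plate).
    """
    voi_shape = _well_voi_shape(plate, psf_margin_mm)
    bg_shape = plate.background_shape or voi_shape
    if plate.layout_id == "six_well" and isinstance(bg_shape, Cylinder):
        bg_shape = Cylinder(bg_shape.diameter_mm, bg_shape.height_mm + psf_margin_mm)
    bg_vois = [make_voi(bg_shape, site, image) for site in plate.background_sites]
    bg = background_stats(image, bg_vois)
    rows = []
    for well in plate.wells:
        voi = make_voi(voi_shape, well.center, image)
        meas = measure_well(image, voi, well.well_id)
        if bg.sd > 0:
            value = cnr(meas, bg)
        else:
            value = float("nan")  # noiseless background: CNR undefined
        if clip_cnr_at_zero and not np.isnan(value):
            value = max(value, 0.0)
        rows.append(
            {
                "well_id": well.well_id,
                "plate_id": plate.plate_id,
                "image_kBq": meas.total_activity_kbq,
                "cnr": value,
                "mu_w": meas.mean_concentration,
                "mu_b": bg.mean,
                "sigma_b": bg.sd,
                "voi_ml": meas.voi_volume_ml,
            }
        )
    columns = [
        "well_id", "plate_id", "image_kBq", "cnr", "mu_w", "mu_b", "sigma_b", "voi_ml",
    ]
    return pd.DataFrame(rows, columns=columns), bg
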