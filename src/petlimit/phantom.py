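"""Digital well-plate phantoms of radiolabeled-cell suspensions.

This module generates the synthetic ground truth the rest of the pipeline is
tested against: plates of wells loaded with ⁸⁹Zr-labeled cells at known cell
numbers and specific activities, rasterized onto a voxel grid, degraded by a
scanner model (Gaussian point-spread blur, uniform background inside the
plate support, Poisson counting noise), and accompanied by well-counter
measurements of each suspension.

Two plate geometries are supported, mirroring the in-vitro study design:

* ``six_well`` — a standard 6-well culture plate; three wells hold labeled
  cell suspensions (nominal 10⁶ / 10⁵ / 10⁴ cells) and the three empty wells
  provide background regions.
* ``cubic_3x3`` — a 3x3 grid of 1 cm³ cubic wells holding cells in a gel
  matrix, used to study cell density; background regions sit in the margin
  between the well grid and the plate case.

Units: activities in kBq, concentrations in kBq/mL, lengths in mm,
specific activity (SA) in kBq per 10⁶ cells, cell density (CD) in
10⁶ cells/mL.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    CapacityError,
    CoverageError,
    ReproducibilityError,
    ValidationError,
)
from .image import ActivityImage

__all__ = [
    "Cylinder",
    "Cube",
    "WellSpec",
    "PlateSpec",
    "ScannerModel",
    "StudyConfig",
    "StudyDataset",
    "build_plate_spec",
    "rasterize_truth",
    "simulate_scan",
    "simulate_well_counter",
    "generate_study",
    "DEFAULT_SCANNERS",
    "CUBIC_PLATE_DEFAULT_LOADING",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# ---------------------------------------------------------------------------
# shapes


@dataclass(frozen=True)
class Cylinder:
    """Upright cylinder (axis along z): diameter and fill height in mm.

    Membership is strict in the radial direction and half-open [lo, hi)
    axially, so an integer-height cylinder on a unit grid spans exactly
    ``height`` slices.
    """

    diameter_mm: float
    height_mm: float

    def contains(self, dx: np.ndarray, dy: np.ndarray, dz: np.ndarray) -> np.ndarray:
        r = self.diameter_mm / 2.0
        h = self.height_mm / 2.0
        return (dx**2 + dy**2 < r**2) & (dz >= -h) & (dz < h)

    def bbox_halfwidths(self) -> tuple[float, float, float]:
        r = self.diameter_mm / 2.0
        return (r, r, self.height_mm / 2.0)

    @property
    def volume_ml(self) -> float:
        r = self.diameter_mm / 2.0
        return float(np.pi * r * r * self.height_mm * 1e-3)


@dataclass(frozen=True)
class Cube:
    """Axis-aligned cube, membership half-open [lo, hi) along each axis so a
    10 mm cube on a 1 mm grid contains exactly 1000 voxel centers (1 mL)."""

    edge_mm: float

    def contains(self, dx: np.ndarray, dy: np.ndarray, dz: np.ndarray) -> np.ndarray:
        h = self.edge_mm / 2.0
        return (
            (dx >= -h) & (dx < h)
            & (dy >= -h) & (dy < h)
            & (dz >= -h) & (dz < h)
        )

    def bbox_halfwidths(self) -> tuple[float, float, float]:
        h = self.edge_mm / 2.0
        return (h, h, h)

    @property
    def volume_ml(self) -> float:
        return float(self.edge_mm**3 * 1e-3)


Shape = Cylinder | Cube


# ---------------------------------------------------------------------------
# wells and plates


@dataclass
class WellSpec:
    """One well: geometry plus its biological/radiochemical ground truth.

    ``fill_fraction`` models how the cells distribute within the well
    volume: the activity occupies the bottom ``fill_fraction`` of the
    shape's height (1.0 = uniform over the whole well).  Sparse suspensions
    in a gel matrix sediment into a thinner layer, which increases
    partial-volume losses — the mechanism that couples recovery to cell
    density.
    """

    well_id: str
    center: tuple[float, float, float]
    shape: Shape
    cell_number: float
    specific_activity: float  # kBq per 1e6 cells
    cell_density: float | None = None  # 1e6 cells/mL (cubic wells)
    qc_excluded: bool = False
    fill_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.cell_number < 0:
            raise ValidationError(f"{self.well_id}: cell_number must be >= 0")
        if self.specific_activity < 0:
            raise ValidationError(f"{self.well_id}: specific_activity must be >= 0")
        if not (0.0 < self.fill_fraction <= 1.0):
            raise ValidationError(f"{self.well_id}: fill_fraction must be in (0, 1]")
        if self.cell_density is None and isinstance(self.shape, Cube):
            # density definition: cells per mL of well volume, in 1e6 cells/mL
            self.cell_density = self.cell_number / (1e6 * self.shape.volume_ml)

    @property
    def truth_kbq(self) -> float:
        """Total well activity: cells x SA / 1e6."""
        return self.cell_number * self.specific_activity / 1e6


# fixed layout coordinates (mm).  Loaded slots are filled first; for the
# six-well plate the remaining empty wells double as background sites.
_SIX_WELL_SLOTS = [
    (20.0, 20.0, 2.5),
    (59.0, 20.0, 2.5),
    (98.0, 20.0, 2.5),
    (20.0, 59.0, 2.5),
    (59.0, 59.0, 2.5),
    (98.0, 59.0, 2.5),
]
_SIX_WELL_SHAPE = Cylinder(diameter_mm=34.0, height_mm=5.0)
_SIX_WELL_BBOX = ((0.0, 118.0), (0.0, 79.0), (-6.0, 12.0))

_CUBIC_SLOTS = [
    (15.0 + 20.0 * c, 15.0 + 20.0 * r, 5.0) for r in range(3) for c in range(3)
]
_CUBIC_SHAPE = Cube(edge_mm=10.0)
_CUBIC_BG_SITES = [(15.0, 75.0, 5.0), (35.0, 75.0, 5.0), (55.0, 75.0, 5.0)]
_CUBIC_BBOX = ((0.0, 70.0), (0.0, 84.0), (-2.0, 12.0))

LAYOUTS = {
    "six_well": dict(slots=_SIX_WELL_SLOTS, shape=_SIX_WELL_SHAPE, bbox=_SIX_WELL_BBOX),
    "cubic_3x3": dict(slots=_CUBIC_SLOTS, shape=_CUBIC_SHAPE, bbox=_CUBIC_BBOX),
}

#: Cell density (1e6 cells/mL) at and above which a cubic gel well is
#: uniformly filled; below it the sedimented activity layer thins
#: proportionally, down to a minimal layer of 10 % of the well height.
SEDIMENT_CD_REF = 1.0
SEDIMENT_MIN_FILL = 0.1


@dataclass
class PlateSpec:
    """One plate: layout id, loaded wells, background sites, support box."""

    layout_id: str
    wells: list[WellSpec]
    plate_id: str = "plate"
    background_sites: list[tuple[float, float, float]] = field(default_factory=list)
    background_shape: Shape | None = None
    support_bbox: tuple[tuple[float, float], ...] = _SIX_WELL_BBOX

    def total_activity_kbq(self) -> float:
        return float(sum(w.truth_kbq for w in self.wells))


def build_plate_spec(
    layout_id: str,
    well_params: Sequence[tuple[float, float]],
    plate_id: str = "plate",
    well_prefix: str | None = None,
) -> PlateSpec:
    """Place wells at the fixed layout coordinates.

    Parameters
    ----------
    layout_id
        ``"six_well"`` or ``"cubic_3x3"``.
    well_params
        ``(cell_number, specific_activity)`` per loaded well, at most the
        layout capacity (6 or 9).  Total well activity in kBq is recorded
        as ``cells x SA / 1e6``.
    """
    if layout_id not in LAYOUTS:
        raise ValidationError(f"unknown layout {layout_id!r}")
    layout = LAYOUTS[layout_id]
    slots = layout["slots"]
    if len(well_params) > len(slots):
        raise CapacityError(
            f"{layout_id} holds at most {len(slots)} wells, got {len(well_params)}"
        )
    prefix = well_prefix if well_prefix is not None else f"{plate_id}-W"
    wells = []
    for i, (cells, sa) in enumerate(well_params):
        well = WellSpec(
            well_id=f"{prefix}{i + 1}",
            center=slots[i],
            shape=layout["shape"],
            cell_number=float(cells),
            specific_activity=float(sa),
        )
        if layout_id == "cubic_3x3":
            # Sparse suspensions sediment in the gel: the activity layer
            # thins with cell density, deepening partial-volume losses.
            well.fill_fraction = float(
                np.clip(well.cell_density / SEDIMENT_CD_REF, SEDIMENT_MIN_FILL, 1.0)
            )
        wells.append(well)
    if layout_id == "six_well":
        bg_sites = [slots[i] for i in range(len(well_params), len(slots))]
        bg_shape = layout["shape"]
    else:
        bg_sites = list(_CUBIC_BG_SITES)
        bg_shape = layout["shape"]
    return PlateSpec(
        layout_id=layout_id,
        wells=wells,
        plate_id=plate_id,
        background_sites=bg_sites,
        background_shape=bg_shape,
        support_bbox=layout["bbox"],
    )


# ---------------------------------------------------------------------------
# rasterization


def _shape_membership(image: ActivityImage, shape: Shape, center) -> np.ndarray:
    """Boolean voxel mask: centers strictly inside the shape."""
    gx, gy, gz = image.index_grid_world()
    dx = (gx - center[0])[:, None, None]
    dy = (gy - center[1])[None, :, None]
    dz = (gz - center[2])[None, None, :]
    return shape.contains(dx, dy, dz)


def _well_membership(image: ActivityImage, well: WellSpec) -> np.ndarray:
    """Voxel mask of the activity-bearing region of a well.

    With ``fill_fraction`` < 1 the activity sits in the bottom slab of the
    well (sedimented cell layer); otherwise it fills the whole shape.
    """
    if well.fill_fraction >= 1.0:
        return _shape_membership(image, well.shape, well.center)
    gx, gy, gz = image.index_grid_world()
    dx = (gx - well.center[0])[:, None, None]
    dy = (gy - well.center[1])[None, :, None]
    dz = (gz - well.center[2])[None, None, :]
    _, _, hz = well.shape.bbox_halfwidths()
    xy = well.shape.contains(dx, dy, np.zeros_like(dz))
    slab = (dz >= -hz) & (dz < -hz + well.fill_fraction * 2.0 * hz)
    return xy & slab


def _grid_for_bbox(bbox, voxel_size: float, padding_mm: float) -> ActivityImage:
    starts, shape = [], []
    for lo, hi in bbox:
        lo, hi = lo - padding_mm, hi + padding_mm
        n = int(np.ceil((hi - lo) / voxel_size)) + 1
        starts.append(lo)
        shape.append(n)
    return ActivityImage(
        np.zeros(shape), (voxel_size,) * 3, tuple(starts)
    )


def rasterize_truth(
    plate: PlateSpec,
    voxel_size: float = 1.0,
    padding_mm: float = 20.0,
    grid: ActivityImage | None = None,
) -> ActivityImage:
    """Rasterize a plate's ground-truth activity onto a voxel grid.

    Each well's total activity is spread uniformly over the voxels whose
    centers fall inside its shape, so the image conserves activity exactly:
    ``sum(image) * voxel_volume == sum(well activities)``.

    A ``grid`` image may be supplied (its values are ignored); otherwise an
    isotropic grid covering the plate support box plus ``padding_mm`` is
    created.  Padding of at least 3x the scanner FWHM keeps later blur
    truncation below 0.1 %.
    """
    if grid is None:
        image = _grid_for_bbox(plate.support_bbox, voxel_size, padding_mm)
    else:
        image = ActivityImage(
            np.zeros(grid.shape), grid.voxel_size, grid.origin
        )
    lo_world = np.asarray(image.origin)
    hi_world = lo_world + (np.asarray(image.shape) - 1) * np.asarray(image.voxel_size)
    vox_vol = image.voxel_volume_ml
    for well in plate.wells:
        half = np.asarray(well.shape.bbox_halfwidths())
        c = np.asarray(well.center)
        if np.any(c - half < lo_world - 0.5) or np.any(c + half > hi_world + 0.5):
            raise CoverageError(f"well {well.well_id} extends outside the grid")
        mask = _well_membership(image, well)
        n_inside = int(mask.sum())
        if n_inside == 0:
            raise CoverageError(f"well {well.well_id} covers no voxel centers")
        image.voxels[mask] += well.truth_kbq / (n_inside * vox_vol)
    image.meta["support_bbox"] = plate.support_bbox
    image.meta["plate_id"] = plate.plate_id
    return image


def _support_mask(image: ActivityImage, bbox) -> np.ndarray:
    gx, gy, gz = image.index_grid_world()
    mx = (gx >= bbox[0][0]) & (gx <= bbox[0][1])
    my = (gy >= bbox[1][0]) & (gy <= bbox[1][1])
    mz = (gz >= bbox[2][0]) & (gz <= bbox[2][1])
    return mx[:, None, None] & my[None, :, None] & mz[None, None, :]


# ---------------------------------------------------------------------------
# scanner model


@dataclass
class ScannerModel:
    """Image-formation parameters of one PET system.

    This is deliberately a phenomenological stand-in for a reconstruction
    chain: a Gaussian point-spread function, a uniform non-zero background
    inside the plate support (mimicking ambient signal on the scanner bed),
    and a single Poisson counting stage whose ``noise_scale`` converts
    concentration to expected counts per voxel.
    """

    scanner_id: str
    psf_fwhm_mm: float = 6.0
    sensitivity_scale: float = 1.0
    background_kbq_ml: float = 0.01
    noise_scale: float | None = 2.5e6  # expected counts per kBq; None = noiseless

    def __post_init__(self) -> None:
        if self.psf_fwhm_mm < 0:
            raise ValidationError("psf_fwhm must be >= 0")
        if self.background_kbq_ml < 0:
            raise ValidationError("background_concentration must be >= 0")
        if self.noise_scale is not None and self.noise_scale <= 0:
            raise ValidationError("noise_scale must be > 0 (or None to disable noise)")

    @property
    def poisson_k(self) -> float | None:
        """Variance-to-mean ratio of voxel concentration implied by the model.

        For expected counts ``c = mu * noise_scale * v`` (v = voxel volume in
        mL), the reconstructed concentration has variance mu / (noise_scale*v),
        i.e. ``sigma^2 = k * mu`` with ``k = 1 / (noise_scale * v)`` at 1 mm³
        voxels.  Returns k for 1 mm³ voxels, or None if noiseless.
        """
        if self.noise_scale is None:
            return None
        return 1.0 / (self.noise_scale * 1e-3)


DEFAULT_SCANNERS = {
    "petct": ScannerModel("petct", psf_fwhm_mm=6.0),
    "petmri": ScannerModel("petmri", psf_fwhm_mm=5.0),
}


def simulate_scan(
    truth: ActivityImage,
    scanner: ScannerModel,
    seed: int | None = None,
    support_bbox=None,
) -> ActivityImage:
    """Form a simulated PET image from a ground-truth activity image.

    Pipeline: (1) Gaussian blur of FWHM ``psf_fwhm_mm`` in continuous
    concentration space; (2) add ``background_kbq_ml`` uniformly inside the
    plate support (the plate bounding box; zero outside, like air around the
    plate on CT); (3) convert to expected counts per voxel via
    ``noise_scale``, draw Poisson, convert back to kBq/mL and apply
    ``sensitivity_scale``.  The same seed always produces the same image.
    """
    if scanner.noise_scale is not None and seed is None:
        raise ReproducibilityError(
            "simulate_scan with Poisson noise enabled requires a seed"
        )
    img = truth.voxels.astype(float)
    if scanner.psf_fwhm_mm > 0:
        sigma = [
            scanner.psf_fwhm_mm * FWHM_TO_SIGMA / v for v in truth.voxel_size
        ]
        img = ndimage.gaussian_filter(img, sigma=sigma, mode="constant", cval=0.0)
    bbox = support_bbox or truth.meta.get("support_bbox")
    if scanner.background_kbq_ml > 0:
        if bbox is not None:
            mask = _support_mask(truth, bbox)
            img = img + scanner.background_kbq_ml * mask
        else:
            img = img + scanner.background_kbq_ml
    if scanner.noise_scale is not None:
        vox_vol = truth.voxel_volume_ml
        rng = np.random.default_rng(seed)
        expected_counts = np.clip(img, 0.0, None) * scanner.noise_scale * vox_vol
        counts = rng.poisson(expected_counts)
        img = counts / (scanner.noise_scale * vox_vol)
    out = ActivityImage(
        img * scanner.sensitivity_scale, truth.voxel_size, truth.origin,
        dict(truth.meta),
    )
    out.meta["scanner"] = scanner.scanner_id
    return out


def simulate_well_counter(
    plate: PlateSpec,
    counter_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Gamma-counter measurement of each well's suspension.

    measured = truth x (1 + eps), eps ~ Normal(0, counter_cv) truncated at
    -1 so measurements stay non-negative.  ``counter_cv = 0`` returns the
    truth exactly.
    """
    if counter_cv < 0:
        raise ValidationError("counter_cv must be >= 0")
    truths = np.array([w.truth_kbq for w in plate.wells])
    if counter_cv == 0 or len(truths) == 0:
        measured = truths.copy()
    else:
        if seed is None:
            raise ReproducibilityError("counter simulation with cv > 0 requires a seed")
        rng = np.random.default_rng(seed)
        eps = np.maximum(rng.normal(0.0, counter_cv, size=len(truths)), -1.0)
        measured = truths * (1.0 + eps)
    return pd.DataFrame(
        {
            "well_id": [w.well_id for w in plate.wells],
            "counter_kBq": measured,
        }
    )


# ---------------------------------------------------------------------------
# whole-study generation


#: Default loading of the 3x3 cubic plate: (cell_number, SA kBq/1e6 cells)
#: spanning low / medium / high label, used when a config does not override it.
CUBIC_PLATE_DEFAULT_LOADING = [
    (1.07e6, 0.67),  # L1
    (1.50e5, 0.42),  # L2
    (6.70e4, 0.14),  # L3
    (8.20e5, 7.23),  # M1
    (3.25e4, 15.41),  # M2
    (3.61e4, 6.61),  # M3
    (3.99e5, 30.63),  # H1
    (1.21e5, 8.47),  # H2
    (6.20e4, 6.60),  # H3
]


@dataclass
class StudyConfig:
    """Parameters of one synthetic detection-limit study.

    Defaults reproduce the design the pipeline analyses: 6 independent
    experiments contributing 12 six-well plates (3 loaded wells each at
    nominal 10⁶/10⁵/10⁴ cells), specific activities log-uniform over
    0.43-31.91 kBq/10⁶ cells, 5 wells flagged by QC, one 3x3 cubic-well
    plate, and every plate scanned by both scanner models.
    """

    n_experiments: int = 6
    plates_per_experiment: int = 2
    wells_per_plate: int = 3
    cell_level_medians: tuple[float, ...] = (1.08e6, 1.45e5, 8.50e4)
    cell_jitter_sigma: float = 0.45  # log-normal sigma around each level median
    sa_range: tuple[float, float] = (0.43, 31.91)
    exclusion_count: int = 5
    counter_cv: float = 0.03
    include_cubic_plate: bool = True
    cubic_loading: tuple[tuple[float, float], ...] = tuple(CUBIC_PLATE_DEFAULT_LOADING)
    voxel_size_mm: float = 1.0
    padding_mm: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_experiments < 1 or self.plates_per_experiment < 1:
            raise ValidationError("need at least one experiment and one plate")
        if not (0 < self.wells_per_plate <= 6):
            raise ValidationError("wells_per_plate must be in 1..6")
        if self.sa_range[0] < 0 or self.sa_range[1] < self.sa_range[0]:
            raise ValidationError("sa_range must be a non-negative interval")
        total = (
            self.n_experiments * self.plates_per_experiment * self.wells_per_plate
        )
        if self.exclusion_count >= total:
            raise ValidationError("exclusion_count must be < total wells")
        if self.counter_cv < 0:
            raise ValidationError("counter_cv must be >= 0")
        if len(self.cell_level_medians) != self.wells_per_plate:
            raise ValidationError(
                "cell_level_medians must provide one level per loaded well"
            )


@dataclass
class StudyDataset:
    """Everything one synthetic study produced."""

    config: StudyConfig
    scanners: dict[str, ScannerModel]
    plates: list[PlateSpec]
    truth_images: dict[str, ActivityImage]
    scan_images: dict[tuple[str, str], ActivityImage]  # (plate_id, scanner_id)
    well_table: pd.DataFrame

    @property
    def six_well_plates(self) -> list[PlateSpec]:
        return [p for p in self.plates if p.layout_id == "six_well"]

    @property
    def cubic_plates(self) -> list[PlateSpec]:
        return [p for p in self.plates if p.layout_id == "cubic_3x3"]


WELL_TABLE_COLUMNS = [
    "well_id",
    "plate_id",
    "scanner",
    "layout",
    "cell_number",
    "specific_activity_kBq_per_1e6",
    "truth_kBq",
    "counter_kBq",
    "qc_excluded",
    "seed",
]


def generate_study(
    config: StudyConfig | None = None,
    scanners: dict[str, ScannerModel] | None = None,
) -> StudyDataset:
    """Generate a full synthetic study: plates, images and well tables.

    Each plate's ground truth is rasterized once and scanned by every
    scanner model with independent noise (emulating a sequential PET/CT
    then PET/MRI session of the same physical plate).  All randomness is a
    pure function of ``config.seed``.
    """
    config = config or StudyConfig()
    config.validate()
    scanners = scanners or {
        k: dataclasses.replace(v) for k, v in DEFAULT_SCANNERS.items()
    }
    root = np.random.SeedSequence(config.seed)
    ss_design, ss_counter, ss_scan = root.spawn(3)
    rng = np.random.default_rng(ss_design)

    plates: list[PlateSpec] = []
    for e in range(config.n_experiments):
        for p in range(config.plates_per_experiment):
            pid = f"E{e + 1}P{p + 1}"
            params = []
            for median in config.cell_level_medians:
                cells = float(
                    np.round(median * rng.lognormal(0.0, config.cell_jitter_sigma))
                )
                lo, hi = config.sa_range
                if hi == lo:
                    sa = float(lo)
                else:
                    sa = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                params.append((cells, sa))
            plates.append(build_plate_spec("six_well", params, plate_id=pid))
    if config.include_cubic_plate:
        plates.append(
            build_plate_spec("cubic_3x3", list(config.cubic_loading), plate_id="CUBE")
        )

    # QC exclusions among the six-well wells, shared across scanner arms
    six_wells = [
        (p.plate_id, w.well_id)
        for p in plates
        if p.layout_id == "six_well"
        for w in p.wells
    ]
    excl_idx = rng.choice(len(six_wells), size=config.exclusion_count, replace=False)
    excluded = {six_wells[i] for i in excl_idx}
    for p in plates:
        for w in p.wells:
            w.qc_excluded = (p.plate_id, w.well_id) in excluded

    counter_seeds = ss_counter.generate_state(len(plates)) % (2**31)
    scan_seed_arr = ss_scan.generate_state(len(plates) * len(scanners)) % (2**31)

    truth_images: dict[str, ActivityImage] = {}
    scan_images: dict[tuple[str, str], ActivityImage] = {}
    rows = []
    scan_i = 0
    for pi, plate in enumerate(plates):
        truth = rasterize_truth(
            plate, voxel_size=config.voxel_size_mm, padding_mm=config.padding_mm
        )
        truth_images[plate.plate_id] = truth
        counter = simulate_well_counter(
            plate, config.counter_cv, seed=int(counter_seeds[pi])
        ).set_index("well_id")["counter_kBq"]
        for scanner_id, scanner in scanners.items():
            seed = int(scan_seed_arr[scan_i])
            scan_i += 1
            scan_images[(plate.plate_id, scanner_id)] = simulate_scan(
                truth, scanner, seed=seed
            )
            for w in plate.wells:
                rows.append(
                    {
                        "well_id": w.well_id,
                        "plate_id": plate.plate_id,
                        "scanner": scanner_id,
                        "layout": plate.layout_id,
                        "cell_number": w.cell_number,
                        "specific_activity_kBq_per_1e6": w.specific_activity,
                        "truth_kBq": w.truth_kbq,
                        "counter_kBq": float(counter[w.well_id]),
                        "qc_excluded": bool(w.qc_excluded),
                        "seed": seed,
                    }
                )
    well_table = pd.DataFrame(rows, columns=WELL_TABLE_COLUMNS)
    return StudyDataset(
        config=config,
        scanners=scanners,
        plates=plates,
        truth_images=truth_images,
        scan_images=scan_images,
        well_table=well_table,
    )
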