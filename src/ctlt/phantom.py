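"""Digital chest phantoms with known air/tissue ground truth.

The phantom emulates the features of a non-contrast chest CT that matter for
densitometry, at reduced resolution:

* two ellipsoidal lungs inside a soft-tissue body envelope (elliptic
  cylinder, +40 HU) with a subcutaneous fat ring (-100 HU);
* lung parenchyma built voxelwise from a known tissue fraction f:
  HU = f * tissue_hu + (1 - f) * air_hu, so tissue/air volumes are exact by
  construction;
* a scatter offset: imaged air defaults to -980 HU rather than the nominal
  -1000 HU, applied to every air-containing structure (parenchymal air,
  trachea, background);
* cylindrical soft-tissue vessels embedded strictly inside the lungs and a
  tracheal air cylinder in the mediastinum;
* a one-voxel partial-volume rim at the lung surface, blending parenchyma
  with the chest wall, so the surface-shell/add-back logic has realistic
  work to do;
* optional additive Gaussian noise, fully determined by the seed;
* paired inspiratory/expiratory states that conserve tissue exactly:
  inspiration scales the lung geometry and dilutes the tissue fraction so
  that f_ins * V_ins = f_exp * V_exp, which makes the inspiratory interior
  mean obey the air-dilution formula identically.

Ground truth (tissue/air volumes, fraction field, structure masks) refers to
the parenchyma: vessels and the partial-volume rim are excluded, mirroring
what the extraction protocol is designed to measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .normative import SHIPPED_MODELS, SubjectRecord, predict
from .air_calibration import PairedScan
from .volume_model import CTVolume, LungMeasurement, RoiSpec, VoxelMask, mask_statistics, roi_mean_hu

__all__ = [
    "GeometryError",
    "PhantomSpec",
    "PhantomTruth",
    "generate",
    "generate_pair",
    "generate_cohort",
    "simulate_paired_cohort",
    "CohortModel",
]


class GeometryError(ValueError):
    """Requested structures do not fit inside the grid/body envelope."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, composition and acquisition parameters of one phantom.

    Units: mm for lengths, HU for attenuations.  ``tissue_fraction`` is the
    uniform parenchymal tissue fraction (normal lung is roughly 0.10-0.15 at
    inspiration); ``true_air_hu`` defaults to -980 (nominal -1000 plus a
    +20 HU scatter offset); ``true_tissue_hu`` to 39.5 (atelectasis
    calibration); ``inspiration_scale`` is the volumetric lung scale factor
    between the expiratory and inspiratory states (about 1.6 in normal
    paired scans).  ``seed`` fully determines the output.
    """

    shape: tuple[int, int, int] = (72, 120, 120)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    lung_semi_axes_mm: tuple[float, float, float] = (70.0, 60.0, 45.0)
    lung_separation_mm: float = 150.0
    tissue_fraction: float = 0.13
    true_air_hu: float = -980.0
    true_tissue_hu: float = 39.5
    vessel_count: int = 3
    vessel_radius_mm: float = 4.0
    vessel_hu: float = 40.0
    trachea_radius_mm: float = 8.0
    wall_hu: float = 40.0
    fat_hu: float = -100.0
    fat_thickness_mm: float = 6.0
    background_hu: float | None = None  # defaults to true_air_hu (imaged air)
    noise_sd: float = 0.0
    seed: int = 0
    inspiration_scale: float = 1.6

    def __post_init__(self) -> None:
        if not (0.0 < self.tissue_fraction < 1.0):
            raise ValueError(f"tissue_fraction must be in (0, 1), got {self.tissue_fraction}")
        if self.inspiration_scale < 1.0:
            raise ValueError(f"inspiration_scale must be >= 1, got {self.inspiration_scale}")
        if self.true_tissue_hu <= self.true_air_hu:
            raise ValueError("true_tissue_hu must exceed true_air_hu")

    @classmethod
    def small(cls, **overrides) -> "PhantomSpec":
        """A coarse, fast variant for cohort simulation and smoke testing."""
        base = dict(
            shape=(48, 84, 84),
            spacing=(3.5, 3.5, 3.5),
            lung_semi_axes_mm=(55.0, 55.0, 40.0),
            lung_separation_mm=140.0,
        )
        base.update(overrides)
        return cls(**base)

    # -- derived geometry (mm; voxel centres at index * spacing) ------------

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def trachea_z_range(self, axes_scale: float = 1.0) -> tuple[float, float]:
        lz = self.extent_mm[0]
        az = self.lung_semi_axes_mm[0] * axes_scale
        cz = 0.52 * lz
        z0 = cz + 0.35 * az
        z1 = min(lz - 2 * self.spacing[0], z0 + max(30.0, 0.8 * az))
        return z0, z1

    def trachea_roi(self) -> RoiSpec:
        """ROI spec for measuring trachea air, clear of the tracheal wall."""
        z0, z1 = self.trachea_z_range()
        k = int(round(((z0 + z1) / 2) / self.spacing[0]))
        _, ly, lx = self.extent_mm
        diameter = min(max(10.0, 1.5 * self.trachea_radius_mm), 25.0)
        return RoiSpec(slice_index=k, center_mm=(ly / 2, lx / 2), diameter_mm=diameter)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one phantom state.

    ``tissue_volume_ml``/``air_volume_ml`` integrate the fraction field over
    the parenchyma (``interior_mask``); ``lung_mask`` is the full lung
    ellipsoids including the partial-volume rim and vessels.
    """

    tissue_volume_ml: float
    air_volume_ml: float
    fraction_field: np.ndarray
    lung_mask: VoxelMask
    interior_mask: VoxelMask
    vessel_mask: VoxelMask
    airway_mask: VoxelMask
    wall_mask: VoxelMask

    @property
    def interior_volume_ml(self) -> float:
        return self.tissue_volume_ml + self.air_volume_ml


def _ellipsoid(coords, center, semi):
    zc, yc, xc = coords
    return (
        ((zc - center[0]) / semi[0]) ** 2
        + ((yc - center[1]) / semi[1]) ** 2
        + ((xc - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _cylinder_z(coords, center_yx, radius, z0, z1):
    zc, yc, xc = coords
    return (
        ((yc - center_yx[0]) ** 2 + (xc - center_yx[1]) ** 2 <= radius**2)
        & (zc >= z0)
        & (zc <= z1)
    )


def generate(
    spec: PhantomSpec,
    _axes_scale: float = 1.0,
    _fraction: float | None = None,
    _noise_key: int = 0,
) -> tuple[CTVolume, PhantomTruth]:
    """Render one phantom state and its ground truth.

    The private parameters are used by :func:`generate_pair` to rescale the
    lung geometry and override the tissue fraction while keeping every other
    aspect (including vessel placement randomness) tied to ``spec.seed``.
    """
    nz, ny, nx = spec.shape
    sz, sy, sx = spec.spacing
    lz, ly, lx = spec.extent_mm
    coords = np.ogrid[0:nz, 0:ny, 0:nx]
    coords = (coords[0] * sz, coords[1] * sy, coords[2] * sx)

    fraction = spec.tissue_fraction if _fraction is None else _fraction
    semi = tuple(a * _axes_scale for a in spec.lung_semi_axes_mm)
    body_semi = (0.45 * ly, 0.47 * lx)
    inner_semi = (body_semi[0] - spec.fat_thickness_mm, body_semi[1] - spec.fat_thickness_mm)
    cy, cx = ly / 2, lx / 2
    cz_lung = 0.52 * lz
    centers = [
        (cz_lung, cy, cx - spec.lung_separation_mm / 2),
        (cz_lung, cy, cx + spec.lung_separation_mm / 2),
    ]

    # geometry validation: lungs inside the grid and the inner body envelope
    for c in centers:
        if c[0] - semi[0] < sz or c[0] + semi[0] > lz - sz:
            raise GeometryError("lung exceeds grid along z")
        if semi[1] > inner_semi[0] - sy or abs(c[2] - cx) + semi[2] > inner_semi[1] - sx:
            raise GeometryError("lung exceeds the body envelope in-plane")
    gap = spec.lung_separation_mm / 2 - semi[2]
    if spec.trachea_radius_mm >= gap:
        raise GeometryError("trachea does not fit between the lungs")

    # body envelope: soft-tissue elliptic cylinder with a fat ring
    yc2 = ((coords[1] - cy) / body_semi[0]) ** 2
    xc2 = ((coords[2] - cx) / body_semi[1]) ** 2
    body = (yc2 + xc2) <= 1.0
    body = np.broadcast_to(body, spec.shape).copy()
    inner = (((coords[1] - cy) / inner_semi[0]) ** 2 + ((coords[2] - cx) / inner_semi[1]) ** 2) <= 1.0
    inner = np.broadcast_to(inner, spec.shape)
    fat = body & ~inner

    background_hu = spec.true_air_hu if spec.background_hu is None else spec.background_hu
    hu = np.full(spec.shape, background_hu, dtype=float)
    hu[body] = spec.wall_hu
    hu[fat] = spec.fat_hu

    # lungs: full ellipsoid, one-voxel-shrunk interior, rim = difference
    full = np.zeros(spec.shape, dtype=bool)
    interior = np.zeros(spec.shape, dtype=bool)
    core = np.zeros(spec.shape, dtype=bool)  # interior shrunk again: vessel territory
    for c in centers:
        full |= _ellipsoid(coords, c, semi)
        interior |= _ellipsoid(coords, c, tuple(a - s for a, s in zip(semi, spec.spacing)))
        core |= _ellipsoid(coords, c, tuple(a - 2 * s for a, s in zip(semi, spec.spacing)))
    rim = full & ~interior

    parenchyma_hu = fraction * spec.true_tissue_hu + (1.0 - fraction) * spec.true_air_hu
    hu[interior] = parenchyma_hu
    hu[rim] = 0.5 * parenchyma_hu + 0.5 * spec.wall_hu

    # vessels: z-aligned cylinders strictly inside the interior
    rng = np.random.default_rng([spec.seed, 7])
    vessel = np.zeros(spec.shape, dtype=bool)
    for c in centers:
        for _ in range(spec.vessel_count):
            oy = rng.uniform(-0.45, 0.45) * semi[1]
            ox = rng.uniform(-0.45, 0.45) * semi[2]
            v = _cylinder_z(
                coords,
                (c[1] + oy, c[2] + ox),
                spec.vessel_radius_mm,
                c[0] - 0.5 * semi[0],
                c[0] + 0.5 * semi[0],
            )
            vessel |= v & core
    hu[vessel] = spec.vessel_hu

    # trachea: air cylinder in the mediastinum, ending below the grid top
    z0, z1 = spec.trachea_z_range(_axes_scale)
    airway = _cylinder_z(coords, (cy, cx), spec.trachea_radius_mm, z0, z1)
    airway = np.broadcast_to(airway, spec.shape) & body
    hu[airway] = spec.true_air_hu

    if spec.noise_sd > 0:
        noise_rng = np.random.default_rng([spec.seed, 11, _noise_key])
        hu = hu + noise_rng.normal(0.0, spec.noise_sd, size=spec.shape)

    parenchyma = interior & ~vessel
    vox_ml = float(np.prod(spec.spacing)) / 1000.0
    fraction_field = np.zeros(spec.shape, dtype=float)
    fraction_field[parenchyma] = fraction
    n_par = int(parenchyma.sum())
    tissue_ml = fraction * n_par * vox_ml
    air_ml = (1.0 - fraction) * n_par * vox_ml
    wall_mask = body & ~fat & ~full & ~airway

    truth = PhantomTruth(
        tissue_volume_ml=tissue_ml,
        air_volume_ml=air_ml,
        fraction_field=fraction_field,
        lung_mask=VoxelMask(full),
        interior_mask=VoxelMask(parenchyma),
        vessel_mask=VoxelMask(vessel),
        airway_mask=VoxelMask(airway),
        wall_mask=VoxelMask(wall_mask),
    )
    return CTVolume(hu, spec.spacing), truth


def generate_pair(
    spec: PhantomSpec,
) -> tuple[tuple[CTVolume, PhantomTruth], tuple[CTVolume, PhantomTruth]]:
    """Expiratory and inspiratory states conserving tissue volume exactly.

    The inspiratory lung axes are scaled by ``inspiration_scale ** (1/3)``
    and the tissue fraction diluted by the realised (discretised) parenchyma
    volume ratio, so ground-truth tissue volume is identical in both states
    and the interior mean HU obeys the dilution formula by construction.
    """
    exp_vol, exp_truth = generate(spec, _noise_key=1)
    scale = spec.inspiration_scale ** (1.0 / 3.0)
    # realise the inspiratory geometry once to learn its parenchyma volume
    _, ins_geom = generate(replace(spec, noise_sd=0.0), _axes_scale=scale)
    f_ins = spec.tissue_fraction * exp_truth.interior_volume_ml / ins_geom.interior_volume_ml
    ins_vol, ins_truth = generate(spec, _axes_scale=scale, _fraction=f_ins, _noise_key=2)
    return (exp_vol, exp_truth), (ins_vol, ins_truth)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortModel:
    """Covariate distributions for synthetic normal cohorts.

    Defaults emulate a normal adult screening population: sex-specific
    height/weight normals (m / kg), a common age distribution, tissue volume
    driven by the pooled height model with lognormal scatter, and a
    per-subject tissue fraction linking tissue to total lung volume.
    """

    male_height: tuple[float, float] = (1.69, 0.06)
    female_height: tuple[float, float] = (1.55, 0.07)
    male_weight: tuple[float, float] = (70.0, 12.5)
    female_weight: tuple[float, float] = (55.6, 11.5)
    age: tuple[float, float] = (62.0, 13.8)
    tissue_lognorm_sd: float = 0.13
    tissue_fraction: tuple[float, float] = (0.13, 0.012)


def _bsa_dubois(height_m: float, weight_kg: float) -> float:
    # Du Bois & Du Bois body-surface-area formula (height in cm)
    return 0.007184 * (height_m * 100) ** 0.725 * weight_kg**0.425


def generate_cohort(
    n: int,
    seed: int = 0,
    model: CohortModel | None = None,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[SubjectRecord, PhantomSpec]]:
    """Sample ``n`` synthetic subjects and the phantom specs realising them.

    Heights and sexes follow the cohort model; each subject's target tissue
    volume is the pooled height model prediction times lognormal noise; the
    phantom spec's lung axes are scaled so the parenchyma volume matches the
    implied total lung volume (tissue / fraction).  Deterministic under
    ``seed``.  Phantom volumes are rendered lazily by the caller.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    model = model or CohortModel()
    base = base_spec or PhantomSpec.small()
    rng = np.random.default_rng([seed, 23])
    height_model = SHIPPED_MODELS[("height_m", "pooled")]

    # parenchyma volume of the base geometry, for axis scaling
    _, base_truth = generate(replace(base, noise_sd=0.0, seed=0))
    base_interior_ml = base_truth.interior_volume_ml

    out: list[tuple[SubjectRecord, PhantomSpec]] = []
    for i in range(n):
        sex = "male" if i % 2 == 0 else "female"
        h_mu, h_sd = model.male_height if sex == "male" else model.female_height
        w_mu, w_sd = model.male_weight if sex == "male" else model.female_weight
        height = float(rng.normal(h_mu, h_sd))
        weight = max(30.0, float(rng.normal(w_mu, w_sd)))
        age = float(np.clip(rng.normal(*model.age), 20.0, 95.0))
        tissue = predict(height_model, height) * float(
            np.exp(rng.normal(0.0, model.tissue_lognorm_sd))
        )
        tissue = max(tissue, 100.0)
        frac = float(np.clip(rng.normal(*model.tissue_fraction), 0.06, 0.3))
        total = tissue / frac
        # uniform rescale of the whole scene (lungs, body, grid spacing): the
        # relative geometry stays valid and parenchyma volume scales cubically
        axes_scale = (total / base_interior_ml) ** (1.0 / 3.0)
        spec = replace(
            base,
            lung_semi_axes_mm=tuple(a * axes_scale for a in base.lung_semi_axes_mm),
            lung_separation_mm=base.lung_separation_mm * axes_scale,
            spacing=tuple(s * axes_scale for s in base.spacing),
            fat_thickness_mm=base.fat_thickness_mm * axes_scale,
            trachea_radius_mm=base.trachea_radius_mm * axes_scale,
            vessel_radius_mm=base.vessel_radius_mm * axes_scale,
            tissue_fraction=frac,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        record = SubjectRecord(
            id=f"S{i:04d}",
            sex=sex,
            age=age,
            height_m=height,
            weight_kg=weight,
            bsa_m2=_bsa_dubois(height, weight),
            tissue_volume_ml=tissue,
            total_volume_ml=total,
        )
        out.append((record, spec))
    return out


def simulate_paired_cohort(
    n: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
    air_hu_mean: float = -980.0,
    air_hu_sd: float = 6.0,
    scale_range: tuple[float, float] = (1.4, 1.8),
    fraction_sd: float = 0.01,
    noise_sd: float = 5.0,
) -> list[PairedScan]:
    """Render ``n`` paired expiration/inspiration phantoms as PairedScans.

    Each subject gets its own imaged-air HU (scatter varies between
    acquisitions), inspiration depth and tissue fraction.  Lung measurements
    are taken over the ground-truth parenchyma of the rendered (noisy)
    volumes; trachea air is measured with the standard circular ROI.
    """
    base = base_spec or PhantomSpec.small()
    rng = np.random.default_rng([seed, 41])
    scans: list[PairedScan] = []
    for i in range(n):
        air = float(rng.normal(air_hu_mean, air_hu_sd))
        frac = float(np.clip(rng.normal(base.tissue_fraction, fraction_sd), 0.06, 0.3))
        spec = replace(
            base,
            true_air_hu=air,
            tissue_fraction=frac,
            inspiration_scale=float(rng.uniform(*scale_range)),
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        (exp_vol, exp_truth), (ins_vol, ins_truth) = generate_pair(spec)
        roi = spec.trachea_roi()
        scans.append(
            PairedScan(
                exp=mask_statistics(exp_vol, exp_truth.interior_mask),
                ins=mask_statistics(ins_vol, ins_truth.interior_mask),
                exp_air_hu=roi_mean_hu(exp_vol, roi),
                ins_air_hu=roi_mean_hu(ins_vol, roi),
                subject_id=f"P{i:03d}",
            )
        )
    return scans
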