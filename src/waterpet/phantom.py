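"""Synthetic motion-free dynamic ¹⁵O-water cardiac PET scans.

The phantom stands in for motion-free clinical stress scans: an LV
myocardial shell (truncated half-ellipsoid, tiltable long axis) with
LAD/RCA/LCx territories, LV-cavity / RV / basal blood pools, and the
thorax surroundings that drive motion artifacts in real scans — low-activity
lung everywhere else and a high-late-activity liver compartment beyond the
infero-posterior wall (the heart rests on the diaphragm, so caudal or
anterior displacement exchanges myocardial voxels against liver or lung).

Every voxel follows the kinetics module's forward model for its compartment,
frame-averaged, with optional additive Gaussian noise whose variance scales
inversely with frame duration (reconstructed-PET-like frame noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .aif import AIFModel, fine_time_base, sample_aif
from .frames import FrameTimeGrid, build_frame_grid
from .kinetics import KineticParams, forward_tissue_curve

__all__ = [
    "PhantomSpec",
    "DynamicImage",
    "GroundTruth",
    "generate_phantom",
    "generate_population",
    "population_specs",
    "draw_population_mbf",
]

TERRITORIES = ("LAD", "RCA", "LCx")

#: Lognormal parameters reproducing the motion-free stress cohort
#: (median 2.35, IQR 0.82 mL·min⁻¹·g⁻¹): mu = ln 2.35, sigma from
#: 2·sinh(0.6745·sigma) = IQR/median.
POPULATION_MEDIAN_MBF = 2.35
POPULATION_IQR_MBF = 0.82
_POP_MU = float(np.log(POPULATION_MEDIAN_MBF))
_POP_SIGMA = float(np.arcsinh(POPULATION_IQR_MBF / (2 * POPULATION_MEDIAN_MBF)) / 0.6745)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of one synthetic subject.

    Lengths in mm; the LV shell is a half-ellipsoid between the inner and
    outer surfaces, truncated at the base plane, with the long axis tilted
    ``tilt_deg`` from caudal toward anterior (thorax-like oblique axis).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 3.27
    inner_radius: float = 25.0          # short-axis radius of the cavity surface
    outer_radius: float = 35.0          # short-axis radius of the epicardium
    elongation: float = 1.8             # long semi-axis = elongation x radius
    tilt_deg: float = 30.0              # apex tipped anterior by this angle
    territory_mbf: dict[str, float] = field(
        default_factory=lambda: {"LAD": 2.4, "RCA": 2.3, "LCx": 2.35}
    )
    ptf: float = 0.70                   # mL/mL
    va: float = 0.15                    # arterial spillover fraction
    lung_fraction: float = 0.12         # background activity as fraction of C_a
    liver_mbf: float = 0.9              # slow-washout compartment, mL/min/g
    liver_ptf: float = 0.85
    liver_va: float = 0.20
    liver_gap: float = 1.0              # mm between epicardium and diaphragm
    basal_pool_length: float = 25.0     # mm of atrial/outflow blood above base
    rv_radius: float = 18.0             # mm
    noise_scale: float = 0.03           # 0 disables noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_radius <= self.inner_radius:
            raise ValueError("outer radius must exceed inner radius")
        if self.voxel_size <= 0:
            raise ValueError("voxel size must be positive")
        if any(v < 0 for v in self.territory_mbf.values()):
            raise ValueError("MBF values must be >= 0")
        if self.ptf < 0 or self.va < 0 or self.noise_scale < 0:
            raise ValueError("kinetic values and noise_scale must be >= 0")

    @property
    def long_axis(self) -> np.ndarray:
        """Unit base→apex direction (+y anterior, +z cranial convention)."""
        tau = np.deg2rad(self.tilt_deg)
        return np.array([0.0, np.sin(tau), -np.cos(tau)])

    @property
    def anterior_ref(self) -> np.ndarray:
        """Unit circumferential reference (anterior), perpendicular to the axis."""
        u = self.long_axis
        y = np.array([0.0, 1.0, 0.0])
        v = y - (y @ u) * u
        return v / np.linalg.norm(v)


@dataclass
class DynamicImage:
    """4-D dynamic activity volume.

    ``voxels`` is indexed ``[frame, x, y, z]`` in Bq/mL with the anatomical
    convention +x right→left, +y posterior→anterior, +z caudal→cranial.
    """

    voxels: np.ndarray
    voxel_size: float
    frame_grid: FrameTimeGrid

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4-D [frame, x, y, z]")
        if self.voxels.shape[0] != len(self.frame_grid):
            raise ValueError("frame count must match the frame grid")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]

    def copy(self) -> "DynamicImage":
        return DynamicImage(self.voxels.copy(), self.voxel_size, self.frame_grid)

    def tac(self, mask: np.ndarray) -> np.ndarray:
        """Mean activity over a boolean mask, per frame."""
        mask = np.asarray(mask, bool)
        if not mask.any():
            raise ValueError("mask is empty")
        return self.voxels[:, mask].mean(axis=1).astype(float)


@dataclass
class GroundTruth:
    """Everything known by construction about one phantom."""

    myocardium_mask: np.ndarray
    territory_masks: dict[str, np.ndarray]
    lv_cavity_mask: np.ndarray
    rv_mask: np.ndarray
    basal_pool_mask: np.ndarray
    liver_mask: np.ndarray
    true_params: dict[str, KineticParams]
    aif: AIFModel
    center_vox: np.ndarray              # heart centre, voxel coordinates
    long_axis: np.ndarray
    anterior_ref: np.ndarray

    @property
    def blood_mask(self) -> np.ndarray:
        return self.lv_cavity_mask | self.rv_mask | self.basal_pool_mask


def _geometry(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Region masks on the voxel grid; assignment priority shell > blood >
    liver > lung."""
    shape = spec.grid_shape
    vs = spec.voxel_size
    half = np.array(shape) * vs / 2.0
    needed = spec.outer_radius * spec.elongation + 20.0
    if np.any(needed > half):
        raise ValueError(
            f"LV shell (extent {needed:.0f} mm) does not fit the grid with a "
            f"20 mm motion margin (half extents {half.round(0)} mm)"
        )
    center = (np.array(shape) - 1) / 2.0            # voxel coords of the heart
    ii = np.indices(shape).astype(float)
    r = (ii - center.reshape(3, 1, 1, 1)) * vs      # mm offsets, axes (x,y,z)
    r = np.moveaxis(r, 0, -1)                       # (...,3)

    u = spec.long_axis
    v1 = spec.anterior_ref
    v2 = np.cross(u, v1)                            # lateral (+x side)
    hu = r @ u                                      # along-axis, >0 toward apex
    c1 = r @ v1
    c2 = r @ v2

    def ellipsoid(a: float) -> np.ndarray:
        c = a * spec.elongation
        return (c1 / a) ** 2 + (c2 / a) ** 2 + (hu / c) ** 2 <= 1.0

    apex_side = hu >= 0
    outer = ellipsoid(spec.outer_radius) & apex_side
    inner = ellipsoid(spec.inner_radius) & apex_side
    shell = outer & ~inner
    cavity = inner

    radial = np.hypot(c1, c2)
    basal = (~apex_side) & (hu >= -spec.basal_pool_length) & (radial <= spec.inner_radius)

    rv_center = (-(spec.outer_radius + spec.rv_radius - 6.0)) * v2 + 4.0 * v1
    rv = np.linalg.norm(r - rv_center, axis=-1) <= spec.rv_radius
    rv &= ~outer & ~basal

    # slow-kinetics surroundings (liver/stomach/spleen, spine and posterior
    # mediastinum): the heart rests in the cardiac impression of the
    # diaphragm dome, which rises laterally around it, and posteriorly
    # there is no lung between the heart and the vertebral column.
    # Modelled as an infero-posterior half-space hugging the epicardium, a
    # posterior slab, and a conical diaphragm dome under/around the apex.
    inferior = -(r @ v1)                            # toward infero-posterior
    apex = spec.outer_radius * spec.elongation * u  # apex position, mm
    d_lat = np.hypot(r[..., 0] - apex[0], r[..., 1] - apex[1])
    z_dome = np.minimum(apex[2] - spec.liver_gap + 0.7 * d_lat, -15.0)
    liver = (
        (inferior >= spec.outer_radius + spec.liver_gap)
        | (r[..., 1] <= -(spec.outer_radius + spec.liver_gap))
        | (r[..., 2] <= z_dome)
    )
    liver &= ~shell & ~cavity & ~rv & ~basal

    # territories: circumferential 120-degree sectors + apical cap -> LAD
    ang = np.arctan2(c2, c1)                        # 0 = anterior, +lateral
    deg = np.rad2deg(ang)
    apex_cap = shell & (hu >= 0.80 * spec.outer_radius * spec.elongation)
    lad = shell & (((deg >= -105) & (deg < 15)) | apex_cap)
    lcx = shell & (deg >= 15) & (deg < 135) & ~apex_cap
    rca = shell & ~lad & ~lcx
    return {
        "shell": shell,
        "cavity": cavity,
        "basal": basal,
        "rv": rv,
        "liver": liver,
        "LAD": lad,
        "RCA": rca,
        "LCx": lcx,
        "center_vox": center,
    }


def generate_phantom(
    spec: PhantomSpec,
    aif: Optional[AIFModel] = None,
    grid: Optional[FrameTimeGrid] = None,
) -> tuple[DynamicImage, GroundTruth]:
    """Generate one motion-free dynamic scan with its ground truth.

    With ``noise_scale = 0`` every myocardial voxel equals the forward model
    of its territory exactly; regeneration with the same spec and seed is
    bit-identical.
    """
    aif = aif or AIFModel()
    grid = grid or build_frame_grid()
    geo = _geometry(spec)
    t_fine = fine_time_base(grid)
    ca_fine = sample_aif(aif, t_fine)

    true_params = {
        t: KineticParams(mbf=spec.territory_mbf[t], ptf=spec.ptf, va=spec.va)
        for t in TERRITORIES
    }
    liver_params = KineticParams(mbf=spec.liver_mbf, ptf=spec.liver_ptf, va=spec.liver_va)

    curves: dict[str, np.ndarray] = {
        t: forward_tissue_curve(true_params[t], ca_fine, grid, t_fine=t_fine)
        for t in TERRITORIES
    }
    blood_frames = forward_tissue_curve(
        KineticParams(mbf=0.0, ptf=0.0, va=1.0), ca_fine, grid, t_fine=t_fine
    )
    curves["blood"] = blood_frames
    curves["liver"] = forward_tissue_curve(liver_params, ca_fine, grid, t_fine=t_fine)
    curves["lung"] = spec.lung_fraction * blood_frames

    n_f = len(grid)
    vox = np.empty((n_f,) + tuple(spec.grid_shape), dtype=np.float32)
    vox[:] = curves["lung"][:, None, None, None]
    region_of = [
        ("liver", geo["liver"]),
        ("blood", geo["cavity"] | geo["basal"] | geo["rv"]),
        ("LAD", geo["LAD"]),
        ("RCA", geo["RCA"]),
        ("LCx", geo["LCx"]),
    ]
    for name, mask in region_of:
        vox[:, mask] = curves[name][:, None].astype(np.float32)

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_scale * aif.amplitude / np.sqrt(grid.durations)
        for f in range(n_f):
            vox[f] += rng.normal(0.0, sigma[f], size=spec.grid_shape).astype(np.float32)

    image = DynamicImage(vox, spec.voxel_size, grid)
    truth = GroundTruth(
        myocardium_mask=geo["shell"],
        territory_masks={t: geo[t] for t in TERRITORIES},
        lv_cavity_mask=geo["cavity"],
        rv_mask=geo["rv"],
        basal_pool_mask=geo["basal"],
        liver_mask=geo["liver"],
        true_params=true_params,
        aif=aif,
        center_vox=geo["center_vox"],
        long_axis=spec.long_axis,
        anterior_ref=spec.anterior_ref,
    )
    return image, truth


def draw_population_mbf(n: int, seed: int) -> np.ndarray:
    """Per-subject global stress MBF draws (lognormal, median 2.35,
    IQR 0.82 mL·min⁻¹·g⁻¹)."""
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = np.random.default_rng(seed)
    return np.exp(rng.normal(_POP_MU, _POP_SIGMA, size=n))


def population_specs(
    n: int,
    seed: int,
    base_spec: Optional[PhantomSpec] = None,
    territory_jitter: float = 0.15,
) -> list[PhantomSpec]:
    """Subject-level specs for a seeded population.

    Global MBF is drawn from the calibrated lognormal; territory values are
    multiplicative jitters around it, renormalised so the mean of the three
    territory values equals the drawn global exactly (``territory_jitter = 0``
    makes all territories equal the global).
    """
    base = base_spec or PhantomSpec()
    globals_ = draw_population_mbf(n, seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)).generate_state(1)[0])
    specs = []
    for i, g in enumerate(globals_):
        jit = np.exp(rng.normal(0.0, territory_jitter, size=3))
        jit /= jit.mean()
        terr = {t: float(g * jit[k]) for k, t in enumerate(TERRITORIES)}
        ptf = float(np.clip(rng.normal(0.70, 0.05), 0.5, 0.9))
        va = float(np.clip(rng.normal(0.15, 0.03), 0.05, 0.30))
        specs.append(
            replace(
                base,
                territory_mbf=terr,
                ptf=ptf,
                va=va,
                seed=int(np.random.SeedSequence((seed, 2, i)).generate_state(1)[0] % (2**31)),
            )
        )
    return specs


def generate_population(
    n: int,
    seed: int,
    base_spec: Optional[PhantomSpec] = None,
    aif: Optional[AIFModel] = None,
    grid: Optional[FrameTimeGrid] = None,
    territory_jitter: float = 0.15,
) -> list[tuple[DynamicImage, GroundTruth]]:
    """Generate a seeded population of motion-free subjects."""
    specs = population_specs(n, seed, base_spec, territory_jitter)
    return [generate_phantom(s, aif=aif, grid=grid) for s in specs]
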