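"""Acoustic property maps and the media that populate them.

A simulation medium is described by four co-registered 2D grids (sound
speed, mass density, absorption, nonlinearity B/A) on an isotropic grid.
The depth axis is axis 0 and increases away from the transducer face at
depth 0; the lateral axis is axis 1 and is centered on the array axis.

This module builds every medium used by the degradation experiments:

* synthetic skull slabs (cortical tables + porous diploe) standing in for
  CT-derived temporal-bone maps,
* sub-resolution speckle media with optional anechoic lesions,
* point targets of variable brightness,
* CT-to-acoustic-property conversion with two-point air/water calibration,
* the isovelocity transform (constant speed, impedance preserved) and the
  clutter reference (target removed) used by the four-case decomposition,
* homogenization (block-average to clinical CT resolution and back).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "SOFT_TISSUE",
    "CORTICAL_BONE",
    "AcousticMap",
    "CTVolume",
    "SkullModelParams",
    "SpeckleParams",
    "LesionSpec",
    "uniform_map",
    "attenuation_from_density",
    "ct_to_acoustic_map",
    "load_ct_volume",
    "generate_skull_slab",
    "generate_speckle_medium",
    "insert_anechoic_lesion",
    "insert_point_target",
    "point_target_footprint",
    "clutter_reference",
    "homogenize_map",
    "isovelocity_transform",
]

#: Reference material properties: (speed m/s, density kg/m^3,
#: attenuation dB MHz^-1 cm^-1, B/A).
SOFT_TISSUE = dict(speed=1540.0, density=1000.0, attenuation=0.3, nonlinearity=7.6)
#: Cortical bone endpoints.  Attenuation is 2.8 dB MHz^-1 cm^-1 when the
#: bone microstructure is resolved by the grid and 13 when a homogenized
#: (clinical-CT resolution) map must compensate for the missing
#: microstructure scattering.
CORTICAL_BONE = dict(speed=3000.0, density=1850.0, attenuation=2.8, nonlinearity=7.6)

#: Attenuation of homogenized (clinical resolution) skull maps.
HOMOGENIZED_BONE_ATTENUATION = 13.0

SPEED_RANGE = (1540.0, 3000.0)
DENSITY_RANGE = (1000.0, 1850.0)


@dataclass
class AcousticMap:
    """Co-registered acoustic property grids defining a simulation medium.

    Attributes
    ----------
    speed : (nz, nx) array, m/s
    density : (nz, nx) array, kg/m^3
    attenuation : (nz, nx) array, dB MHz^-1 cm^-1
    nonlinearity : (nz, nx) array, B/A (dimensionless)
    dx : float, isotropic grid spacing in m
    """

    speed: np.ndarray
    density: np.ndarray
    attenuation: np.ndarray
    nonlinearity: np.ndarray
    dx: float
    seed: int | None = None

    def __post_init__(self) -> None:
        self.speed = np.asarray(self.speed, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        self.nonlinearity = np.asarray(self.nonlinearity, dtype=float)
        shapes = {g.shape for g in self._grids()}
        if len(shapes) != 1:
            raise ValueError(f"property grids have mismatched shapes: {shapes}")
        if self.speed.ndim != 2:
            raise ValueError("property grids must be 2D (depth, lateral)")
        if not self.dx > 0:
            raise ValueError("dx must be positive")
        if np.any(self.speed <= 0) or np.any(self.density <= 0):
            raise ValueError("speed and density must be strictly positive")
        if np.any(self.attenuation < 0):
            raise ValueError("attenuation must be non-negative")

    def _grids(self):
        return (self.speed, self.density, self.attenuation, self.nonlinearity)

    @property
    def shape(self) -> tuple[int, int]:
        return self.speed.shape

    @property
    def extent(self) -> tuple[float, float]:
        """Physical (depth, width) in m."""
        nz, nx = self.shape
        return (nz * self.dx, nx * self.dx)

    @property
    def impedance(self) -> np.ndarray:
        """Acoustic impedance rho*c in Rayl (kg m^-2 s^-1)."""
        return self.density * self.speed

    @property
    def z_coords(self) -> np.ndarray:
        """Depth of each row center, transducer face at depth 0."""
        return np.arange(self.shape[0]) * self.dx

    @property
    def x_coords(self) -> np.ndarray:
        """Lateral coordinate of each column, centered on the array axis."""
        nx = self.shape[1]
        return (np.arange(nx) - (nx - 1) / 2.0) * self.dx

    def copy(self) -> "AcousticMap":
        return AcousticMap(
            self.speed.copy(),
            self.density.copy(),
            self.attenuation.copy(),
            self.nonlinearity.copy(),
            self.dx,
            self.seed,
        )

    def index_of(self, depth: float, lateral: float) -> tuple[int, int]:
        """Grid index of a physical (depth, lateral) position."""
        iz = int(round(depth / self.dx))
        ix = int(round(lateral / self.dx + (self.shape[1] - 1) / 2.0))
        return iz, ix

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("speed", "density", "attenuation", "nonlinearity"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["dx"] = self.dx
            f.attrs["provenance"] = "skullwave"
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path) -> "AcousticMap":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                f["speed"][...],
                f["density"][...],
                f["attenuation"][...],
                f["nonlinearity"][...],
                dx=float(f.attrs["dx"]),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )


@dataclass
class CTVolume:
    """A CT grid in scanner units with air/water calibration references."""

    hu: np.ndarray
    spacing: float
    air_ref: float = -1000.0
    water_ref: float = 0.0

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        if self.air_ref == self.water_ref:
            raise ValueError("air and water references must differ")

    def calibrated_density(self) -> np.ndarray:
        """Two-point linear density calibration through air and water.

        Maps the scanner units of the air reference onto 1.225 kg/m^3 and
        the water reference onto 997 kg/m^3.
        """
        rho_air, rho_water = 1.225, 997.0
        slope = (rho_water - rho_air) / (self.water_ref - self.air_ref)
        return rho_air + slope * (self.hu - self.air_ref)


@dataclass
class SkullModelParams:
    """Geometry and texture of a synthetic temporal-bone slab.

    All thicknesses in m.  The defaults describe the temporal acoustic
    window used for transcranial imaging: ~3 mm total, almost entirely
    cortical bone with only a sliver of diploe — a mild aberrator, as
    temporal-bone specimens are.  Thicker cortical-diploe-cortical
    regions (parietal-style) are built by raising ``diploe_thickness``.
    The porous diploe is filled with a correlated random porosity
    texture whose amplitude and correlation length emulate trabecular
    spacing (0.5-2 mm in human skull); ``diploe_thickness`` may be 0 for
    a purely cortical plate.
    """

    standoff: float = 3e-3
    outer_cortical: float = 1.2e-3
    diploe_thickness: float = 1.0e-3
    inner_cortical: float = 0.8e-3
    porosity_amplitude: float = 0.5
    porosity_correlation_length: float = 0.8e-3
    surface_roughness: float = 0.15e-3
    #: clinical-resolution maps use the homogenization-compensating 13
    #: dB MHz^-1 cm^-1 throughout the bone; pass (2.8, 2.8) or a porosity
    #: interpolation for microstructure-resolving slabs
    attenuation_range: tuple[float, float] = (HOMOGENIZED_BONE_ATTENUATION,) * 2
    #: 'continuous' emulates what clinical CT reports (smooth porosity);
    #: 'trabecular' thresholds the texture into a binary bone/marrow
    #: structure, emulating resolved microstructure (trabecular elements
    #: with ~0.5-2 mm separation and ~50% pore fraction)
    microstructure: str = "continuous"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("standoff", "outer_cortical", "diploe_thickness", "inner_cortical"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.porosity_amplitude <= 1.0:
            raise ValueError("porosity_amplitude must be in [0, 1]")

    @property
    def total_thickness(self) -> float:
        return self.outer_cortical + self.diploe_thickness + self.inner_cortical


@dataclass
class SpeckleParams:
    """Sub-resolution scatterer field emulating soft-tissue speckle."""

    scatterers_per_cell: float = 15.0
    fractional_variation: float = 0.005
    background_density: float = 1000.0
    background_attenuation: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.scatterers_per_cell > 0:
            raise ValueError("scatterers_per_cell must be positive")
        if not 0.0 <= self.fractional_variation < 1.0:
            raise ValueError("fractional_variation must be in [0, 1)")


@dataclass
class LesionSpec:
    """An anechoic disc (no scatterers, optionally non-attenuating)."""

    center: tuple[float, float]  # (lateral, depth) in m
    diameter: float = 0.01
    attenuation_inside: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("diameter must be >= 0")


def uniform_map(
    shape: tuple[int, int],
    dx: float,
    speed: float = SOFT_TISSUE["speed"],
    density: float = SOFT_TISSUE["density"],
    attenuation: float = SOFT_TISSUE["attenuation"],
    nonlinearity: float = SOFT_TISSUE["nonlinearity"],
) -> AcousticMap:
    """A homogeneous medium, soft tissue by default."""
    nz, nx = shape
    return AcousticMap(
        np.full((nz, nx), float(speed)),
        np.full((nz, nx), float(density)),
        np.full((nz, nx), float(attenuation)),
        np.full((nz, nx), float(nonlinearity)),
        dx=dx,
    )


def attenuation_from_density(
    density: np.ndarray,
    alpha_min: float,
    alpha_max: float,
    density_range: tuple[float, float] = DENSITY_RANGE,
) -> np.ndarray:
    """Map bone density to absorption through porosity.

    Porosity is Phi = (rho_max - rho) / (rho_max - rho_min), zero for pure
    cortical bone and one at the marrow endpoint.  Absorption interpolates
    between the cortical value ``alpha_min`` (Phi = 0) and the porous
    endpoint ``alpha_max`` (Phi = 1) as

        alpha = alpha_min + (alpha_max - alpha_min) * sqrt(Phi)

    i.e. monotonically increasing with porosity (decreasing with density),
    endpoint-exact, with a square-root law so that small amounts of
    porosity already raise absorption appreciably.
    """
    if alpha_max < alpha_min:
        raise ValueError("alpha_max must be >= alpha_min")
    rho_min, rho_max = density_range
    if not rho_max > rho_min:
        raise ValueError("density_range must be increasing")
    density = np.asarray(density, dtype=float)
    tol = 1e-9 * (rho_max - rho_min)
    bad = (density < rho_min - tol) | (density > rho_max + tol)
    if np.any(bad):
        offending = float(density[bad].flat[0])
        raise ValueError(
            f"density {offending} kg/m^3 outside calibration range "
            f"[{rho_min}, {rho_max}]"
        )
    phi = np.clip((rho_max - density) / (rho_max - rho_min), 0.0, 1.0)
    return alpha_min + (alpha_max - alpha_min) * np.sqrt(phi)


def ct_to_acoustic_map(
    ct: CTVolume,
    bone_threshold: float,
    speed_range: tuple[float, float] = SPEED_RANGE,
    density_range: tuple[float, float] = DENSITY_RANGE,
    attenuation_range: tuple[float, float] = (HOMOGENIZED_BONE_ATTENUATION,) * 2,
    soft_tissue: dict = SOFT_TISSUE,
) -> AcousticMap:
    """Convert a (2D slice of a) CT scan to acoustic property maps.

    The skull is segmented as voxels above ``bone_threshold`` scanner
    units.  Segmented values are scaled linearly so that the segmented
    minimum maps onto the soft-tissue endpoints (1540 m/s, 1000 kg/m^3)
    and the segmented maximum onto the cortical endpoints (3000 m/s,
    1850 kg/m^3).  Non-bone voxels receive soft-tissue values.  Bone
    absorption follows :func:`attenuation_from_density`; by default both
    endpoints sit at 13 dB MHz^-1 cm^-1, the value that compensates for
    the microstructure missing from clinical-resolution scans.
    """
    hu = np.asarray(ct.hu, dtype=float)
    if hu.ndim != 2:
        raise ValueError("expected a 2D CT slice (use load_ct_volume(..., slice_index=))")
    bone = hu > bone_threshold
    if not bone.any():
        raise ValueError(f"no voxel above bone threshold {bone_threshold}")
    seg = hu[bone]
    lo, hi = float(seg.min()), float(seg.max())
    if hi == lo:
        raise ValueError("segmented CT values are constant: calibration is degenerate")
    frac = np.zeros_like(hu)
    frac[bone] = (hu[bone] - lo) / (hi - lo)

    c_min, c_max = speed_range
    r_min, r_max = density_range
    speed = np.full_like(hu, soft_tissue["speed"])
    density = np.full_like(hu, soft_tissue["density"])
    speed[bone] = c_min + frac[bone] * (c_max - c_min)
    density[bone] = r_min + frac[bone] * (r_max - r_min)
    attenuation = np.full_like(hu, soft_tissue["attenuation"])
    attenuation[bone] = attenuation_from_density(
        density[bone], attenuation_range[0], attenuation_range[1], (r_min, r_max)
    )
    nonlinearity = np.full_like(hu, soft_tissue["nonlinearity"])
    return AcousticMap(speed, density, attenuation, nonlinearity, dx=ct.spacing)


def load_ct_volume(path, slice_index: int | None = None) -> CTVolume:
    """Load a CT volume from NIfTI or from a raw binary + JSON header pair.

    The raw dialect expects ``<stem>.json`` next to the binary with keys
    ``shape``, ``dtype``, ``spacing`` (m) and optional ``air_ref`` /
    ``water_ref``.
    """
    path = Path(path)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(float)
        spacing = float(img.header.get_zooms()[0]) * 1e-3  # mm -> m
        hu = data
    else:
        header = json.loads(path.with_suffix(".json").read_text())
        hu = np.fromfile(path, dtype=np.dtype(header["dtype"])).reshape(header["shape"])
        spacing = float(header["spacing"])
        ct = CTVolume(
            hu.astype(float),
            spacing,
            air_ref=float(header.get("air_ref", -1000.0)),
            water_ref=float(header.get("water_ref", 0.0)),
        )
        if slice_index is not None and ct.hu.ndim == 3:
            ct = replace(ct, hu=ct.hu[:, :, slice_index])
        return ct
    if slice_index is not None and hu.ndim == 3:
        hu = hu[:, :, slice_index]
    return CTVolume(hu, spacing)


def _smooth_noise_1d(rng, n: int, corr_cells: float) -> np.ndarray:
    """Unit-std Gaussian noise with the given correlation length (cells)."""
    g = rng.standard_normal(n)
    if corr_cells > 0:
        g = ndimage.gaussian_filter1d(g, corr_cells, mode="wrap")
    s = g.std()
    return g / s if s > 0 else g


def generate_skull_slab(
    params: SkullModelParams,
    shape: tuple[int, int],
    dx: float,
    background: AcousticMap | None = None,
    speed_range: tuple[float, float] = SPEED_RANGE,
    density_range: tuple[float, float] = DENSITY_RANGE,
) -> AcousticMap:
    """Embed a synthetic skull slab into a background medium.

    The slab is an outer cortical table, a porous diploe and an inner
    cortical table, starting ``standoff`` below the transducer face.
    Cortical tables sit at the cortical endpoint values; the diploe is
    filled with a seeded, spatially correlated porosity texture converted
    to speed and density by the same linear law as the CT conversion and
    to absorption by :func:`attenuation_from_density`.  Interfaces get a
    seeded roughness profile.  Everywhere else the background medium
    (water/soft tissue by default) is left untouched.
    """
    nz, nx = shape
    if background is None:
        out = uniform_map(shape, dx)
    else:
        if background.shape != tuple(shape) or background.dx != dx:
            raise ValueError("background grid does not match requested shape/dx")
        out = background.copy()

    depth_needed = params.standoff + params.total_thickness + params.surface_roughness
    if depth_needed >= nz * dx:
        raise ValueError(
            f"skull layers ({depth_needed * 1e3:.1f} mm) exceed map depth "
            f"({nz * dx * 1e3:.1f} mm)"
        )

    rng = np.random.default_rng(params.seed)
    rough_cells = max(1.0, 2e-3 / dx)  # ~2 mm lateral correlation of roughness
    top_off = params.surface_roughness * _smooth_noise_1d(rng, nx, rough_cells)
    bot_off = params.surface_roughness * _smooth_noise_1d(rng, nx, rough_cells)

    # porosity texture for the diploe, correlated over the trabecular scale
    g = rng.standard_normal((nz, nx))
    corr_cells = params.porosity_correlation_length / dx
    if corr_cells > 0:
        g = ndimage.gaussian_filter(g, corr_cells, mode="wrap")
        s = g.std()
        if s > 0:
            g = g / s
    if params.microstructure == "trabecular":
        # binary bone/marrow structure at an anatomical ~40% pore fraction
        thresh = np.quantile(g, 0.6)
        phi = np.where(g > thresh, params.porosity_amplitude, 0.0)
    elif params.microstructure == "continuous":
        phi = params.porosity_amplitude * np.clip(0.5 + g / 4.0, 0.0, 1.0)
    else:
        raise ValueError(f"unknown microstructure {params.microstructure!r}")

    z = np.arange(nz)[:, None] * dx
    top = params.standoff + top_off[None, :]
    b1 = top + params.outer_cortical
    b2 = b1 + params.diploe_thickness
    bottom = b2 + params.inner_cortical + bot_off[None, :]

    bone = (z >= top) & (z < bottom)
    diploe = bone & (z >= b1) & (z < b2)
    phi_map = np.zeros((nz, nx))
    phi_map[diploe] = phi[diploe]

    c_min, c_max = speed_range
    r_min, r_max = density_range
    out.speed[bone] = c_max - phi_map[bone] * (c_max - c_min)
    out.density[bone] = r_max - phi_map[bone] * (r_max - r_min)
    a_min, a_max = params.attenuation_range
    out.attenuation[bone] = attenuation_from_density(
        out.density[bone], a_min, a_max, (r_min, r_max)
    )
    out.seed = params.seed
    return out


def generate_speckle_medium(
    params: SpeckleParams,
    shape: tuple[int, int],
    dx: float,
    f0: float,
    speed: float = SOFT_TISSUE["speed"],
) -> AcousticMap:
    """Sub-resolution scatterer field emulating soft tissue.

    Single-pixel density perturbations of magnitude
    ``fractional_variation * background_density`` with random sign are
    placed at uniform random pixels.  The expected number of scatterers is
    ``scatterers_per_cell`` per wavelength-squared cell (wavelength at
    ``f0`` in the background speed), the canonical fully developed speckle
    density.  Absorption is uniform at ``background_attenuation``.
    """
    nz, nx = shape
    lam = speed / f0
    if dx >= lam / 2:
        raise ValueError("grid spacing does not resolve single-pixel scatterers")
    out = uniform_map(
        shape,
        dx,
        speed=speed,
        density=params.background_density,
        attenuation=params.background_attenuation,
    )
    area = (nz * dx) * (nx * dx)
    mean_count = params.scatterers_per_cell * area / lam**2
    rng = np.random.default_rng(params.seed)
    n = int(rng.poisson(mean_count))
    if n > nz * nx:
        raise ValueError("more scatterers than grid pixels; refine the grid")
    # distinct pixels, so the realized count follows the sampling law
    flat = rng.choice(nz * nx, size=n, replace=False)
    sign = rng.choice((-1.0, 1.0), size=n)
    delta = params.fractional_variation * params.background_density
    out.density.ravel()[flat] = params.background_density + sign * delta
    out.seed = params.seed
    return out


def _disc_mask(map_: AcousticMap, center_lateral: float, center_depth: float,
               radius: float) -> np.ndarray:
    zz = map_.z_coords[:, None]
    xx = map_.x_coords[None, :]
    return (zz - center_depth) ** 2 + (xx - center_lateral) ** 2 <= radius**2


def insert_anechoic_lesion(map_: AcousticMap, spec: LesionSpec,
                           background_density: float | None = None,
                           background_speed: float | None = None) -> AcousticMap:
    """Clear all scatterers inside a disc and make it non-attenuating.

    Inside the disc, density and speed are reset to the background values
    (the medium mode, i.e. the most common value, unless given) and
    absorption is set to ``spec.attenuation_inside``.
    """
    lat, dep = spec.center
    r = spec.diameter / 2.0
    depth_ext, width_ext = map_.extent
    if not (r <= dep <= depth_ext - r and abs(lat) + r <= width_ext / 2):
        raise ValueError("lesion disc does not fit inside the map")
    if spec.diameter == 0:
        return map_.copy()
    out = map_.copy()
    mask = _disc_mask(map_, lat, dep, r)
    if background_density is None:
        vals, counts = np.unique(map_.density, return_counts=True)
        background_density = float(vals[np.argmax(counts)])
    if background_speed is None:
        vals, counts = np.unique(map_.speed, return_counts=True)
        background_speed = float(vals[np.argmax(counts)])
    out.density[mask] = background_density
    out.speed[mask] = background_speed
    out.attenuation[mask] = spec.attenuation_inside
    return out


DEFAULT_TARGET_CONTRAST = 0.65
DEFAULT_TARGET_RADIUS_CELLS = 1.6


def point_target_footprint(map_: AcousticMap, depth: float, lateral: float = 0.0,
                           radius_cells: float = DEFAULT_TARGET_RADIUS_CELLS) -> np.ndarray:
    """Boolean mask of the few-pixel disc occupied by a point target."""
    return _disc_mask(map_, lateral, depth, radius_cells * map_.dx)


def insert_point_target(
    map_: AcousticMap,
    depth: float,
    lateral: float = 0.0,
    brightness_scale: float = 1.0,
    base_contrast: float = DEFAULT_TARGET_CONTRAST,
    speed_contrast: float = 0.0,
    radius_cells: float = DEFAULT_TARGET_RADIUS_CELLS,
) -> AcousticMap:
    """Place a bright point target (a few-pixel disc) in the medium.

    Brightness is realized as an impedance contrast through density: the
    density inside the disc is multiplied by
    ``1 + brightness_scale * base_contrast``, so the echo amplitude is
    proportional to ``brightness_scale`` (at the defaults the
    full-brightness target presents ~1 MRayl of impedance mismatch over
    soft tissue).  Keeping the sound speed untouched makes the
    isovelocity transform exactly neutral for skull-free scenes.  A
    speed-scaled realization (``speed_contrast > 0``) is available for
    experiments that vary target speed instead.  ``brightness_scale = 0``
    leaves the map unchanged.
    """
    depth_ext, width_ext = map_.extent
    if not (0 <= depth <= depth_ext and abs(lateral) <= width_ext / 2):
        raise ValueError("target position outside the map")
    out = map_.copy()
    if brightness_scale == 0 and speed_contrast == 0:
        return out
    mask = point_target_footprint(map_, depth, lateral, radius_cells)
    out.density[mask] *= 1.0 + brightness_scale * base_contrast
    if speed_contrast:
        out.speed[mask] *= 1.0 + speed_contrast
    return out


def clutter_reference(
    map_with_target: AcousticMap,
    target_footprint: np.ndarray,
    background: AcousticMap | None = None,
) -> AcousticMap:
    """The same medium with the target removed (for clutter-only runs).

    Footprint pixels are restored to the background medium; every other
    pixel is left bit-identical.  When ``background`` (the pre-insertion
    map) is given, its values are copied exactly; otherwise the footprint
    is filled with the most common speed/density of the pixels bordering
    it.
    """
    target_footprint = np.asarray(target_footprint, dtype=bool)
    if target_footprint.shape != map_with_target.shape:
        raise ValueError("footprint shape does not match the map")
    if not target_footprint.any():
        raise ValueError("target footprint is empty")
    out = map_with_target.copy()
    if background is not None:
        if background.shape != map_with_target.shape:
            raise ValueError("background shape mismatch")
        for name in ("speed", "density", "attenuation", "nonlinearity"):
            getattr(out, name)[target_footprint] = getattr(background, name)[target_footprint]
        return out
    ring = ndimage.binary_dilation(target_footprint, iterations=2) & ~target_footprint
    for name in ("speed", "density", "attenuation", "nonlinearity"):
        grid = getattr(out, name)
        vals, counts = np.unique(grid[ring], return_counts=True)
        grid[target_footprint] = vals[np.argmax(counts)]
    return out


def homogenize_map(map_: AcousticMap, coarse_resolution: float,
                   method: str = "mean") -> AcousticMap:
    """Degrade a map to clinical-CT resolution on its own grid.

    ``method='mean'`` block-averages every property grid over
    ``coarse_resolution / dx`` sized tiles and writes the tile values
    back to the original grid (zeroth-order interpolation back to
    ``dx``), emulating the partial-volume blur a clinical scanner
    applies to finely structured bone; the spatial mean is preserved
    exactly.  ``method='subsample'`` keeps one representative pixel per
    tile (decimation), which is what resampling a high-resolution
    volume onto a coarse scanner grid does: interfaces stay sharp but
    are displaced by up to one tile.  Both methods are idempotent at a
    fixed resolution.
    """
    if coarse_resolution < map_.dx:
        raise ValueError("coarse_resolution must be >= the map resolution")
    b = int(round(coarse_resolution / map_.dx))
    if b <= 1:
        return map_.copy()
    nz, nx = map_.shape
    iz = np.arange(nz) // b
    ix = np.arange(nx) // b
    out = map_.copy()
    if method == "mean":
        labels = iz[:, None] * (ix.max() + 1) + ix[None, :]
        for name in ("speed", "density", "attenuation", "nonlinearity"):
            grid = getattr(map_, name)
            sums = np.bincount(labels.ravel(), weights=grid.ravel())
            cnts = np.bincount(labels.ravel())
            setattr(out, name, (sums / cnts)[labels])
    elif method == "subsample":
        # representative pixel: the center of each tile (clamped)
        rz = np.minimum(iz * b + b // 2, nz - 1)
        rx = np.minimum(ix * b + b // 2, nx - 1)
        for name in ("speed", "density", "attenuation", "nonlinearity"):
            grid = getattr(map_, name)
            setattr(out, name, grid[np.ix_(rz, rx)])
    else:
        raise ValueError(f"unknown homogenization method {method!r}")
    return out


def isovelocity_transform(map_: AcousticMap, c0: float = SOFT_TISSUE["speed"]) -> AcousticMap:
    """Constant-speed medium with the impedance grid preserved.

    Speed is set to ``c0`` everywhere and density rescaled by c/c0 so that
    rho' c' = rho c at every pixel: phase aberration is removed while all
    impedance interfaces (hence reverberation) are retained.
    """
    if not c0 > 0:
        raise ValueError("c0 must be positive")
    out = map_.copy()
    out.density = map_.density * (map_.speed / c0)
    out.speed = np.full_like(map_.speed, float(c0))
    return out
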