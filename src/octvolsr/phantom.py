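"""Seeded synthetic anterior-segment OCT phantoms.

The generator emulates the anatomy a scanned eye presents to an
anterior-segment OCT system — a corneal arc (spherical-cap shell), two iris
slabs with a central pupil aperture, and the crystalline lens (ellipsoidal
shell with a weakly reflective interior) — on a dark background, then
multiplies unit-mean gamma speckle over the clean reflectivity map.  It is
deliberately schematic: the point is smooth curved boundaries plus
coherent-imaging noise, the two features the upsampling networks must
reconstruct, not biometric realism.

All coordinates are in voxel units of the high-resolution grid, X axial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import ResolutionTriplet, ScanGrid, Volume, make_triplet, normalize

logger = logging.getLogger(__name__)


class GeometryError(ValueError):
    """A phantom structure does not fit inside the scan grid."""


@dataclass(frozen=True)
class SphericalCap:
    """Cornea model: the +X-facing cap of a spherical shell."""

    center: tuple[float, float, float]
    radius: float
    thickness: float = 1.5
    reflectivity: float = 0.85
    cap_depth: float = 0.35  # fraction of the radius the cap spans axially


@dataclass(frozen=True)
class Ellipsoid:
    """Crystalline-lens model: shell plus weakly scattering interior."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    shell_reflectivity: float = 0.7
    interior_reflectivity: float = 0.15
    thickness: float = 1.5  # shell half-width in implicit-function units


@dataclass(frozen=True)
class IrisSlabs:
    """Two coplanar slabs normal to X with a central circular aperture."""

    depth: float  # X position of the slab mid-plane
    thickness: float = 2.5
    aperture_radius: float = 10.0
    reflectivity: float = 0.55


@dataclass(frozen=True)
class PhantomSpec:
    """Full parametric description of one phantom volume."""

    grid: ScanGrid = field(default_factory=lambda: ScanGrid(nx=64, ny=64, nz=32))
    cornea: SphericalCap | None = None
    lens: Ellipsoid | None = None
    iris: IrisSlabs | None = None
    background_level: float = 0.02
    psf_sigma: float = 1.5  # Gaussian blur (voxels) emulating the system PSF
    speckle_distribution: str = "gamma"
    speckle_scale: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for r in self._reflectivities():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"reflectivity {r} outside [0, 1]")
        if self.speckle_scale < 0:
            raise ValueError("speckle scale must be >= 0")

    def _reflectivities(self) -> list[float]:
        out = [self.background_level]
        if self.cornea:
            out.append(self.cornea.reflectivity)
        if self.lens:
            out += [self.lens.shell_reflectivity, self.lens.interior_reflectivity]
        if self.iris:
            out.append(self.iris.reflectivity)
        return out


def default_spec(grid: ScanGrid | None = None, seed: int = 0) -> PhantomSpec:
    """An eye-like phantom scaled to the given grid (default 64 x 64 x 32)."""
    grid = grid or ScanGrid(nx=64, ny=64, nz=32)
    nx, ny, nz = grid.shape
    cy, cz = (ny - 1) / 2, (nz - 1) / 2
    return PhantomSpec(
        grid=grid,
        cornea=SphericalCap(
            center=(0.55 * nx, cy, cz),
            radius=0.45 * nx,
            thickness=max(1.5, 0.02 * nx),
        ),
        lens=Ellipsoid(
            center=(0.62 * nx, cy, cz),
            semi_axes=(0.18 * nx, 0.30 * ny, 0.30 * nz),
            thickness=0.08,
        ),
        iris=IrisSlabs(
            depth=0.42 * nx,
            thickness=max(2.0, 0.03 * nx),
            aperture_radius=0.18 * min(ny, nz),
        ),
        seed=seed,
    )


def _coords(grid: ScanGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(
        np.arange(grid.nx, dtype=np.float32),
        np.arange(grid.ny, dtype=np.float32),
        np.arange(grid.nz, dtype=np.float32),
        indexing="ij",
    )


def render_clean(spec: PhantomSpec) -> Volume:
    """Deterministic noiseless reflectivity map of a phantom spec.

    Surfaces are thin shells; voxels take the reflectivity of the structure
    containing them, later structures drawn over earlier ones in the order
    background -> lens interior -> lens shell -> iris -> cornea.
    """
    grid = spec.grid
    x, y, z = _coords(grid)
    vol = np.full(grid.shape, spec.background_level, dtype=np.float32)

    if spec.lens is not None:
        le = spec.lens
        _check_inside(grid, le.center, "lens")
        q = (
            ((x - le.center[0]) / le.semi_axes[0]) ** 2
            + ((y - le.center[1]) / le.semi_axes[1]) ** 2
            + ((z - le.center[2]) / le.semi_axes[2]) ** 2
        )
        vol[q < 1.0] = le.interior_reflectivity
        vol[np.abs(q - 1.0) < le.thickness] = le.shell_reflectivity

    if spec.iris is not None:
        ir = spec.iris
        if not 0 <= ir.depth < grid.nx:
            raise GeometryError(f"iris depth {ir.depth} outside axial range")
        cy, cz = (grid.ny - 1) / 2, (grid.nz - 1) / 2
        in_slab = np.abs(x - ir.depth) <= ir.thickness / 2
        outside_pupil = (y - cy) ** 2 + (z - cz) ** 2 > ir.aperture_radius**2
        vol[in_slab & outside_pupil] = ir.reflectivity

    if spec.cornea is not None:
        co = spec.cornea
        _check_inside(grid, co.center, "cornea")
        r = np.sqrt(
            (x - co.center[0]) ** 2 + (y - co.center[1]) ** 2 + (z - co.center[2]) ** 2
        )
        on_shell = np.abs(r - co.radius) <= co.thickness / 2
        # keep only the cap facing the beam (low-X side), spanning
        # cap_depth * radius axially from the shell apex
        cap = x <= co.center[0] - (1.0 - co.cap_depth) * co.radius
        vol[on_shell & cap] = co.reflectivity

    return Volume(vol)


def _check_inside(
    grid: ScanGrid, center: tuple[float, float, float], name: str
) -> None:
    for c, n in zip(center, grid.shape):
        if not 0 <= c < n:
            raise GeometryError(f"{name} center {center} outside grid {grid.shape}")


def apply_speckle(vol: Volume, spec: PhantomSpec) -> Volume:
    """Multiply unit-mean speckle over a non-negative volume and renormalize.

    The default distribution is gamma with shape 1/scale^2 and mean 1, the
    usual surrogate for (partially averaged) coherent-imaging speckle; a
    scale of 0 degenerates to the clean volume.  Output is min-max
    rescaled to [0, 1].
    """
    if vol.data.min() < 0:
        raise ValueError("speckle requires non-negative input")
    if spec.speckle_scale == 0:
        return normalize(vol)
    if spec.speckle_distribution != "gamma":
        raise ValueError(
            f"unknown speckle distribution {spec.speckle_distribution!r}"
        )
    rng = np.random.default_rng(spec.seed)
    shape = 1.0 / spec.speckle_scale**2
    noise = rng.gamma(shape, scale=1.0 / shape, size=vol.shape).astype(np.float32)
    return normalize(Volume(vol.data * noise))


def apply_psf(vol: Volume, sigma: float) -> Volume:
    """Gaussian blur emulating the finite optical point-spread function.

    Real OCT volumes are band-limited by the beam spot: at full lateral
    sampling (7 mm / 1024 A-scans = 6.8 um pitch) the 25.8 um spot spans
    roughly 1.5 voxel standard deviations, so boundaries are smooth at the
    voxel scale rather than binary steps.  ``sigma`` is in voxels of the
    rendered grid; 0 disables smoothing.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol
    return Volume(ndimage.gaussian_filter(vol.data, sigma))


def render(spec: PhantomSpec) -> Volume:
    """Clean render, PSF smoothing, speckle: the ground-truth high volume."""
    clean = apply_psf(render_clean(spec), spec.psf_sigma)
    return apply_speckle(clean, spec)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

@dataclass
class PhantomDataset:
    train: list[ResolutionTriplet]
    validation: list[ResolutionTriplet]
    specs: list[PhantomSpec]


def _jitter_spec(
    base: PhantomSpec, rng: np.random.Generator, jitter: float
) -> PhantomSpec:
    """Perturb geometry multiplicatively/translationally within +/- jitter."""

    def j(v: float, lo: float | None = None) -> float:
        out = v * (1.0 + rng.uniform(-jitter, jitter))
        return out if lo is None else max(out, lo)

    def jc(c: tuple[float, float, float], scale: float) -> tuple[float, float, float]:
        return tuple(v + rng.uniform(-jitter, jitter) * scale for v in c)

    nx = base.grid.nx
    cornea = lens = iris = None
    if base.cornea:
        cornea = replace(
            base.cornea,
            center=jc(base.cornea.center, 0.1 * nx),
            radius=j(base.cornea.radius, 2.0),
        )
    if base.lens:
        lens = replace(
            base.lens,
            center=jc(base.lens.center, 0.1 * nx),
            semi_axes=tuple(j(s, 1.5) for s in base.lens.semi_axes),
        )
    if base.iris:
        iris = replace(
            base.iris,
            depth=j(base.iris.depth),
            aperture_radius=j(base.iris.aperture_radius, 1.0),
        )
    return replace(
        base,
        cornea=cornea,
        lens=lens,
        iris=iris,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def generate_dataset(
    n: int,
    base_spec: PhantomSpec | None = None,
    jitter: float = 0.1,
    seed: int = 0,
    train_fraction: float = 200 / 236,
    max_retries: int = 20,
) -> PhantomDataset:
    """Generate ``n`` jittered phantom triplets with a train/validation split.

    The split fraction defaults to 200:36, so a 236-volume dataset divides
    into 200 training and 36 validation members.  Specs whose jittered
    geometry falls outside the grid are rejected and resampled up to
    ``max_retries`` times.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or default_spec()
    rng = np.random.default_rng(seed)
    triplets: list[ResolutionTriplet] = []
    specs: list[PhantomSpec] = []
    for _ in range(n):
        for attempt in range(max_retries):
            spec = _jitter_spec(base, rng, jitter)
            try:
                high = render(spec)
                triplets.append(make_triplet(high))
                specs.append(spec)
                break
            except (GeometryError, ValueError) as err:
                logger.debug("rejected jittered spec (attempt %d): %s", attempt, err)
        else:
            raise GeometryError(
                f"could not draw a valid phantom spec in {max_retries} tries"
            )
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 0), n)
    if n > 1:
        n_train = min(max(n_train, 1), n - 1)
    return PhantomDataset(
        train=triplets[:n_train], validation=triplets[n_train:], specs=specs
    )
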