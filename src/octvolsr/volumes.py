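"""Volume data model and scan-grid arithmetic for undersampled OCT C-scans.

A C-scan is stored as a 3D intensity grid indexed ``(X, Y, Z)`` where X is
the axial (A-scan) axis, Y the fast lateral galvo axis and Z the slow lateral
galvo axis.  The acquisition scheme this package targets records a sparse
lateral raster (every 4th A-scan along both lateral axes) and reconstructs
the dense grid computationally, so the central data contract is the
low / mid / high resolution triplet tied together by exact sub-grid
selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

AXIS_LABELS = ("X", "Y", "Z")


class DegenerateRangeError(ValueError):
    """Raised when min-max normalization is requested on a constant volume."""


class ShapeContractError(ValueError):
    """Raised when a volume's extents violate a divisibility contract."""


@dataclass
class Volume:
    """A 3D OCT intensity volume with fixed axis semantics.

    Parameters
    ----------
    data:
        3D array indexed ``(X, Y, Z)`` = (axial, fast, slow).  Stored as
        ``float32``; all values must be finite.
    axis_labels:
        Semantic tags for the three axes; fixed to ``("X", "Y", "Z")``.
    """

    data: np.ndarray
    axis_labels: tuple[str, str, str] = AXIS_LABELS

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(
                f"Volume requires a 3D (X, Y, Z) array, got {arr.ndim} axes"
            )
        if arr.size == 0:
            raise ValueError("Volume axes must all have extent >= 1")
        arr = arr.astype(np.float32, copy=False)
        if not np.all(np.isfinite(arr)):
            raise ValueError("Volume values must be finite")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def nx(self) -> int:
        return self.data.shape[0]

    @property
    def ny(self) -> int:
        return self.data.shape[1]

    @property
    def nz(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "Volume":
        return Volume(self.data.copy())


@dataclass(frozen=True)
class ScanGrid:
    """Voxel counts plus physical extents of a raster scan.

    The default values describe the undersampled acquisition grid:
    1024 x 256 x 32 voxels covering 3.6 mm (axial) x 7 mm x 7 mm with a
    25.8 um lateral spot size.
    """

    nx: int = 1024
    ny: int = 256
    nz: int = 32
    extent_x_mm: float = 3.6
    extent_y_mm: float = 7.0
    extent_z_mm: float = 7.0
    lateral_resolution_um: float = 25.8

    def __post_init__(self) -> None:
        for name in ("nx", "ny", "nz"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        for name in (
            "extent_x_mm",
            "extent_y_mm",
            "extent_z_mm",
            "lateral_resolution_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def voxel_count(self) -> int:
        return self.nx * self.ny * self.nz

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)


FULL_GRID = ScanGrid(nx=1024, ny=1024, nz=128)
SPARSE_GRID = ScanGrid(nx=1024, ny=256, nz=32)


@dataclass
class ResolutionTriplet:
    """Low / mid / high resolution views of one ground-truth volume.

    ``low`` keeps every 4th fast-axis and every 4th slow-axis A-scan of
    ``high``; ``mid`` is the intermediate grid that is dense along Y but
    sparse along Z (the target of the fast-axis upsampling stage).
    """

    low: Volume
    mid: Volume
    high: Volume

    def __post_init__(self) -> None:
        lo, mi, hi = self.low.shape, self.mid.shape, self.high.shape
        ok = (
            lo[1] * 4 == mi[1]
            and mi[0] == hi[0]
            and lo[0] == hi[0]
            and mi[1] == hi[1]
            and mi[2] * 4 == hi[2]
            and lo[2] == mi[2]
        )
        if not ok:
            raise ShapeContractError(
                f"triplet shape contract violated: low={lo} mid={mi} high={hi}"
            )


def normalize(vol: Volume) -> Volume:
    """Min-max rescale a volume affinely onto [0, 1].

    Raises
    ------
    DegenerateRangeError
        If the volume is constant (zero dynamic range cannot be rescaled).
    """
    lo = float(vol.data.min())
    hi = float(vol.data.max())
    if hi == lo:
        raise DegenerateRangeError(
            f"cannot min-max normalize a constant volume (value {lo})"
        )
    out = (vol.data - lo) / (hi - lo)
    return Volume(out.astype(np.float32))


def downsample_grid(
    vol: Volume, step_y: int = 1, step_z: int = 1, prefilter: bool = False
) -> Volume:
    """Sparsely select A-scans with the given steps along Y and Z.

    Keeps indices ``0, step, 2*step, ...`` along each lateral axis; the axial
    axis is untouched.  By default no low-pass prefilter is applied — the
    selection emulates a scanner that simply visits fewer lateral positions
    with an unchanged spot size.  ``prefilter=True`` applies a Gaussian
    (sigma = step/2 per decimated axis) before selection, for experiments
    on the aliasing/noise trade-off.
    """
    if step_y < 1 or step_z < 1:
        raise ValueError("steps must be >= 1")
    for step, axis, n in ((step_y, "Y", vol.ny), (step_z, "Z", vol.nz)):
        if step > n:
            logger.warning(
                "step %d exceeds %s extent %d; output keeps a single slice",
                step,
                axis,
                n,
            )
    data = vol.data
    if prefilter and (step_y > 1 or step_z > 1):
        from scipy import ndimage

        sigma = (0.0, step_y / 2 if step_y > 1 else 0.0, step_z / 2 if step_z > 1 else 0.0)
        data = ndimage.gaussian_filter(data, sigma)
    return Volume(data[:, ::step_y, ::step_z].copy())


def make_triplet(high: Volume) -> ResolutionTriplet:
    """Build the low/mid/high training triplet from a dense volume.

    ``mid`` drops slow-axis B-scans (Z step 4); ``low`` additionally drops
    fast-axis A-scans (Y step 4).  Both lateral extents of ``high`` must be
    divisible by 4 so the three grids nest exactly.
    """
    for axis, n in (("Y", high.ny), ("Z", high.nz)):
        if n % 4 != 0:
            raise ShapeContractError(
                f"high-resolution {axis} extent {n} is not divisible by 4"
            )
    mid = downsample_grid(high, step_y=1, step_z=4)
    low = downsample_grid(mid, step_y=4, step_z=1)
    return ResolutionTriplet(low=low, mid=mid, high=high)


def nyquist_min_samples(grid: ScanGrid, axis: str = "Y") -> int:
    """Minimum lateral sample count satisfying the Nyquist criterion.

    Two samples per resolvable element: ``round(extent / resolution * 2)``.
    For a 7 mm field at 25.8 um lateral resolution this is 543 samples.
    """
    extent_mm = {"Y": grid.extent_y_mm, "Z": grid.extent_z_mm}[axis.upper()]
    resolution_mm = grid.lateral_resolution_um * 1e-3
    return round(extent_mm / resolution_mm * 2)


def nyquist_coverage(grid: ScanGrid) -> dict[str, float]:
    """Fraction of the Nyquist-required sample count actually acquired.

    Returns per-axis fractions, e.g. 256/543 ~ 0.47 along the fast axis and
    32/543 ~ 0.06 along the slow axis for the sparse acquisition grid.
    """
    return {
        "Y": grid.ny / nyquist_min_samples(grid, "Y"),
        "Z": grid.nz / nyquist_min_samples(grid, "Z"),
    }


def sampling_fraction(sub: ScanGrid, full: ScanGrid) -> float:
    """Voxel-count ratio between an undersampled grid and the dense grid."""
    if full.voxel_count == 0:
        raise ZeroDivisionError("full grid has zero voxels")
    if sub.nx > full.nx or sub.ny > full.ny or sub.nz > full.nz:
        raise ValueError("sub grid exceeds full grid along some axis")
    return sub.voxel_count / full.voxel_count
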