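"""Volume file I/O: multi-page TIFF, NIfTI-1 and NPZ.

Axis order on disk
------------------
The in-memory contract is ``(X, Y, Z)``.  TIFF stacks store one page per Z
slice (page shape X x Y), which is the natural B-scan browsing order for OCT
viewers.  NIfTI and NPZ store the array in its native (X, Y, Z) order.
Round-trips are bit-exact at float32 precision.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .volumes import Volume

FORMATS = ("tiff", "nifti", "npz")
_SUFFIXES = {
    ".tif": "tiff",
    ".tiff": "tiff",
    ".nii": "nifti",
    ".gz": "nifti",  # .nii.gz
    ".npz": "npz",
}
NPZ_KEY = "volume"


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        f = fmt.lower()
        if f not in FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
        return f
    f = _SUFFIXES.get(path.suffix.lower())
    if f is None:
        raise ValueError(f"cannot infer volume format from suffix of {path}")
    return f


def write_volume(vol: Volume, path: str | Path, fmt: str | None = None) -> Path:
    """Write a volume to TIFF / NIfTI / NPZ (format inferred from suffix)."""
    path = Path(path)
    f = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if f == "tiff":
        # pages indexed by Z, each page an (X, Y) B-scan
        tifffile.imwrite(path, np.moveaxis(vol.data, 2, 0))
    elif f == "nifti":
        img = nib.Nifti1Image(vol.data, affine=np.eye(4))
        img.header.set_data_dtype(np.float32)
        nib.save(img, path)
    else:
        np.savez(path, **{NPZ_KEY: vol.data})
    return path


def read_volume(path: str | Path, fmt: str | None = None) -> Volume:
    """Read a volume written by :func:`write_volume`.

    Rejects arrays that are not 3D; a 2D image is not a C-scan.
    """
    path = Path(path)
    f = _infer_format(path, fmt)
    if not path.exists():
        raise FileNotFoundError(path)
    if f == "tiff":
        arr = tifffile.imread(path)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-axis TIFF stack, got {arr.ndim} axes")
        arr = np.moveaxis(arr, 0, 2)
    elif f == "nifti":
        arr = np.asarray(nib.load(path).dataobj)
    else:
        with np.load(path) as z:
            keys = list(z.keys())
            key = NPZ_KEY if NPZ_KEY in keys else keys[0]
            arr = z[key]
    if arr.ndim != 3:
        raise ValueError(f"volume file must hold a 3D array, got {arr.ndim} axes")
    return Volume(np.asarray(arr, dtype=np.float32))
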