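"""Reading and writing of multi-echo stacks, parametric maps and tables.

The pipeline's on-disk interchange formats are NIfTI (``.nii``/``.nii.gz``)
and multi-page TIFF for image data, CSV for tables and JSON for the
acquisition descriptor.  Conventions used throughout the package:

* echo index is 1-based in the physics (``Te_i = i * te``) and 0-based in
  arrays; array index ``k`` corresponds to echo ``i = k + 1``;
* pixel coordinates are ``(row, column)``, 0-based, row increasing downward;
* invalid pixels in written maps are encoded with the sentinel ``-1.0``
  (every physical quantity written here is non-negative).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

#: Sentinel written to maps in place of invalid (non-fitted / trimmed) pixels.
INVALID_SENTINEL = -1.0

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_TIFF_SUFFIXES = (".tif", ".tiff")


class FormatError(ValueError):
    """The file cannot be parsed in any supported format."""


class DescriptorMismatchError(ValueError):
    """File contents disagree with the acquisition descriptor."""


class EncodingError(ValueError):
    """Array values cannot be represented losslessly in the target format."""


@dataclass(frozen=True)
class AcquisitionDescriptor:
    """Multi-spin multi-echo acquisition parameters.

    ``te_spacing`` is the uniform inter-echo spacing ``te`` (ms), so echo
    ``i`` is sampled at ``Te_i = i * te``.  ``tr``, ``field_of_view`` and
    ``slice_thickness`` are carried as metadata for volume conversion.
    """

    te_spacing: float
    n_echoes: int
    tr: float = 752.0
    field_of_view: tuple[float, float] = (40.0, 40.0)
    slice_thickness: float = 0.9

    def __post_init__(self) -> None:
        if self.te_spacing <= 0:
            raise ValueError(f"te_spacing must be > 0, got {self.te_spacing}")
        if self.n_echoes < 2:
            raise ValueError(f"n_echoes must be >= 2, got {self.n_echoes}")

    @property
    def echo_times(self) -> np.ndarray:
        """Echo times ``Te_i = i * te`` (ms), for i = 1..n_echoes."""
        return self.te_spacing * np.arange(1, self.n_echoes + 1, dtype=float)

    def with_n_echoes(self, n_echoes: int) -> "AcquisitionDescriptor":
        return dataclasses.replace(self, n_echoes=n_echoes)

    def pixel_area_mm2(self, shape: tuple[int, int]) -> float:
        """In-plane pixel area (mm^2) for an image of the given shape."""
        return (self.field_of_view[0] / shape[0]) * (self.field_of_view[1] / shape[1])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["field_of_view"] = list(self.field_of_view)
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionDescriptor":
        payload = json.loads(Path(path).read_text())
        payload["field_of_view"] = tuple(payload["field_of_view"])
        return cls(**payload)


@dataclass
class EchoStack:
    """A multi-echo image stack: ``data[k]`` is the image at echo ``k + 1``.

    Raw scans are non-negative; stacks that have been through synthetic
    noise injection may carry negative values (noise is never clipped), so
    only finiteness is enforced here.
    """

    data: np.ndarray
    descriptor: AcquisitionDescriptor

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3-D (echo, row, col) data, got shape {self.data.shape}")
        if self.data.shape[0] != self.descriptor.n_echoes:
            raise DescriptorMismatchError(
                f"stack has {self.data.shape[0]} echoes, descriptor says "
                f"{self.descriptor.n_echoes}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")

    @property
    def first_echo(self) -> np.ndarray:
        """The first-echo image, the highest-SNR member of the echo train."""
        return self.data[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


def _suffix_kind(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        return "nifti"
    if name.endswith(_TIFF_SUFFIXES):
        return "tiff"
    raise FormatError(f"unsupported file extension for {path}")


def _read_array(path: Path) -> np.ndarray:
    kind = _suffix_kind(path)
    try:
        if kind == "nifti":
            img = nib.load(str(path))
            return np.asarray(img.dataobj, dtype=float)
        return np.asarray(tifffile.imread(str(path)), dtype=float)
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"cannot read {path}: {exc}") from exc


def read_echo_stack(path: str | Path, descriptor: AcquisitionDescriptor) -> EchoStack:
    """Read a multi-echo stack from NIfTI (3rd axis = echo) or TIFF (pages)."""
    path = Path(path)
    arr = _read_array(path)
    if _suffix_kind(path) == "nifti":
        if arr.ndim != 3:
            raise FormatError(f"NIfTI stack must be 3-D, got shape {arr.shape}")
        arr = np.transpose(arr, (2, 0, 1))  # (row, col, echo) -> (echo, row, col)
    else:
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise FormatError(f"TIFF stack must have one page per echo, got shape {arr.shape}")
    if arr.shape[0] != descriptor.n_echoes:
        raise DescriptorMismatchError(
            f"file holds {arr.shape[0]} echoes, descriptor says {descriptor.n_echoes}"
        )
    return EchoStack(arr, descriptor)


def write_echo_stack(stack: EchoStack, path: str | Path) -> Path:
    """Write a stack so that :func:`read_echo_stack` round-trips it exactly."""
    path = Path(path)
    kind = _suffix_kind(path)
    if stack.data.shape[0] == 0:
        raise ValueError("refusing to write an empty (0-echo) stack")
    if kind == "nifti":
        img = nib.Nifti1Image(np.transpose(stack.data, (1, 2, 0)), affine=np.eye(4))
        nib.save(img, str(path))
    else:
        tifffile.imwrite(str(path), stack.data)
    return path


def write_map(map2d: np.ndarray, path: str | Path) -> Path:
    """Persist a single 2-D map (T2, S0, confidence, label, mask) to NIfTI/TIFF.

    NaN values are rejected: encode invalid pixels with
    :data:`INVALID_SENTINEL` (via :func:`encode_invalid`) before writing.
    """
    path = Path(path)
    arr = np.asarray(map2d, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"write_map expects a 2-D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise EncodingError(
            "map contains NaN/inf; encode invalid pixels with the -1 sentinel first"
        )
    kind = _suffix_kind(path)
    if kind == "nifti":
        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
    else:
        tifffile.imwrite(str(path), arr)
    return path


def read_map(path: str | Path) -> np.ndarray:
    arr = _read_array(Path(path))
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise FormatError(f"expected a single 2-D map in {path}, got shape {arr.shape}")
    return arr


def encode_invalid(map2d: np.ndarray, valid_mask: np.ndarray) -> np.ndarray:
    """Return a copy with pixels outside ``valid_mask`` set to the sentinel."""
    out = np.asarray(map2d, dtype=float).copy()
    out[~np.asarray(valid_mask, dtype=bool)] = INVALID_SENTINEL
    return out


def write_table(frame: pd.DataFrame, path: str | Path) -> Path:
    """Persist a table (region scores, calibration sweep, ...) as headered CSV."""
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
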