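"""In-memory image containers and NIfTI I/O.

An :class:`ImageVolume` is a 3-D grid of values with isotropic-or-not voxel
spacing in mm and a semantic ``kind`` tag that records what the voxels mean
(counts, activity, time-integrated activity, dose, density).  Operations in
the package change the tag only through defined transitions (quantification
turns counts into activity, dose engines turn TIA into dose, ...).

A :class:`LabelMap` is an integer organ segmentation on the same grid with a
catalogue mapping each label to an organ name and mass density.  Label 0 is
reserved for background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np

from .errors import ConfigurationError, InvalidInputError, TableLookupError

#: Allowed semantic tags for ImageVolume.
VOLUME_KINDS = ("counts", "activity_MBq", "TIA_MBqh", "dose_Gy", "density_gcc")


def _check_spacing(spacing) -> Tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise InvalidInputError(f"spacing must be 3 positive lengths (mm), got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """3-D value grid + voxel spacing (mm) + semantic tag."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    kind: str
    time_post_injection_h: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise InvalidInputError("ImageVolume data must be 3-D")
        self.spacing = _check_spacing(self.spacing)
        if self.kind not in VOLUME_KINDS:
            raise InvalidInputError(f"unknown volume kind {self.kind!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_geometry(self, other: "ImageVolume") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.spacing, other.spacing, rtol=1e-12, atol=0.0
        )

    def with_data(self, data: np.ndarray, kind: Optional[str] = None) -> "ImageVolume":
        return ImageVolume(data, self.spacing, kind or self.kind, self.time_post_injection_h)

    # -- I/O --------------------------------------------------------------
    def save(self, path) -> None:
        """Write as NIfTI-1; spacing goes into the affine, tag/time into extensions."""
        affine = np.diag(list(self.spacing) + [1.0])
        img = nib.Nifti1Image(self.data.astype(np.float64), affine)
        img.header["descrip"] = _descrip(self.kind, self.time_post_injection_h)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path, kind: Optional[str] = None) -> "ImageVolume":
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        stored_kind, time_h = _parse_descrip(img.header["descrip"].item())
        return cls(np.asanyarray(img.dataobj), spacing, kind or stored_kind or "counts", time_h)


def _descrip(kind: str, time_h: Optional[float]) -> bytes:
    s = f"dosekit kind={kind}"
    if time_h is not None:
        s += f" t_h={time_h:.6g}"
    return s.encode()[:79]


def _parse_descrip(raw) -> Tuple[Optional[str], Optional[float]]:
    try:
        text = raw.decode() if isinstance(raw, bytes) else str(raw)
    except Exception:
        return None, None
    kind = time_h = None
    for tok in text.split():
        if tok.startswith("kind="):
            kind = tok[5:]
        elif tok.startswith("t_h="):
            time_h = float(tok[4:])
    return kind, time_h


def apply_integer_shift(arr: np.ndarray, shift) -> np.ndarray:
    """Translate array content by an integer voxel shift, zero-filling.

    The voxel at index ``x`` moves to ``x + shift``; voxels shifted outside
    the grid are dropped and vacated voxels are zero.
    """
    shift = tuple(int(s) for s in shift)
    if len(shift) != arr.ndim:
        raise InvalidInputError("shift length must match array dimensionality")
    out = np.zeros_like(arr)
    src, dst = [], []
    for n, s in zip(arr.shape, shift):
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = arr[tuple(src)]
    return out


@dataclass(frozen=True)
class Organ:
    """Catalogue entry: integer label, name, mass density in g/cm^3."""

    label: int
    name: str
    density_gcc: float

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise InvalidInputError("organ labels must be positive (0 = background)")
        if not self.density_gcc > 0:
            raise InvalidInputError("density must be > 0 g/cm^3")


@dataclass
class LabelMap:
    """Integer organ segmentation + organ catalogue on an image grid."""

    data: np.ndarray
    spacing: Tuple[float, float, float]
    catalogue: Dict[int, Organ] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidInputError("LabelMap data must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InvalidInputError("LabelMap data must be integer-valued")
        self.spacing = _check_spacing(self.spacing)
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.catalogue)
        if missing:
            raise ConfigurationError(f"labels {sorted(missing)} absent from catalogue")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    def organ(self, label: int) -> Organ:
        try:
            return self.catalogue[int(label)]
        except KeyError:
            raise TableLookupError(f"label {label} not in organ catalogue") from None

    def mask(self, label: int) -> np.ndarray:
        self.organ(label)
        return self.data == int(label)

    def labels(self):
        """Sorted non-zero labels present in the catalogue."""
        return sorted(self.catalogue)

    def same_geometry(self, vol: ImageVolume) -> bool:
        return self.data.shape == vol.data.shape and np.allclose(
            self.spacing, vol.spacing, rtol=1e-12, atol=0.0
        )

    # -- I/O: label volume as NIfTI + catalogue as JSON sidecar -----------
    def save(self, path) -> None:
        path = Path(path)
        affine = np.diag(list(self.spacing) + [1.0])
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), affine), str(path))
        sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz / .nii
        cat = {
            str(o.label): {"name": o.name, "density_gcc": o.density_gcc}
            for o in self.catalogue.values()
        }
        Path(str(sidecar) + ".labels.json").write_text(json.dumps(cat, indent=2))

    @classmethod
    def load(cls, path) -> "LabelMap":
        path = Path(path)
        img = nib.load(str(path))
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".labels.json")
        catalogue: Dict[int, Organ] = {}
        if sidecar.exists():
            for lab, entry in json.loads(sidecar.read_text()).items():
                catalogue[int(lab)] = Organ(int(lab), entry["name"], entry["density_gcc"])
        data = np.asanyarray(img.dataobj).astype(np.int32)
        return cls(data, spacing, catalogue)
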