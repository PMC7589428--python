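"""Activity quantification: alignment, per-organ activity, masses, TACs.

This is the step that turns reconstructed count images plus a calibration
factor into per-organ activity samples at each time point.  Volumes of
interest are defined once (the label map, conventionally drawn on the first
time point) and propagated rigidly, so the organ volume -- and hence mass --
is constant across time points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .kinetics import TimeActivityCurve
from .units import AcquisitionMeta, CalibrationFactor, InjectedActivity
from .volumes import (  # noqa: F401  (re-exported: the quantify surface owns these types)
    ImageVolume,
    LabelMap,
    Organ,
    apply_integer_shift,
)


@dataclass(frozen=True)
class ShiftResult:
    """Integer displacement of `moving` relative to `reference` + NCC score."""

    shift: Tuple[int, int, int]
    score: float
    degenerate: bool = False


@dataclass(frozen=True)
class OrganSample:
    """One organ at one time point: activity, voxel count, constant mass."""

    label: int
    name: str
    time_h: float
    activity_MBq: float
    voxel_count: int
    mass_g: float


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_translation(
    moving: ImageVolume, reference: ImageVolume, search_radius: int = 5
) -> ShiftResult:
    """Find the integer voxel translation of `moving` relative to `reference`.

    Searches the cube of shifts within ``search_radius`` voxels per axis and
    returns the displacement ``d`` maximizing the normalized cross-correlation
    over the overlap region, i.e. ``moving`` looks like the reference content
    translated by ``+d``.  ``apply_integer_shift(moving.data, -d)`` therefore
    aligns the moving volume onto the reference.  Constant (degenerate)
    volumes return a zero shift with ``degenerate=True``.
    """
    if not moving.same_geometry(reference):
        raise InvalidInputError("volumes must share shape and spacing")
    if search_radius < 0:
        raise InvalidInputError("search_radius must be >= 0")
    mov, ref = moving.data, reference.data
    if np.ptp(mov) == 0 or np.ptp(ref) == 0:
        warnings.warn("degenerate (constant) volume: returning zero shift")
        return ShiftResult((0, 0, 0), 0.0, degenerate=True)

    best_shift, best_score = (0, 0, 0), -np.inf
    r = int(search_radius)
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                sl_ref, sl_mov = [], []
                ok = True
                for n, d in zip(ref.shape, (dx, dy, dz)):
                    if abs(d) >= n:
                        ok = False
                        break
                    # moving = reference shifted by +d  =>  mov[x] ~ ref[x-d]
                    if d >= 0:
                        sl_ref.append(slice(0, n - d))
                        sl_mov.append(slice(d, n))
                    else:
                        sl_ref.append(slice(-d, n))
                        sl_mov.append(slice(0, n + d))
                if not ok:
                    continue
                score = _ncc(ref[tuple(sl_ref)], mov[tuple(sl_mov)])
                if score > best_score + 1e-15 or (
                    np.isclose(score, best_score)
                    and sum(abs(v) for v in (dx, dy, dz)) < sum(abs(v) for v in best_shift)
                ):
                    best_score, best_shift = score, (dx, dy, dz)
    return ShiftResult(best_shift, best_score)


def organ_mass(labels: LabelMap, label: int) -> float:
    """Organ mass in grams: voxel count x voxel volume (cm^3) x density."""
    organ = labels.organ(label)
    n = int((labels.data == label).sum())
    return n * labels.voxel_volume_cm3 * organ.density_gcc


def voi_activity(
    counts: ImageVolume,
    labels: LabelMap,
    cf: CalibrationFactor,
    acquisition: Optional[AcquisitionMeta] = None,
) -> List[OrganSample]:
    """Per-organ activity at one time point.

    activity = (sum of counts in the VOI) x (MBq per count), where the
    calibration factor is rescaled to this acquisition's total duration.
    The result is independent of the unit kind the factor is expressed in
    and additive over disjoint VOIs.
    """
    if counts.kind != "counts":
        raise ConfigurationError(f"expected a counts volume, got kind={counts.kind!r}")
    if not labels.same_geometry(counts):
        raise ConfigurationError("label map and counts volume geometry differ")
    mbq_per_count = cf.mbq_per_count(acquisition)
    samples = []
    t = counts.time_post_injection_h
    if t is None and acquisition is not None:
        t = acquisition.time_post_injection_h
    for label in labels.labels():
        organ = labels.organ(label)
        mask = labels.data == label
        total_counts = float(counts.data[mask].sum())
        samples.append(
            OrganSample(
                label=label,
                name=organ.name,
                time_h=float(t) if t is not None else float("nan"),
                activity_MBq=total_counts * mbq_per_count,
                voxel_count=int(mask.sum()),
                mass_g=organ_mass(labels, label),
            )
        )
    return samples


def build_tac(
    samples: Iterable[OrganSample], a0: InjectedActivity
) -> Dict[int, TimeActivityCurve]:
    """Group per-time-point samples into one time-activity curve per organ.

    Samples may arrive unsorted; output times are sorted and must be unique
    per organ.
    """
    by_organ: Dict[int, List[OrganSample]] = {}
    names: Dict[int, str] = {}
    for s in samples:
        by_organ.setdefault(s.label, []).append(s)
        names[s.label] = s.name
    tacs: Dict[int, TimeActivityCurve] = {}
    for label, group in sorted(by_organ.items()):
        group = sorted(group, key=lambda s: s.time_h)
        times = np.array([s.time_h for s in group])
        if np.any(np.diff(times) <= 0):
            raise InvalidInputError(f"duplicate acquisition times for organ {names[label]!r}")
        tacs[label] = TimeActivityCurve(
            label=label,
            name=names[label],
            times_h=times,
            activities_MBq=np.array([s.activity_MBq for s in group]),
            a0_MBq=a0.a0_MBq,
        )
    return tacs


def samples_to_frame(samples: Sequence[OrganSample]) -> pd.DataFrame:
    """Tabular export schema: organ, time_h, activity_MBq, voxel_count, mass_g."""
    return pd.DataFrame(
        [
            {
                "organ": s.name,
                "label": s.label,
                "time_h": s.time_h,
                "activity_MBq": s.activity_MBq,
                "voxel_count": s.voxel_count,
                "mass_g": s.mass_g,
            }
            for s in samples
        ]
    )
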