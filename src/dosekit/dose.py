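"""Absorbed-dose engines: S values, local energy deposition, kernel convolution.

Organ-level dosimetry follows the standard source/target formalism: the
mean absorbed dose to a target region is the sum over source regions of
(number of nuclear transformations in the source) x (S value, the mean
dose to the target per transformation in the source).  S values are
tabulated for reference anatomies, so the self-dose term is rescaled by
reference mass / patient mass when patient organ masses are known.

Voxel-level dosimetry starts from a time-integrated-activity (TIA) map:

* **LED** (local energy deposition) assumes every transformation deposits
  its non-penetrating energy in the voxel where it occurs, divided by the
  voxel mass (with per-voxel density correction);
* **DVK** (dose-voxel-kernel) convolution spreads each voxel's energy
  according to a precomputed kernel for a homogeneous water medium, with an
  optional first-order density correction.

A kernel of radius 0 is exactly the LED model in water, which ties the two
voxel engines together.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate, signal

from .errors import (
    ConfigurationError,
    InvalidInputError,
    NormalizationError,
    TableLookupError,
)
from .units import DECAYS_PER_MBQ_H, Radionuclide
from .volumes import ImageVolume, LabelMap

WATER_DENSITY_GCC = 1.0


# ---------------------------------------------------------------------------
# S-value engine
# ---------------------------------------------------------------------------

@dataclass
class SValueTable:
    """(source, target) -> S value in Gy/(MBq.h), plus reference masses (g).

    Pluggable via CSV with columns ``source,target,S_Gy_per_MBqh,ref_mass_g``
    (the reference mass is read from the self-dose rows).
    """

    nuclide_name: str
    s_Gy_per_MBqh: Dict[Tuple[str, str], float]
    ref_masses_g: Dict[str, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.s_Gy_per_MBqh.values()):
            raise InvalidInputError("S values must be >= 0")
        if any(m <= 0 for m in self.ref_masses_g.values()):
            raise InvalidInputError("reference masses must be > 0 g")

    def s(self, target: str, source: str) -> float:
        try:
            return self.s_Gy_per_MBqh[(source, target)]
        except KeyError:
            raise TableLookupError(
                f"no S value for source={source!r} -> target={target!r}"
            ) from None

    @classmethod
    def from_csv(cls, path, nuclide_name: str = "", provenance: str = "") -> "SValueTable":
        df = pd.read_csv(path)
        s = {(r.source, r.target): float(r.S_Gy_per_MBqh) for r in df.itertuples()}
        masses = {
            r.target: float(r.ref_mass_g)
            for r in df.itertuples()
            if r.source == r.target and not pd.isna(r.ref_mass_g)
        }
        return cls(nuclide_name, s, masses, provenance or str(path))

    def to_csv(self, path) -> None:
        rows = [
            {
                "source": src,
                "target": tgt,
                "S_Gy_per_MBqh": val,
                "ref_mass_g": self.ref_masses_g.get(tgt) if src == tgt else None,
            }
            for (src, tgt), val in sorted(self.s_Gy_per_MBqh.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def svalue_dose(
    tiacs_h: Dict[str, float],
    a0_MBq: float,
    table: SValueTable,
    patient_masses_g: Dict[str, float],
    targets: Optional[Sequence[str]] = None,
    scale_cross_dose: bool = False,
) -> Dict[str, float]:
    """Mean organ doses (Gy) from TIACs and an S-value table.

    D(target) = sum_sources A0 * TIAC(source) * S(target <- source) * adj,
    with adj = ref_mass(target)/patient_mass(target) applied to the
    self-dose term (and, if ``scale_cross_dose``, to cross terms too --
    different platform generations differ here).
    """
    if not a0_MBq > 0:
        raise InvalidInputError("A0 must be > 0 MBq")
    sources = [s for s, v in tiacs_h.items() if v != 0.0]
    targets = list(targets) if targets is not None else sorted(tiacs_h)
    doses: Dict[str, float] = {}
    for tgt in targets:
        if tgt not in patient_masses_g or not patient_masses_g[tgt] > 0:
            raise InvalidInputError(f"missing or non-positive patient mass for {tgt!r}")
        mass_adj = table.ref_masses_g.get(tgt)
        if mass_adj is None:
            raise TableLookupError(f"no reference mass for target {tgt!r}")
        adj_self = mass_adj / patient_masses_g[tgt]
        total = 0.0
        for src in sources:
            adj = adj_self if (src == tgt or scale_cross_dose) else 1.0
            total += a0_MBq * tiacs_h[src] * table.s(tgt, src) * adj
        doses[tgt] = total
    return doses


# ---------------------------------------------------------------------------
# voxel engines
# ---------------------------------------------------------------------------

def _led_scale_water(voxvol_cm3: float, energy_j: float) -> float:
    """Gy per MBq.h for one voxel of water: decays x E / voxel mass (kg)."""
    voxel_mass_kg = voxvol_cm3 * WATER_DENSITY_GCC * 1e-3
    return DECAYS_PER_MBQ_H * energy_j / voxel_mass_kg


def _density_correct(dose: np.ndarray, tia: np.ndarray, density: ImageVolume) -> np.ndarray:
    rel = density.data / WATER_DENSITY_GCC
    bad = (rel <= 0) & (tia > 0)
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise InvalidInputError(f"zero/negative density with nonzero TIA at voxel {idx}")
    out = np.zeros_like(dose)
    np.divide(dose, rel, out=out, where=rel > 0)
    return out


def led_dose(
    tia_map: ImageVolume, density: ImageVolume, nuclide: Radionuclide
) -> ImageVolume:
    """Local-energy-deposition dose map with per-voxel density correction.

    dose(voxel) = TIA [MBq.h] x 3.6e9 decays/(MBq.h) x E_local [J]
                  / (density x voxel volume) [kg].
    """
    if tia_map.kind != "TIA_MBqh":
        raise ConfigurationError("led_dose expects a TIA map")
    if not tia_map.same_geometry(density):
        raise InvalidInputError("TIA and density maps must share geometry")
    energy = nuclide.require_energy()
    scale = _led_scale_water(tia_map.voxel_volume_cm3, energy)
    dose = tia_map.data * scale
    dose = _density_correct(dose, tia_map.data, density)
    return ImageVolume(dose, tia_map.spacing, "dose_Gy")


@dataclass
class DoseKernel:
    """Odd-sized voxel dose kernel: Gy per MBq.h in the source's center voxel."""

    values: np.ndarray
    spacing: Tuple[float, float, float]
    energy_fraction: float  # fraction of E_local contained in the grid
    medium: str = "water"
    nuclide_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or any(n % 2 == 0 for n in self.values.shape):
            raise InvalidInputError("kernel must be 3-D with odd side lengths")
        center = tuple(n // 2 for n in self.values.shape)
        if self.values[center] < self.values.max():
            raise InvalidInputError("kernel center voxel must hold the maximum")

    @property
    def is_point(self) -> bool:
        return self.values.size == 1


def exponential_profile(scale_mm: float):
    """Isotropic exponential deposition density p(r) ~ exp(-r/scale).

    Returned unnormalized; kernel construction divides by the continuous
    integral over all space.  The default 0.3 mm scale reflects the
    sub-voxel electron range of Lu-177 at typical SPECT voxel sizes.
    """
    if not scale_mm > 0:
        raise InvalidInputError("profile scale must be > 0 mm")
    return lambda r_mm: np.exp(-np.asarray(r_mm, dtype=float) / scale_mm)


def build_water_kernel(
    nuclide: Radionuclide,
    spacing: Tuple[float, float, float],
    radius_voxels: int,
    profile=None,
    scale_mm: float = 0.3,
    truncation_tol: float = 0.005,
    subsample: int = 7,
) -> DoseKernel:
    """Construct a water dose-voxel kernel from an isotropic deposition profile.

    The profile (a radial energy-deposition density, any positive scaling) is
    normalized by its continuous integral over all space; each kernel voxel
    receives the profile's integral over the voxel (midpoint quadrature with
    ``subsample``^3 points per voxel).  The kernel's total energy must equal
    E_local within ``truncation_tol``; radius 0 collapses to the pure-LED
    single-voxel kernel.
    """
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise InvalidInputError("spacing must be positive")
    if radius_voxels < 0:
        raise InvalidInputError("radius must be >= 0 voxels")
    energy = nuclide.require_energy()
    voxvol_cm3 = float(np.prod(spacing)) / 1000.0
    led_peak = _led_scale_water(voxvol_cm3, energy)

    if radius_voxels == 0:
        return DoseKernel(
            np.array([[[led_peak]]]), spacing, energy_fraction=1.0,
            nuclide_name=nuclide.name,
        )

    p = profile if profile is not None else exponential_profile(scale_mm)
    probe = np.asarray(p(np.linspace(0.0, 4.0 * max(spacing) * (radius_voxels + 1), 257)))
    if np.any(probe < 0):
        raise NormalizationError("deposition profile must be non-negative")
    cont, _ = integrate.quad(
        lambda r: 4.0 * math.pi * r * r * float(p(r)), 0.0, np.inf,
        epsabs=0.0, epsrel=1e-8, limit=500,
    )
    if not np.isfinite(cont) or cont <= 0:
        raise NormalizationError("deposition profile has no finite positive integral")

    # Discrete voxel weights are normalized by the same midpoint quadrature
    # extended over a grid that captures essentially all of the profile, so
    # the quadrature bias cancels and the fractions sum to <= 1 exactly.
    reach = _profile_reach_mm(p, cont)  # ~99% radius
    r_ext = max(radius_voxels, int(math.ceil(2.0 * reach / min(spacing))) + 1)
    # finer subsampling for profiles much narrower than a voxel
    sub_eff = int(max(subsample, min(41, math.ceil(6.0 * max(spacing) / reach))))
    w_ext = _voxel_weights(p, spacing, r_ext, sub_eff)
    norm = float(w_ext.sum())
    lo, hi = r_ext - radius_voxels, r_ext + radius_voxels + 1
    frac = w_ext[lo:hi, lo:hi, lo:hi] / norm
    total = float(frac.sum())
    if total < 1.0 - truncation_tol:
        raise NormalizationError(
            f"kernel truncation {1.0 - total:.4%} exceeds tolerance "
            f"{truncation_tol:.2%}; increase radius or narrow the profile"
        )
    values = led_peak * frac
    return DoseKernel(values, spacing, energy_fraction=total, nuclide_name=nuclide.name)


def _profile_reach_mm(p, cont_integral: float) -> float:
    """Radius containing ~99% of the profile's integral (bisection)."""
    lo, hi = 1e-3, 1.0
    f = lambda R: integrate.quad(
        lambda r: 4.0 * math.pi * r * r * float(p(r)), 0.0, R, epsabs=0.0,
        epsrel=1e-8, limit=500,
    )[0]
    while f(hi) < 0.99 * cont_integral and hi < 1e4:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0.99 * cont_integral:
            lo = mid
        else:
            hi = mid
    return hi


def _voxel_weights(p, spacing, radius: int, subsample: int) -> np.ndarray:
    """Midpoint-quadrature integral of the radial density over each voxel."""
    n = 2 * radius + 1
    off = (np.arange(subsample) + 0.5) / subsample - 0.5  # voxel units
    sub = [((np.arange(n) - radius)[:, None] + off[None, :]) * s for s in spacing]
    z2 = sub[2] ** 2  # (n, S)
    w = np.empty((n, n, n))
    voxvol_mm3 = float(np.prod(spacing))
    for i in range(n):
        x2 = sub[0][i] ** 2
        for j in range(n):
            y2 = sub[1][j] ** 2
            rr = np.sqrt(
                x2[:, None, None, None] + y2[None, :, None, None] + z2[None, None, :, :]
            )
            vals = np.asarray(p(rr))
            if np.any(vals < 0):
                raise NormalizationError("deposition profile must be non-negative")
            w[i, j, :] = vals.mean(axis=(0, 1, 3)) * voxvol_mm3
    return w


def dvk_dose(
    tia_map: ImageVolume,
    kernel: DoseKernel,
    density: Optional[ImageVolume] = None,
) -> ImageVolume:
    """Dose map by zero-padded linear convolution of the TIA map with a DVK.

    Kernel and map spacings must match exactly (matched spatial sampling; no
    resampling is implied).  When ``density`` is given, a first-order
    correction divides each voxel's dose by its density relative to water.
    With the radius-0 kernel and a density map the result equals
    :func:`led_dose` exactly.
    """
    if tia_map.kind != "TIA_MBqh":
        raise ConfigurationError("dvk_dose expects a TIA map")
    if not np.allclose(tia_map.spacing, kernel.spacing, rtol=1e-12, atol=0.0):
        raise InvalidInputError(
            f"kernel spacing {kernel.spacing} does not match map spacing {tia_map.spacing}"
        )
    if kernel.is_point:
        dose = tia_map.data * kernel.values.ravel()[0]
    else:
        dose = signal.fftconvolve(tia_map.data, kernel.values, mode="same")
        np.maximum(dose, 0.0, out=dose)  # clip FFT round-off below zero
    if density is not None:
        if not tia_map.same_geometry(density):
            raise InvalidInputError("TIA and density maps must share geometry")
        dose = _density_correct(dose, tia_map.data, density)
    return ImageVolume(dose, tia_map.spacing, "dose_Gy")


# ---------------------------------------------------------------------------
# DVH and reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram: fraction of the VOI receiving >= dose."""

    dose_Gy: np.ndarray
    fraction: np.ndarray

    def at(self, dose_Gy: float) -> float:
        """Fraction of the VOI receiving at least ``dose_Gy``."""
        idx = np.searchsorted(self.dose_Gy, dose_Gy, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.fraction[idx])


def dvh(
    dose_map: ImageVolume,
    labels: LabelMap,
    label: int,
    bin_width_Gy: float = 0.01,
) -> Tuple[DVH, float]:
    """Cumulative DVH and mean dose over one organ's VOI.

    The DVH starts at 1.0 and is monotone non-increasing; the mean dose is
    the plain voxel mean over the VOI (computed from the map, not the
    histogram).
    """
    if not labels.same_geometry(dose_map):
        raise InvalidInputError("dose map and label map geometry differ")
    if not bin_width_Gy > 0:
        raise InvalidInputError("bin width must be > 0 Gy")
    values = dose_map.data[labels.mask(label)]
    if values.size == 0:
        raise InvalidInputError(f"organ label {label} has an empty VOI")
    top = float(values.max())
    n_bins = max(int(math.ceil(top / bin_width_Gy)) + 1, 2)
    edges = np.round(np.arange(n_bins + 1) * bin_width_Gy, 12)
    # fraction of voxels with dose >= edge
    frac = 1.0 - np.searchsorted(np.sort(values), edges, side="left") / values.size
    return DVH(edges, frac), float(values.mean())


@dataclass
class DoseReport:
    """Per-organ dosimetry summary for one engine (+ optional map and DVHs)."""

    engine: str
    rows: pd.DataFrame  # columns: organ, label, mass_g, tiac_h, mean_dose_Gy
    dose_map: Optional[ImageVolume] = None
    dvhs: Dict[int, DVH] = field(default_factory=dict)

    REQUIRED = ("organ", "label", "mass_g", "tiac_h", "mean_dose_Gy")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ConfigurationError(f"DoseReport rows missing columns {missing}")

    def to_csv(self, path) -> None:
        out = self.rows.copy()
        out.insert(0, "engine", self.engine)
        out.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "engine": self.engine,
            "organs": self.rows.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_csv(cls, path) -> "DoseReport":
        df = pd.read_csv(path)
        engine = str(df["engine"].iloc[0]) if "engine" in df.columns else "unknown"
        return cls(engine, df.drop(columns=[c for c in ("engine",) if c in df.columns]))


def mean_organ_doses(
    dose_map: ImageVolume, labels: LabelMap
) -> Dict[int, float]:
    """Voxel-mean dose per organ VOI."""
    return {
        lab: float(dose_map.data[labels.data == lab].mean()) for lab in labels.labels()
    }
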