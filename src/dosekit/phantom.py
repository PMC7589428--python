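"""Synthetic digital abdominal phantom with analytic ground truth.

The generator emulates a quantitative SPECT/CT dosimetry study of a
Lu-177-DOTATATE-like therapy: four co-registered time-point acquisitions at
4/24/72/192 h after injecting ~7200 MBq, reconstructed onto a 128x128x96
grid of 4.42 mm isotropic voxels acquired as 60 projections x 45 s.
Organs are non-overlapping ellipsoids with mono- or bi-exponential
kinetics (an uptake fraction of the injected activity decaying at an
effective rate), and reconstructed voxel counts follow the forward
quantification model

    counts(voxel, t) = activity(voxel, t) [MBq] x sensitivity [cps/MBq]
                       x total acquisition duration [s]

optionally Poisson-distributed around that mean.  No projection /
reconstruction physics is simulated: counts are generated directly in
image space, so resolution loss, scatter and partial-volume effects of
real SPECT are absent by design.

Every quantity a downstream stage should recover (organ mass, activity per
time point, time-integrated activity TIA, its coefficient TIAC = TIA/A0,
and the local-energy-deposition mean dose) is available in closed form in
:class:`GroundTruth`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import InvalidInputError, SpecificationError
from .units import DECAYS_PER_MBQ_H, AcquisitionMeta, Radionuclide
from .volumes import ImageVolume, LabelMap, Organ, apply_integer_shift


@dataclass(frozen=True)
class Kinetics:
    """Sum-of-exponentials organ kinetics: A(t) = A0 * sum_i f_i exp(-l_i t).

    ``fractions`` are uptake fractions of the injected activity and
    ``rates_per_h`` the matching effective decay constants (biological
    clearance + physical decay).  One term is mono-exponential, two terms
    bi-exponential.  Fractions may not be negative, so activity is
    non-negative for all t >= 0.
    """

    fractions: Tuple[float, ...]
    rates_per_h: Tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.rates_per_h) or not self.fractions:
            raise SpecificationError("fractions and rates must be non-empty and matched")
        if any(f < 0 for f in self.fractions):
            raise SpecificationError("uptake fractions must be >= 0")
        if any(r <= 0 for r in self.rates_per_h):
            raise SpecificationError("effective rates must be > 0 per hour")

    def activity_MBq(self, a0_MBq: float, t_h) -> np.ndarray:
        t = np.asarray(t_h, dtype=float)
        out = np.zeros_like(t)
        for f, lam in zip(self.fractions, self.rates_per_h):
            out = out + f * a0_MBq * np.exp(-lam * t)
        return out

    def tia_MBqh(self, a0_MBq: float) -> float:
        """Closed-form integral of A(t) on (0, inf)."""
        return float(sum(f * a0_MBq / lam for f, lam in zip(self.fractions, self.rates_per_h)))

    def tiac_h(self) -> float:
        return float(sum(f / lam for f, lam in zip(self.fractions, self.rates_per_h)))


@dataclass(frozen=True)
class EllipsoidOrgan:
    """An organ as an axis-aligned ellipsoid in world (mm) coordinates."""

    label: int
    name: str
    center_mm: Tuple[float, float, float]
    semiaxes_mm: Tuple[float, float, float]
    density_gcc: float
    kinetics: Kinetics

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise SpecificationError("organ labels must be positive")
        if any(a <= 0 for a in self.semiaxes_mm):
            raise SpecificationError("ellipsoid semi-axes must be positive")


@dataclass
class PhantomSpec:
    """Full description of a synthetic study; seed fixes all randomness."""

    shape: Tuple[int, int, int] = (128, 128, 96)
    spacing_mm: Tuple[float, float, float] = (4.42, 4.42, 4.42)
    organs: Sequence[EllipsoidOrgan] = ()
    background: Optional[Kinetics] = None
    a0_MBq: float = 7200.0
    times_h: Sequence[float] = (4.0, 24.0, 72.0, 192.0)
    acquisition: AcquisitionMeta = field(
        default_factory=lambda: AcquisitionMeta(n_projections=60, seconds_per_projection=45.0)
    )
    sensitivity_cps_per_MBq: float = 9.67
    nuclide: Optional[Radionuclide] = None
    noise: str = "none"
    shifts_voxels: Optional[Sequence[Tuple[int, int, int]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("none", "poisson"):
            raise SpecificationError(f"noise must be 'none' or 'poisson', got {self.noise!r}")
        if not self.a0_MBq > 0:
            raise SpecificationError("a0_MBq must be > 0")
        if not self.sensitivity_cps_per_MBq > 0:
            raise SpecificationError("sensitivity must be > 0 cps/MBq")
        times = list(self.times_h)
        if any(t < 0 for t in times) or sorted(times) != times or len(set(times)) != len(times):
            raise SpecificationError("times_h must be non-negative and strictly increasing")
        if self.shifts_voxels is not None and len(self.shifts_voxels) != len(times):
            raise SpecificationError("one shift per time point required")


@dataclass(frozen=True)
class OrganTruth:
    """Analytic per-organ reference values implied by the phantom spec."""

    label: int
    name: str
    voxel_count: int
    mass_g: float
    activities_MBq: Tuple[float, ...]
    tia_MBqh: float
    tiac_h: float
    mean_dose_led_Gy: Optional[float]  # requires nuclide energy


@dataclass(frozen=True)
class GroundTruth:
    a0_MBq: float
    times_h: Tuple[float, ...]
    organs: Dict[str, OrganTruth]

    def as_records(self) -> List[dict]:
        rows = []
        for t in self.organs.values():
            rows.append(
                {
                    "organ": t.name,
                    "label": t.label,
                    "mass_g": t.mass_g,
                    "tia_MBqh": t.tia_MBqh,
                    "tiac_h": t.tiac_h,
                    "mean_dose_led_Gy": t.mean_dose_led_Gy,
                }
            )
        return rows


@dataclass(frozen=True)
class PhantomStudy:
    """Everything the simulator produces for one study."""

    label_map: LabelMap
    density: ImageVolume
    counts: Tuple[ImageVolume, ...]
    ground_truth: GroundTruth
    spec: PhantomSpec


def _voxel_centers(shape, spacing):
    """World mm coordinate of each voxel center along one axis: (i + 0.5) * s."""
    return [
        (np.arange(n, dtype=float) + 0.5) * s for n, s in zip(shape, spacing)
    ]


def _ellipsoid_mask(spec: PhantomSpec, organ: EllipsoidOrgan) -> np.ndarray:
    ax = _voxel_centers(spec.shape, spec.spacing_mm)
    gx = (ax[0][:, None, None] - organ.center_mm[0]) / organ.semiaxes_mm[0]
    gy = (ax[1][None, :, None] - organ.center_mm[1]) / organ.semiaxes_mm[1]
    gz = (ax[2][None, None, :] - organ.center_mm[2]) / organ.semiaxes_mm[2]
    return gx * gx + gy * gy + gz * gz <= 1.0


def build_phantom(
    spec: PhantomSpec, background_density_gcc: float = 1.0
) -> Tuple[LabelMap, ImageVolume]:
    """Rasterize the organ primitives into a label map and a density volume.

    Every voxel belongs to exactly one label (0 = background); overlapping
    ellipsoids are a specification error.
    """
    labels = np.zeros(spec.shape, dtype=np.int32)
    density = np.full(spec.shape, float(background_density_gcc))
    catalogue: Dict[int, Organ] = {}
    for organ in spec.organs:
        if organ.label in catalogue:
            raise SpecificationError(f"duplicate organ label {organ.label}")
        mask = _ellipsoid_mask(spec, organ)
        if np.any(labels[mask] != 0):
            raise SpecificationError(f"organ {organ.name!r} overlaps an earlier organ")
        labels[mask] = organ.label
        density[mask] = organ.density_gcc
        catalogue[organ.label] = Organ(organ.label, organ.name, organ.density_gcc)
    label_map = LabelMap(labels, spec.spacing_mm, catalogue)
    density_vol = ImageVolume(density, spec.spacing_mm, "density_gcc")
    return label_map, density_vol


def _organ_truth(spec: PhantomSpec, organ: EllipsoidOrgan, n_vox: int) -> OrganTruth:
    voxvol_cm3 = float(np.prod(spec.spacing_mm)) / 1000.0
    mass_g = n_vox * voxvol_cm3 * organ.density_gcc
    acts = tuple(float(a) for a in organ.kinetics.activity_MBq(spec.a0_MBq, list(spec.times_h)))
    tia = organ.kinetics.tia_MBqh(spec.a0_MBq)
    tiac = organ.kinetics.tiac_h()
    dose = None
    if spec.nuclide is not None and spec.nuclide.energy_per_decay_j is not None:
        # Uniform uptake: mean LED dose = TIA * decays/(MBq.h) * E / organ mass.
        dose = tia * DECAYS_PER_MBQ_H * spec.nuclide.energy_per_decay_j / (mass_g * 1e-3)
    return OrganTruth(organ.label, organ.name, n_vox, mass_g, acts, tia, tiac, dose)


def simulate_timepoints(spec: PhantomSpec) -> PhantomStudy:
    """Generate the count-volume time series plus analytic ground truth.

    In noiseless mode voxel counts equal exactly
    activity(t) x sensitivity x total duration; in ``poisson`` mode they are
    drawn per voxel with that mean, reproducibly from ``spec.seed``.
    """
    label_map, density = build_phantom(spec)
    duration_s = spec.acquisition.total_duration_s
    if not duration_s > 0:
        raise SpecificationError("acquisition duration must be positive")
    rng = np.random.default_rng(spec.seed)

    organs_by_label = {o.label: o for o in spec.organs}
    masks = {lab: label_map.data == lab for lab in organs_by_label}
    n_vox = {lab: int(m.sum()) for lab, m in masks.items()}
    for lab, o in organs_by_label.items():
        if n_vox[lab] == 0:
            raise SpecificationError(f"organ {o.name!r} rasterizes to zero voxels")
    bg_mask = label_map.data == 0
    n_bg = int(bg_mask.sum())

    truths: Dict[str, OrganTruth] = {
        o.name: _organ_truth(spec, o, n_vox[o.label]) for o in spec.organs
    }

    counts: List[ImageVolume] = []
    for i, t in enumerate(spec.times_h):
        expected = np.zeros(spec.shape, dtype=float)
        for lab, organ in organs_by_label.items():
            a_t = float(organ.kinetics.activity_MBq(spec.a0_MBq, t))
            if a_t < 0:
                raise SpecificationError(f"negative activity for {organ.name!r} at t={t} h")
            expected[masks[lab]] = a_t / n_vox[lab] * spec.sensitivity_cps_per_MBq * duration_s
        if spec.background is not None and n_bg:
            a_bg = float(spec.background.activity_MBq(spec.a0_MBq, t))
            if a_bg < 0:
                raise SpecificationError(f"negative background activity at t={t} h")
            expected[bg_mask] = a_bg / n_bg * spec.sensitivity_cps_per_MBq * duration_s
        data = rng.poisson(expected).astype(float) if spec.noise == "poisson" else expected
        if spec.shifts_voxels is not None:
            data = apply_integer_shift(data, spec.shifts_voxels[i])
        counts.append(
            ImageVolume(data, spec.spacing_mm, "counts", time_post_injection_h=float(t))
        )

    gt = GroundTruth(spec.a0_MBq, tuple(float(t) for t in spec.times_h), truths)
    return PhantomStudy(label_map, density, tuple(counts), gt, spec)


def default_abdominal_spec(
    nuclide: Optional[Radionuclide] = None,
    noise: str = "none",
    seed: int = 0,
) -> PhantomSpec:
    """The study-like default phantom: liver, spleen, two kidneys.

    Geometry sits on the default 128x128x96 grid at 4.42 mm; kinetics are
    mono-exponential with uptake fractions and effective rates chosen so the
    organ TIACs (~10 h liver, ~0.9 h spleen, ~1.5 h both kidneys) and masses
    (~1 kg liver, ~170 g spleen, ~130 g per kidney) are typical of reported
    Lu-177-DOTATATE patient studies.
    """
    organs = (
        EllipsoidOrgan(
            1, "liver", (180.0, 230.0, 230.0), (80.0, 60.0, 50.0), 1.06,
            Kinetics((0.12,), (0.012,)),
        ),
        EllipsoidOrgan(
            2, "spleen", (400.0, 210.0, 230.0), (35.0, 25.0, 45.0), 1.06,
            Kinetics((0.0135,), (0.015,)),
        ),
        EllipsoidOrgan(
            3, "kidney_left", (380.0, 330.0, 130.0), (30.0, 20.0, 50.0), 1.05,
            Kinetics((0.014,), (0.0187,)),
        ),
        EllipsoidOrgan(
            4, "kidney_right", (180.0, 330.0, 130.0), (30.0, 20.0, 50.0), 1.05,
            Kinetics((0.014,), (0.0187,)),
        ),
    )
    background = Kinetics((0.30,), (0.05,))
    return PhantomSpec(
        organs=organs, background=background, nuclide=nuclide, noise=noise, seed=seed
    )
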