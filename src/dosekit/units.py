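"""Physical constants, acquisition metadata, and calibration-factor algebra.

Internal unit conventions, used everywhere in the package:

* activity in MBq, time in hours (acquisition durations in seconds),
  mass in grams, absorbed dose in Gy, lengths in mm;
* a *calibration factor* ties reconstructed image counts to activity and is
  only meaningful together with the acquisition duration it was measured
  over.  SPECT systems report it in several equivalent unit kinds
  (cps/MBq, MBq/count, Bq/count, Bq/intensity); this module converts
  between them exactly and rescales count-based factors when the patient
  acquisition uses a different duration than the calibration scan.

One MBq.h corresponds to 3.6e9 nuclear transformations, the conversion
used by the local-energy-deposition and kernel dose engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import yaml

from .errors import ConfigurationError, InvalidInputError

#: Nuclear transformations per MBq.h (1e6 Bq x 3600 s).
DECAYS_PER_MBQ_H = 3.6e9

#: Recognised calibration-factor unit kinds. "Bq_per_intensity" is the
#: STRATOS spelling of Bq per reconstructed count and is treated as a
#: synonym of "Bq_per_count".
UNIT_KINDS = ("cps_per_MBq", "MBq_per_count", "Bq_per_count", "Bq_per_intensity")

_COUNT_BASED = {"MBq_per_count", "Bq_per_count", "Bq_per_intensity"}


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide with its physical half-life and locally deposited energy.

    Parameters
    ----------
    name:
        Display name, e.g. ``"Lu-177"``.
    half_life_h:
        Physical half-life in hours (159.53 h for Lu-177).
    energy_per_decay_j:
        Energy (J) deposited locally per nuclear transformation, i.e. the
        electron/beta energy assumed absorbed where it is emitted.  Required
        by the LED and kernel dose engines; take it from a decay-data
        compilation (ICRP 107, MIRD).  ``None`` for decay-only uses.
    """

    name: str
    half_life_h: float
    energy_per_decay_j: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise InvalidInputError(f"half-life must be > 0 h, got {self.half_life_h}")
        if self.energy_per_decay_j is not None and self.energy_per_decay_j < 0:
            raise InvalidInputError("energy per decay must be >= 0 J")

    @property
    def decay_constant_per_h(self) -> float:
        """Physical decay constant ln(2)/T1/2 in 1/h (always derived)."""
        return math.log(2.0) / self.half_life_h

    def require_energy(self) -> float:
        if self.energy_per_decay_j is None:
            raise ConfigurationError(
                f"{self.name}: energy_per_decay_j is required for dose "
                "calculation but was not provided"
            )
        return self.energy_per_decay_j


def decay_constant(nuclide: Radionuclide) -> float:
    """Physical decay constant ln(2)/half-life, in 1/h."""
    return nuclide.decay_constant_per_h


@dataclass(frozen=True)
class AcquisitionMeta:
    """SPECT acquisition timing: projections, dwell time, time post injection."""

    n_projections: int
    seconds_per_projection: float
    time_post_injection_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_projections <= 0:
            raise InvalidInputError("n_projections must be positive")
        if not self.seconds_per_projection > 0:
            raise InvalidInputError("seconds_per_projection must be positive")
        if self.time_post_injection_h is not None and self.time_post_injection_h < 0:
            raise InvalidInputError("time_post_injection_h must be >= 0")

    @property
    def total_duration_s(self) -> float:
        """Total acquisition duration = n_projections x seconds_per_projection."""
        return self.n_projections * self.seconds_per_projection

    def at_time(self, time_h: float) -> "AcquisitionMeta":
        return replace(self, time_post_injection_h=time_h)


@dataclass(frozen=True)
class InjectedActivity:
    """Administered activity A0 (MBq); injection defines time zero."""

    a0_MBq: float

    def __post_init__(self) -> None:
        if not self.a0_MBq > 0:
            raise InvalidInputError("injected activity must be > 0 MBq")


@dataclass(frozen=True)
class CalibrationFactor:
    """Counts-to-activity conversion factor tied to its calibration scan.

    ``magnitude`` is expressed in ``unit_kind``; for count-based kinds the
    factor is only defined relative to the total acquisition duration of
    the scan it was measured on (``context``), because the same activity
    accumulates more counts in a longer scan.
    """

    magnitude: float
    unit_kind: str
    context: Optional[AcquisitionMeta] = None

    def __post_init__(self) -> None:
        if not self.magnitude > 0:
            raise InvalidInputError("calibration-factor magnitude must be > 0")
        if self.unit_kind not in UNIT_KINDS:
            raise ConfigurationError(
                f"unknown unit kind {self.unit_kind!r}; expected one of {UNIT_KINDS}"
            )

    # -- internal helpers -------------------------------------------------
    @property
    def is_count_based(self) -> bool:
        return self.unit_kind in _COUNT_BASED

    def _context_duration_s(self) -> float:
        if self.context is None:
            raise ConfigurationError(
                f"calibration factor in {self.unit_kind} needs an acquisition "
                "duration context"
            )
        return self.context.total_duration_s

    def _mbq_per_count_in_context(self) -> float:
        """Factor as MBq/count for the context duration."""
        if self.unit_kind == "MBq_per_count":
            return self.magnitude
        if self.unit_kind in ("Bq_per_count", "Bq_per_intensity"):
            return self.magnitude * 1e-6
        # cps_per_MBq: counts = A * S * T  =>  MBq/count = 1/(S*T)
        return 1.0 / (self.magnitude * self._context_duration_s())

    # -- public algebra ---------------------------------------------------
    def sensitivity_cps_per_MBq(self) -> float:
        """System sensitivity in cps/MBq (duration-free form of the factor)."""
        if self.unit_kind == "cps_per_MBq":
            return self.magnitude
        return 1.0 / (self._mbq_per_count_in_context() * self._context_duration_s())

    def mbq_per_count(self, acquisition: Optional[AcquisitionMeta] = None) -> float:
        """Effective MBq per count for ``acquisition`` (defaults to context)."""
        if acquisition is None:
            acquisition = self.context
        if acquisition is None:
            raise ConfigurationError("an acquisition duration is required")
        return 1.0 / (self.sensitivity_cps_per_MBq() * acquisition.total_duration_s)

    def rescale_for_duration(self, target: AcquisitionMeta) -> "CalibrationFactor":
        """Re-express a count-based factor for a different acquisition duration.

        Count-based magnitudes scale by (context duration / target duration);
        cps/MBq is duration-invariant and returned with the new context.
        The sensitivity in cps/MBq is unchanged by construction.
        """
        if not target.total_duration_s > 0:
            raise InvalidInputError("target duration must be positive")
        if not self.is_count_based:
            return replace(self, context=target)
        scale = self._context_duration_s() / target.total_duration_s
        return replace(self, magnitude=self.magnitude * scale, context=target)

    def as_unit(self, unit_kind: str) -> "CalibrationFactor":
        """Exact conversion to another unit kind (round-trip identity)."""
        if unit_kind not in UNIT_KINDS:
            raise ConfigurationError(f"unknown unit kind {unit_kind!r}")
        if unit_kind == self.unit_kind:
            return self
        if unit_kind == "cps_per_MBq":
            mag = self.sensitivity_cps_per_MBq()
        else:
            mbq_per_count = self._mbq_per_count_in_context()
            mag = mbq_per_count if unit_kind == "MBq_per_count" else mbq_per_count * 1e6
        return CalibrationFactor(mag, unit_kind, self.context)


def sensitivity_cps_per_MBq(cf: CalibrationFactor) -> float:
    """System sensitivity (cps/MBq) of a calibration factor; see the method."""
    return cf.sensitivity_cps_per_MBq()


def rescale_for_duration(cf: CalibrationFactor, target: AcquisitionMeta) -> CalibrationFactor:
    """Functional form of :meth:`CalibrationFactor.rescale_for_duration`."""
    return cf.rescale_for_duration(target)


# ---------------------------------------------------------------------------
# Nuclide config: a plain-text key-value (YAML) registry.  The packaged file
# ships physical half-lives only; the locally deposited energy per decay must
# come from the user's decay-data compilation.
# ---------------------------------------------------------------------------

_DATA_FILE = Path(__file__).parent / "data" / "nuclides.yaml"


def load_nuclide(
    name: str,
    energy_per_decay_j: Optional[float] = None,
    config_path: Optional[Path] = None,
) -> Radionuclide:
    """Load a nuclide from the packaged (or a user) key-value registry.

    The registry maps ``name -> {half_life_h: float, energy_per_decay_j:
    optional float}``.  An ``energy_per_decay_j`` argument overrides the file.
    """
    path = Path(config_path) if config_path is not None else _DATA_FILE
    registry = yaml.safe_load(path.read_text())
    if name not in registry:
        raise ConfigurationError(f"nuclide {name!r} not in registry {path}")
    entry = registry[name]
    energy = energy_per_decay_j if energy_per_decay_j is not None else entry.get("energy_per_decay_j")
    return Radionuclide(name, float(entry["half_life_h"]), energy)
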