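import numpy as np
import pytest

from dosekit import (
    AcquisitionMeta,
    EllipsoidOrgan,
    Kinetics,
    PhantomSpec,
    Radionuclide,
    TimeActivityCurve,
)

STUDY_TIMES_H = (4.0, 24.0, 72.0, 192.0)


@pytest.fixture
def lu177():
    """Lu-177 with a locally deposited energy typical of decay-data tables."""
    return Radionuclide("Lu-177", 159.53, 2.37e-14)


@pytest.fixture
def toy_nuclide():
    """Synthetic nuclide with round numbers for hand-checkable dosimetry."""
    return Radionuclide("toy", 100.0, 1e-12)


@pytest.fixture
def worked_tac():
    """The four-point worked curve: (4,90) (24,70) (72,40) (192,10) MBq."""
    return TimeActivityCurve(
        label=1,
        name="kidney",
        times_h=np.array(STUDY_TIMES_H),
        activities_MBq=np.array([90.0, 70.0, 40.0, 10.0]),
        a0_MBq=7200.0,
    )


def small_phantom_spec(nuclide=None, noise="none", seed=0, background=True):
    """Two-organ phantom on a small grid for fast unit tests."""
    organs = (
        EllipsoidOrgan(
            1, "organ_a", (40.0, 40.0, 35.0), (22.0, 16.0, 14.0), 1.06,
            Kinetics((0.10,), (0.02,)),
        ),
        EllipsoidOrgan(
            2, "organ_b", (100.0, 100.0, 65.0), (18.0, 14.0, 20.0), 1.05,
            Kinetics((0.02,), (0.03,)),
        ),
    )
    return PhantomSpec(
        shape=(32, 32, 24),
        spacing_mm=(4.42, 4.42, 4.42),
        organs=organs,
        background=Kinetics((0.2,), (0.05,)) if background else None,
        a0_MBq=7200.0,
        times_h=STUDY_TIMES_H,
        acquisition=AcquisitionMeta(60, 45.0),
        sensitivity_cps_per_MBq=9.67,
        nuclide=nuclide,
        noise=noise,
        seed=seed,
    )


@pytest.fixture
def small_spec(lu177):
    return small_phantom_spec(nuclide=lu177)
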