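import numpy as np
import pytest

from minibeams import (
    C12,
    LI7,
    PROTON,
    BeamShape,
    BeamSpec,
    EnergySpec,
    energy_for_range,
)


def read_artifact_csv(path) -> dict[str, np.ndarray]:
    """Parse a package CSV artifact: '#' metadata header, then named columns."""
    with open(path) as fh:
        rows = [line.strip() for line in fh if line.strip() and not line.startswith("#")]
    names = rows[0].split(",")
    data = np.array([[float(tok) for tok in row.split(",")] for row in rows[1:]])
    return dict(zip(names, data.T))


@pytest.fixture(scope="session")
def proton_pencil_109() -> BeamSpec:
    """109-MeV proton pencil minibeam, 0.3-mm incident, 1.0-mm lattice."""
    return BeamSpec(
        species=PROTON,
        energy=EnergySpec(109.0),
        shape=BeamShape.PENCIL,
        incident_width_fwhm=0.3,
        spacing_on_center=1.0,
    )


@pytest.fixture(scope="session")
def proton_planar_10cm() -> BeamSpec:
    """0.3-mm planar proton comb, 1.0-mm on-center, 10-cm range."""
    return BeamSpec(
        species=PROTON,
        energy=EnergySpec(energy_for_range(PROTON, 10.0)),
        shape=BeamShape.PLANAR,
        incident_width_fwhm=0.3,
        spacing_on_center=1.0,
    )


@pytest.fixture(scope="session")
def li7_planar_10cm() -> BeamSpec:
    """0.3-mm planar Li-7 comb, 1.0-mm on-center, 10-cm range."""
    return BeamSpec(
        species=LI7,
        energy=EnergySpec(energy_for_range(LI7, 10.0)),
        shape=BeamShape.PLANAR,
        incident_width_fwhm=0.3,
        spacing_on_center=1.0,
    )


@pytest.fixture(scope="session")
def carbon_rabbit() -> BeamSpec:
    """Carbon minibeam at the energy whose range is the rabbit target's distal edge."""
    return BeamSpec(
        species=C12,
        energy=EnergySpec(energy_for_range(C12, 4.25)),
        shape=BeamShape.PLANAR,
        incident_width_fwhm=0.3,
        spacing_on_center=1.05,
    )
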