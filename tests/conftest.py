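import numpy as np
import pytest

import gdosim as g


@pytest.fixture(scope="session")
def catalogue():
    return g.builtin_nuclides()


@pytest.fixture(scope="session")
def gd146(catalogue):
    return catalogue["Gd-146"]


@pytest.fixture(scope="session")
def gd148(catalogue):
    return catalogue["Gd-148"]


@pytest.fixture(scope="session")
def gd153(catalogue):
    return catalogue["Gd-153"]


@pytest.fixture(scope="session")
def params():
    return g.IngestionParams()


@pytest.fixture(scope="session")
def hrtm():
    return g.HRTMParams()


@pytest.fixture(scope="session")
def detector():
    return g.DetectorConfig()


@pytest.fixture(scope="session")
def coeffs(catalogue):
    return g.DoseCoefficients.from_catalogue(catalogue)


@pytest.fixture(scope="session")
def scenario_5y():
    return g.ReleaseScenario.five_year()


@pytest.fixture(scope="session")
def scenario_1y():
    return g.ReleaseScenario.one_year()


def bookkeeping_whole_body_q(t, nuclide, params, *, environmental_decay=False, dt=0.05):
    """Independent time-stepped bookkeeping oracle for the chronic-ingestion
    whole-body content per unit daily intake.

    Each intake parcel is tracked explicitly: a plug-flow GI stay of
    ``gi_transit_time`` with radioactive decay, and a transfer of the
    effective systemic fraction into a first-order pool whose rate combines
    the biological retention and the isotope's physical decay.  No closed
    forms from the implementation are reused.
    """
    lam = np.log(2.0) / nuclide.half_life
    lam_bio = np.log(2.0) / params.systemic_halftime - np.log(2.0) / params.reference_half_life
    transfer = params.systemic_amplitude * np.log(2.0) / params.systemic_halftime
    s = np.arange(0.0, t, dt) + dt / 2.0  # parcel ingestion times
    parcels = np.full_like(s, dt)  # Bq per parcel at unit daily intake
    if environmental_decay:
        parcels = parcels * np.exp(-lam * s)
    age = t - s
    gi = float(np.sum(parcels * np.exp(-lam * age) * (age < params.gi_transit_time)))
    systemic = float(np.sum(parcels * transfer * np.exp(-(lam_bio + lam) * age)))
    return gi + systemic
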