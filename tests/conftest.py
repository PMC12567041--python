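"""Shared fixtures: compound models, the mean reference subject, the
calibrated clearance scalars, and a few expensive simulations reused across
test modules (session scope keeps the whole suite inside a few minutes)."""

import numpy as np
import pytest

from ascipk import (Calibration, EngineOptions, PBPKSystem, calibrate,
                    load_compound, mean_subject, steady_state_clf)


@pytest.fixture(scope="session")
def asciminib():
    return load_compound("asciminib")


@pytest.fixture(scope="session")
def subject():
    return mean_subject()


@pytest.fixture(scope="session")
def calibration(asciminib, subject) -> Calibration:
    """Two-stage clearance calibration at the 20 mg BID operating point."""
    return calibrate(asciminib, subject)


@pytest.fixture(scope="session")
def single_dose_40(asciminib, subject, calibration):
    """Dense 40 mg single-dose simulation in the mean healthy subject."""
    system = PBPKSystem(asciminib, subject, calibration=calibration)
    return system.simulate({"asciminib": [(0.0, 40.0)]}, duration=120.0)


@pytest.fixture(scope="session")
def clf_by_dose(asciminib, subject, calibration):
    """Steady-state CL/F with and without BCRP across the BID dose range."""
    out = {}
    for dose in (20.0, 40.0, 80.0, 200.0):
        w = steady_state_clf(asciminib, subject, dose, 12.0, 15, calibration,
                             bcrp=True)
        wo = steady_state_clf(asciminib, subject, dose, 12.0, 15, calibration,
                              bcrp=False)
        out[dose] = (w, wo)
    return out


@pytest.fixture(scope="session")
def asciminib_ss_40bid(asciminib, subject, calibration):
    """Steady-state 40 mg BID profile (perpetrator exposure source)."""
    system = PBPKSystem(asciminib, subject, calibration=calibration)
    times = [(i * 12.0, 40.0) for i in range(20)]
    res = system.simulate({"asciminib": times}, duration=240.0)
    mask = res.t >= 228.0
    return res.t[mask], res.plasma_conc()[mask]
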