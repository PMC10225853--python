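"""Shared fixtures: small synthetic landscapes and climate stacks."""

import numpy as np
import pytest
from hypothesis import settings

from dcrange import synthetic
from dcrange.calibration import ParameterVector
from dcrange.climate import ClimateStack, PREDICTORS, StdRecord
from dcrange.ibm import PopulationState

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def make_zstack(values=None, years=(2000, 2001, 2002), shape=(6, 6), cell_km=1.0):
    """Standardized climate stack with given per-predictor values.

    ``values`` maps predictor -> scalar, (rows, cols) grid or (years, rows,
    cols) array; default all zeros (all rates at their intercepts).  The
    standardization record is the identity (mean 0, sd 1).
    """
    years = np.asarray(years, dtype=int)
    data, std = {}, {}
    for p in PREDICTORS:
        v = 0.0 if values is None else values.get(p, 0.0)
        arr = np.broadcast_to(np.asarray(v, dtype=float), (len(years),) + tuple(shape)).copy()
        data[p] = arr
        std[p] = StdRecord(mean=0.0, sd=1.0, reference_years=tuple(int(y) for y in years))
    return ClimateStack(years=years, data=data, std=std, cell_km=cell_km)


def make_raw_stack(values, years, cell_km=1.0):
    """Raw (unstandardized) stack from explicit (years, rows, cols) arrays."""
    return ClimateStack(years=np.asarray(years, dtype=int),
                        data={p: np.asarray(v, dtype=float) for p, v in values.items()},
                        cell_km=cell_km)


def uniform_state(shape, adults_per_cell, habitat=None):
    adults = np.full(shape, adults_per_cell, dtype=np.int64)
    if habitat is not None:
        adults = np.where(np.asarray(habitat) > 0, adults, 0)
    return PopulationState(adults=adults, juveniles=np.zeros(shape, dtype=np.int64))


def neutral_theta(fec_0=0.0, sj_0=0.0, sa_0=0.0, b=0.01, p_e=0.0, d_mean=1.0, sigma=20.0):
    """Parameter vector with all climate slopes zero (spatially uniform rates)."""
    coeffs = np.zeros(14)
    coeffs[0], coeffs[5], coeffs[10] = fec_0, sj_0, sa_0
    return ParameterVector(coeffs=coeffs, b=b, p_e=p_e, d_mean=d_mean, sigma=sigma)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small but complete synthetic scenario for integration-style tests."""
    scen = synthetic.SyntheticScenario(
        nrows=15, ncols=15, first_year=2000, last_year=2007,
        n_sites=25, spinup_years=10, seed=42,
    )
    return synthetic.generate(scen)
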