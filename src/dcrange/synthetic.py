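"""Synthetic landscapes, climate histories and surveys with known truth.

Everything the inference pipeline consumes can be generated here with the
statistical structure the analysis assumes, so the full workflow is testable
without external rasters or survey archives:

* climate: per predictor, a smooth spatial base field (Gaussian random field
  with a configurable correlation length) plus a linear temporal trend and
  spatially correlated interannual noise;
* habitat: a fine-scale (100 m analogue) thresholded random field aggregated
  to the 0..100 suitability index, so the landscape-mean suitability tracks
  the requested cover fraction and clustering is controllable;
* initial abundance: every suitable cell is seeded with a fixed number of
  adult females and the model is spun up under first-year climate (a simple,
  explicit stand-in for survey-derived initial-abundance models);
* survey: one stochastic model realization under the true parameters,
  observed at uniformly sampled sites through negative-binomial error, plus
  a total-abundance reference index.

All randomness derives from the scenario's master seed; identical scenarios
reproduce identical data byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import dcr, ibm
from .calibration import ParameterVector
from .climate import PREDICTORS, ClimateStack, standardize
from .habitat import aggregate_suitability
from .ibm import DispersalParams, PopulationState, stream

# Archetype parameter vectors mimicking contrasting demography-climate
# response shapes (package fixtures, not empirical estimates): "mountain"
# loses fecundity with warming but gains survival from milder, wetter
# winters; "lowland" shows the opposite temperature responses.
ARCHETYPES = {
    "mountain": ParameterVector(
        coeffs=np.array([
            0.405, -0.30, -0.10, 0.20, -0.10,   # fecundity vs T_br, P_br
            -0.20, -0.25, -0.05, 0.30, -0.10,   # juvenile survival vs T_at, P_wn
            0.40, 0.20, 0.10, -0.05,            # adult survival vs T_wn, P_wn
        ]),
        b=0.10, p_e=0.25, d_mean=2.0, sigma=20.0,
    ),
    "lowland": ParameterVector(
        coeffs=np.array([
            0.50, 0.25, -0.15, -0.10, -0.05,
            -0.30, 0.20, -0.10, -0.20, -0.05,
            0.30, -0.15, 0.05, -0.10,
        ]),
        b=0.08, p_e=0.35, d_mean=3.0, sigma=30.0,
    ),
}

# Default per-year trends emulate two decades of observed alpine climate
# change (about +1 K breeding-season and +1.5 K winter-minimum warming and
# +29 mm winter precipitation per 20 years).
_DEFAULT_TREND = {"T_br": 0.05, "P_br": -0.58, "T_at": 0.055, "T_wn": 0.075, "P_wn": 1.45}
_DEFAULT_MEAN = {"T_br": 12.0, "P_br": 150.0, "T_at": 6.0, "T_wn": -5.0, "P_wn": 100.0}
_DEFAULT_SPATIAL_SD = {"T_br": 2.0, "P_br": 40.0, "T_at": 2.0, "T_wn": 3.0, "P_wn": 30.0}
_DEFAULT_NOISE_SD = {"T_br": 0.4, "P_br": 20.0, "T_at": 0.5, "T_wn": 0.8, "P_wn": 15.0}


@dataclass
class SyntheticScenario:
    """Complete recipe for one synthetic study; all randomness keyed to ``seed``."""

    nrows: int = 30
    ncols: int = 30
    cell_km: float = 1.0
    first_year: int = 1999
    last_year: int = 2013
    corr_length: float = 5.0
    trend_slope: dict = field(default_factory=lambda: dict(_DEFAULT_TREND))
    climate_mean: dict = field(default_factory=lambda: dict(_DEFAULT_MEAN))
    spatial_sd: dict = field(default_factory=lambda: dict(_DEFAULT_SPATIAL_SD))
    interannual_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    habitat_cover: float = 0.6
    habitat_clustering: float = 3.0
    archetype: str = "mountain"
    theta_true: ParameterVector | None = None
    sigma_true: float | None = None
    n_sites: int = 60
    spinup_years: int = 20
    seed_density: int = 2
    ref_index_noise_sd: float = 0.0
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.theta_true is None:
            self.theta_true = ARCHETYPES[self.archetype]
        if self.sigma_true is None:
            self.sigma_true = self.theta_true.sigma
        if self.last_year - self.first_year + 1 < 3:
            raise ValueError("scenario must span at least 3 years")
        if self.nrows < 5 or self.ncols < 5:
            raise ValueError("grid must be at least 5 x 5")
        if not 0.0 <= self.habitat_cover <= 1.0:
            raise ValueError("habitat cover fraction must be in [0, 1]")
        if self.n_sites > self.nrows * self.ncols:
            raise ValueError("more survey sites than grid cells")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["theta_true"] = self.theta_true.to_array().tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        theta = d.get("theta_true")
        if theta is not None and not isinstance(theta, ParameterVector):
            d["theta_true"] = ParameterVector.from_array(np.asarray(theta, dtype=float))
        return cls(**d)


_norm_cache: dict[tuple, float] = {}


def _grf(shape: tuple[int, int], corr_length: float, rng) -> np.ndarray:
    """Unit-variance Gaussian random field via wrapped Gaussian smoothing."""
    if corr_length <= 0:
        raise ValueError("correlation length must be > 0")
    key = (shape, float(corr_length))
    if key not in _norm_cache:
        impulse = np.zeros(shape)
        impulse[shape[0] // 2, shape[1] // 2] = 1.0
        k = gaussian_filter(impulse, corr_length, mode="wrap")
        _norm_cache[key] = float(np.sqrt((k * k).sum()))
    white = rng.standard_normal(shape)
    return gaussian_filter(white, corr_length, mode="wrap") / _norm_cache[key]


def gen_climate(scenario: SyntheticScenario) -> ClimateStack:
    """Raw climate stack: spatial base field + linear trend + interannual noise."""
    shape = (scenario.nrows, scenario.ncols)
    years = scenario.years
    data = {}
    for pi, pred in enumerate(PREDICTORS):
        base = scenario.climate_mean[pred] + scenario.spatial_sd[pred] * _grf(
            shape, scenario.corr_length, stream(scenario.seed, 1, pi)
        )
        arr = np.empty((len(years),) + shape)
        for yi, y in enumerate(years):
            noise = scenario.interannual_sd[pred] * _grf(
                shape, scenario.corr_length, stream(scenario.seed, 2, pi, yi)
            )
            arr[yi] = base + scenario.trend_slope[pred] * (y - years[0]) + noise
        data[pred] = arr
    return ClimateStack(years=years, data=data, cell_km=scenario.cell_km)


def gen_habitat(scenario: SyntheticScenario) -> np.ndarray:
    """Suitability index 0..100 from a clustered fine-scale habitat field.

    A fine grid at 10x the landscape resolution is thresholded at the
    requested cover fraction and aggregated by block counting, so the mean of
    ``h / 100`` equals the realized fine-scale cover and positive clustering
    produces spatially autocorrelated suitability.
    """
    factor = 10
    fine_shape = (scenario.nrows * factor, scenario.ncols * factor)
    rng = stream(scenario.seed, 3)
    if scenario.habitat_cover <= 0.0:
        return np.zeros((scenario.nrows, scenario.ncols), dtype=np.int64)
    if scenario.habitat_cover >= 1.0:
        return np.full((scenario.nrows, scenario.ncols), 100, dtype=np.int64)
    corr = max(scenario.habitat_clustering * factor, 1e-3)
    g = _grf(fine_shape, corr, rng) if scenario.habitat_clustering > 0 else rng.standard_normal(fine_shape)
    thr = np.quantile(g, 1.0 - scenario.habitat_cover)
    binary = (g >= thr).astype(np.uint8)
    return aggregate_suitability(binary, factor=factor)


def gen_initial_abundance(
    habitat,
    climate: ClimateStack,
    theta: ParameterVector,
    spinup_years: int = 20,
    seed: int = 0,
    seed_density: int = 2,
    year: int | None = None,
) -> PopulationState:
    """Initial population: seed suitable cells, spin up under first-year climate.

    An explicit, reproducible stand-in for initial-abundance models fitted to
    historical survey snapshots.
    """
    if spinup_years < 0:
        raise ValueError("spinup_years must be >= 0")
    h = np.asarray(habitat)
    if not (h > 0).any():
        raise ValueError("no suitable cells to seed")
    if climate.std is None:
        climate = standardize(climate)
    if year is None:
        year = int(climate.years[0])
    rates = dcr.rate_maps(theta.coeffs, climate, year, habitat=h)
    dp = DispersalParams(p_e=theta.p_e, d_mean=theta.d_mean)
    adults = np.where(h > 0, int(seed_density), 0).astype(np.int64)[None]
    for t in range(int(spinup_years)):
        rngs = tuple(stream(seed, t, p) for p in (1, 2, 3))
        adults = ibm.step_year(adults, rates, h, theta.b, dp, rngs, cell_km=climate.cell_km)
    return PopulationState(adults=adults[0], juveniles=np.zeros_like(adults[0]), year=year)


@dataclass
class SyntheticTruth:
    """Everything needed for recovery tests: the generating state and process."""

    theta: ParameterVector
    sim: np.ndarray                 # (year, 1, row, col) true realization
    site_rows: np.ndarray
    site_cols: np.ndarray
    reference_index: np.ndarray
    initial: PopulationState


def gen_survey(
    theta: ParameterVector,
    climate: ClimateStack,
    habitat,
    n_sites: int,
    sigma_true: float,
    seed: int = 0,
    initial: PopulationState | None = None,
    ref_index_noise_sd: float = 0.0,
    spinup_years: int = 20,
    seed_density: int = 2,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulated survey: one model realization observed with NB error.

    Sites are sampled uniformly without replacement over all grid cells (the
    survey design does not condition on suitability).  Counts per site-year
    are negative-binomial with mean equal to the simulated adult females and
    dispersion ``sigma_true``.  The reference abundance index is the true
    total adult series relative to the first year, optionally with
    multiplicative log-normal noise (re-normalized so the first year is 1).
    """
    if sigma_true <= 0:
        raise ValueError("observation dispersion must be > 0")
    h = np.asarray(habitat)
    if climate.std is None:
        climate = standardize(climate)
    if n_sites > h.size:
        raise ValueError("more sites than cells")
    if initial is None:
        initial = gen_initial_abundance(
            h, climate, theta, spinup_years=spinup_years,
            seed=int(stream(seed, 4).integers(2**31 - 1)), seed_density=seed_density,
        )
    sim = ibm.simulate(theta, climate, h, initial, n_reps=1,
                       seed=int(stream(seed, 5).integers(2**31 - 1)))
    rng = stream(seed, 6)
    flat = rng.choice(h.size, size=n_sites, replace=False)
    rows, cols = np.unravel_index(flat, h.shape)
    order = np.argsort(flat)
    rows, cols = rows[order], cols[order]

    records = []
    obs_rng = stream(seed, 7)
    for s in range(n_sites):
        mu = sim[:, 0, rows[s], cols[s]].astype(float)
        p = sigma_true / (sigma_true + mu)
        counts = obs_rng.negative_binomial(sigma_true, p)
        for yi, y in enumerate(climate.years):
            records.append({
                "site_id": s,
                "x_cell": int(cols[s]),
                "y_cell": int(rows[s]),
                "year": int(y),
                "count": int(counts[yi]),
            })
    survey = pd.DataFrame.from_records(records)

    totals = sim[:, 0].sum(axis=(1, 2)).astype(float)
    if ref_index_noise_sd > 0:
        noise = stream(seed, 8).lognormal(0.0, ref_index_noise_sd, size=len(totals))
        totals = totals * noise
    if totals[0] > 0:
        ref_index = totals / totals[0]
    else:
        warnings.warn("population extinct in the first survey year; reference index undefined")
        ref_index = np.full(len(totals), np.nan)

    truth = SyntheticTruth(
        theta=theta, sim=sim, site_rows=rows, site_cols=cols,
        reference_index=ref_index, initial=initial,
    )
    return survey, truth


@dataclass
class ScenarioBundle:
    """All artifacts of one synthetic scenario, ready for the pipeline."""

    scenario: SyntheticScenario
    climate_raw: ClimateStack
    climate: ClimateStack           # standardized
    habitat: np.ndarray
    survey: pd.DataFrame
    truth: SyntheticTruth


def generate(scenario: SyntheticScenario) -> ScenarioBundle:
    """Generate the full artifact bundle for a scenario."""
    climate_raw = gen_climate(scenario)
    climate = standardize(climate_raw)
    habitat = gen_habitat(scenario)
    initial = gen_initial_abundance(
        habitat, climate, scenario.theta_true,
        spinup_years=scenario.spinup_years,
        seed=int(stream(scenario.seed, 9).integers(2**31 - 1)),
        seed_density=scenario.seed_density,
    )
    survey, truth = gen_survey(
        scenario.theta_true, climate, habitat,
        n_sites=scenario.n_sites, sigma_true=float(scenario.sigma_true),
        seed=scenario.seed, initial=initial,
        ref_index_noise_sd=scenario.ref_index_noise_sd,
    )
    return ScenarioBundle(
        scenario=scenario, climate_raw=climate_raw, climate=climate,
        habitat=habitat, survey=survey, truth=truth,
    )
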