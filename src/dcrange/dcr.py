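"""Demography-climate relationships (DCRs).

Three demographic rates of the female-only two-stage population model are
linked to standardized seasonal climate predictors through GLM-type link
functions:

* fecundity (log link)::

      rho_max = exp(b0 + b1*T_br + b2*T_br^2 + b3*P_br + b4*P_br^2)

* juvenile survival (logit link)::

      s_j = logistic(g0 + g1*T_at + g2*T_at^2 + g3*P_wn + g4*P_wn^2)

* adult survival (logit link, winter minimum temperature linear only)::

      s_a = logistic(d0 + d1*T_wn + d2*P_wn + d3*P_wn^2)

Winter minimum temperature is excluded from juvenile survival (it is highly
collinear with autumn temperature), so the 14 coefficients above are the
complete DCR parameterization.

Fecundity ``rho_max`` is the expected number of independent female juveniles
per adult female per year at vanishing density.  Density dependence acts
multiplicatively and locally::

    rho(n_i) = rho_max * exp(-n_i * b_i),   b_i = b * 100 / h_i

where ``n_i`` is the adult-female density of cell *i* (per 1-km cell),
``1/b`` the overall resource availability and ``h_i`` the 0..100 habitat
suitability.  Cells with ``h_i = 0`` support no reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: canonical order of the 14 DCR coefficients
COEF_NAMES = (
    "fec_0", "fec_Tbr", "fec_Tbr2", "fec_Pbr", "fec_Pbr2",
    "sj_0", "sj_Tat", "sj_Tat2", "sj_Pwn", "sj_Pwn2",
    "sa_0", "sa_Twn", "sa_Pwn", "sa_Pwn2",
)

FEC = slice(0, 5)
SJ = slice(5, 10)
SA = slice(10, 14)

PREDICTORS_USED = ("T_br", "P_br", "T_at", "T_wn", "P_wn")

#: which predictors drive which rate (temperature-like, precipitation-like)
RATE_PREDICTORS = {
    "fecundity": ("T_br", "P_br"),
    "juvenile_survival": ("T_at", "P_wn"),
    "adult_survival": ("T_wn", "P_wn"),
}

# linear predictors are clipped before exp/logistic; implementation guard
# against overflow, not model content
_ETA_CLIP = 50.0


def _logistic(eta):
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))


def fecundity_max(t_br, p_br, beta) -> np.ndarray:
    """Low-density fecundity ``rho_max`` from the quadratic log-linear DCR."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[-1] != 5:
        raise ValueError("fecundity DCR takes 5 coefficients")
    t = np.asarray(t_br, dtype=float)
    p = np.asarray(p_br, dtype=float)
    eta = beta[0] + beta[1] * t + beta[2] * t * t + beta[3] * p + beta[4] * p * p
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def density_rate(b: float, h) -> np.ndarray:
    """Local density-dependence rate ``b_i = b * 100 / h_i`` (inf where h=0)."""
    if b <= 0:
        raise ValueError("density-dependence strength b must be > 0")
    h = np.asarray(h, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(h > 0, b * 100.0 / np.where(h > 0, h, 1.0), np.inf)


def fecundity_realized(rho_max, n, h, b: float) -> np.ndarray:
    """Realized fecundity ``rho_max * exp(-n * b_i)``; 0 on unsuitable cells."""
    if b <= 0:
        raise ValueError("density-dependence strength b must be > 0")
    rho_max = np.asarray(rho_max, dtype=float)
    n = np.asarray(n, dtype=float)
    h = np.asarray(h, dtype=float)
    hs = np.where(h > 0, h, 1.0)
    rho = rho_max * np.exp(-n * (b * 100.0 / hs))
    return np.where(h > 0, rho, 0.0)


def survival(t, p, coeffs, t_order: int = 2) -> np.ndarray:
    """Survival probability from the logistic DCR.

    ``t_order`` is the polynomial order of the temperature effect (2 for
    juvenile survival on autumn temperature, 1 for adult survival on winter
    minimum temperature); precipitation always enters quadratically.  The
    coefficient vector must have ``1 + t_order + 2`` entries, ordered
    intercept, temperature terms, precipitation terms.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if t_order not in (1, 2):
        raise ValueError("t_order must be 1 or 2")
    if coeffs.shape[-1] != 1 + t_order + 2:
        raise ValueError(
            f"survival DCR with t_order={t_order} takes {1 + t_order + 2} coefficients, "
            f"got {coeffs.shape[-1]}"
        )
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    eta = coeffs[0] + coeffs[1] * t
    k = 2
    if t_order == 2:
        eta = eta + coeffs[2] * t * t
        k = 3
    eta = eta + coeffs[k] * p + coeffs[k + 1] * p * p
    return _logistic(eta)


@dataclass
class RateMaps:
    """Cellwise demographic rates for one year (pre-density-dependence)."""

    rho_max: np.ndarray
    s_j: np.ndarray
    s_a: np.ndarray
    year: int


@dataclass
class RateStack:
    """Demographic rates for all years at once, shape ``(years, rows, cols)``."""

    rho_max: np.ndarray
    s_j: np.ndarray
    s_a: np.ndarray
    years: np.ndarray

    def at(self, year_index: int) -> RateMaps:
        return RateMaps(
            rho_max=self.rho_max[year_index],
            s_j=self.s_j[year_index],
            s_a=self.s_a[year_index],
            year=int(self.years[year_index]),
        )


def rate_maps_all(coeffs, climate, habitat=None, years=None) -> RateStack:
    """Vectorized :func:`rate_maps` over every year of the stack."""
    if climate.std is None:
        raise ValueError("rate_maps expects a standardized climate stack")
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (14,):
        raise ValueError("expected the 14 DCR coefficients")
    if years is None:
        years = climate.years
    years = np.asarray(years, dtype=int)
    sel = np.array([climate.year_index(int(y)) for y in years])
    g = {p: climate.data[p][sel] for p in PREDICTORS_USED}
    rho = fecundity_max(g["T_br"], g["P_br"], coeffs[FEC])
    s_j = survival(g["T_at"], g["P_wn"], coeffs[SJ], t_order=2)
    s_a = survival(g["T_wn"], g["P_wn"], coeffs[SA], t_order=1)
    if habitat is not None:
        h = np.asarray(habitat)
        if h.shape != rho.shape[1:]:
            raise ValueError("habitat grid shape does not match climate grid")
        unsuit = h <= 0
        rho = np.where(unsuit, 0.0, rho)
        s_j = np.where(unsuit, 0.0, s_j)
        s_a = np.where(unsuit, 0.0, s_a)
    return RateStack(rho_max=rho, s_j=s_j, s_a=s_a, years=years)


def rate_maps(coeffs, climate, year: int, habitat=None) -> RateMaps:
    """Apply the three DCRs cellwise for one year of a standardized stack.

    Density dependence is not applied here (it needs the running population
    state and is applied inside the simulation).  If ``habitat`` is given,
    rates on unsuitable cells are zeroed.
    """
    if climate.std is None:
        raise ValueError("rate_maps expects a standardized climate stack")
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (14,):
        raise ValueError("expected the 14 DCR coefficients")
    yi = climate.year_index(year)
    g = {p: climate.data[p][yi] for p in RATE_PREDICTORS["fecundity"] + ("T_at", "T_wn", "P_wn")}
    rho = fecundity_max(g["T_br"], g["P_br"], coeffs[FEC])
    s_j = survival(g["T_at"], g["P_wn"], coeffs[SJ], t_order=2)
    s_a = survival(g["T_wn"], g["P_wn"], coeffs[SA], t_order=1)
    if habitat is not None:
        h = np.asarray(habitat)
        if h.shape != rho.shape:
            raise ValueError("habitat grid shape does not match climate grid")
        unsuit = h <= 0
        rho = np.where(unsuit, 0.0, rho)
        s_j = np.where(unsuit, 0.0, s_j)
        s_a = np.where(unsuit, 0.0, s_a)
    return RateMaps(rho_max=rho, s_j=s_j, s_a=s_a, year=int(year))


def _rate_eval(rate_id, coeffs, t, p, b=None, h=None, n=1.0):
    if rate_id == "fecundity":
        rho = fecundity_max(t, p, coeffs[FEC])
        if b is None or h is None:
            raise ValueError("fecundity response needs b and h")
        return fecundity_realized(rho, n, h, b)
    if rate_id == "juvenile_survival":
        return survival(t, p, coeffs[SJ], t_order=2)
    if rate_id == "adult_survival":
        return survival(t, p, coeffs[SA], t_order=1)
    raise ValueError(f"unknown rate {rate_id!r}")


def response_curve(
    coeff_draws,
    rate_id: str,
    predictor_id: str,
    climate_sample: dict[str, np.ndarray],
    b_draws=None,
    h_median: float = 100.0,
    n_density: float = 1.0,
    quantile_lo: float = 0.10,
    quantile_hi: float = 0.90,
    n_grid: int = 101,
) -> dict[str, np.ndarray]:
    """Conditional response of one rate to one predictor across posterior draws.

    The focal predictor varies over the [q10, q90] range of the supplied
    occupied-cell climate sample (standardized units); the co-predictor is
    held at its sample median.  For fecundity the suitability is held at the
    species median and density at one breeding pair per cell, giving the
    fecundity realized at low density.  Returns the evaluation grid, the
    across-draw median and 80% / 95% envelopes.
    """
    draws = np.atleast_2d(np.asarray(coeff_draws, dtype=float))
    t_id, p_id = RATE_PREDICTORS[rate_id]
    if predictor_id not in (t_id, p_id):
        raise ValueError(f"{predictor_id} does not drive {rate_id}")
    focal = np.asarray(climate_sample[predictor_id], dtype=float)
    if focal.size == 0:
        raise ValueError("empty climate sample")
    other_id = p_id if predictor_id == t_id else t_id
    other_med = float(np.median(np.asarray(climate_sample[other_id], dtype=float)))
    lo, hi = np.quantile(focal, [quantile_lo, quantile_hi])
    x = np.linspace(lo, hi, n_grid)
    if b_draws is None:
        b_draws = [None] * len(draws)
    curves = np.empty((len(draws), n_grid))
    for i, (c, b) in enumerate(zip(draws, b_draws)):
        t = x if predictor_id == t_id else other_med
        p = x if predictor_id == p_id else other_med
        curves[i] = _rate_eval(rate_id, c, t, p, b=b, h=h_median, n=n_density)
    q = np.quantile(curves, [0.5, 0.10, 0.90, 0.025, 0.975], axis=0)
    return {
        "x": x,
        "median": q[0],
        "lo80": q[1],
        "hi80": q[2],
        "lo95": q[3],
        "hi95": q[4],
        "draws": curves,
    }
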