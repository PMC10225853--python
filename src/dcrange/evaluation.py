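"""Goodness-of-fit and discriminatory power of posterior predictions.

Four complementary measures:

* **RMSE** between predicted and observed site-year counts;
* **spatio-temporal c-index** (Harrell's concordance): the probability that a
  randomly chosen pair of site-years with different observed counts is ranked
  in the same order by the predictions (ties in the prediction score 1/2);
* **mean yearly spatial AUC**: abundance predictions are compressed to
  presence-absence, replicate-averaged into per-cell occupancy probabilities,
  scored against observed presence with a ROC AUC per year, and averaged
  over years;
* **temporal c-index**: the c-index between the predicted relative total
  abundance series and an externally supplied reference abundance index.

Site-level predictions default to the replicate mean of simulated adults at
the surveyed cell (block-level aggregation is available via the calibration
module's aggregator).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score


def rmse(pred, obs) -> float:
    """Root mean squared error over paired values."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    if pred.size == 0:
        raise ValueError("empty pairs")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValueError("pairs must be finite")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def c_index(pred, obs) -> float:
    """Harrell's concordance index.

    Over all pairs with distinct observed values, a pair scores 1 when the
    predictions rank it like the observations, 1/2 when the predictions tie,
    and 0 otherwise.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length and non-empty")
    do = obs[:, None] - obs[None, :]
    dp = pred[:, None] - pred[None, :]
    usable = do > 0  # each unordered pair counted once, oriented by obs
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("all observed values tied; c-index undefined")
    concordant = (dp[usable] > 0).sum()
    ties = (dp[usable] == 0).sum()
    return float((concordant + 0.5 * ties) / n_usable)


def site_predictions(sim: np.ndarray, survey: pd.DataFrame, years) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-mean predicted abundance aligned with observed counts.

    ``sim`` has shape (year, rep, row, col).  Returns ``(pred, obs)`` over
    the survey's site-year records.
    """
    years = np.asarray(years, dtype=int)
    year_index = {int(y): i for i, y in enumerate(years)}
    obs_rows = survey[survey["year"].isin(set(year_index))]
    t = obs_rows["year"].map(year_index).to_numpy(dtype=int)
    r = obs_rows["y_cell"].to_numpy(dtype=int)
    c = obs_rows["x_cell"].to_numpy(dtype=int)
    mean_sim = sim.mean(axis=1)
    return mean_sim[t, r, c], obs_rows["count"].to_numpy(dtype=float)


def spatial_auc(occupancy_prob: np.ndarray, observed_presence: np.ndarray) -> tuple[float, list]:
    """Mean yearly AUC of occupancy probability against observed presence.

    Both inputs have shape ``(years, units)``; years lacking both a presence
    and an absence are skipped with a warning.  Returns the mean AUC and the
    per-year values (``nan`` for skipped years).
    """
    occ = np.asarray(occupancy_prob, dtype=float)
    pres = np.asarray(observed_presence)
    if occ.shape != pres.shape:
        raise ValueError("occupancy and presence arrays must match")
    per_year = []
    for t in range(occ.shape[0]):
        y = (pres[t] > 0).astype(int)
        if y.min() == y.max():
            warnings.warn(f"year index {t} has a single class; skipped in spatial AUC")
            per_year.append(float("nan"))
            continue
        per_year.append(float(roc_auc_score(y, occ[t])))
    valid = [v for v in per_year if np.isfinite(v)]
    if not valid:
        raise ValueError("no year with both presence and absence")
    return float(np.mean(valid)), per_year


def occupancy_probability(sim: np.ndarray) -> np.ndarray:
    """Per cell-year occupancy probability: replicate mean of (abundance > 0)."""
    return (sim > 0).mean(axis=1)


def temporal_c_index(relative_pred, reference_index, years_pred=None, years_ref=None) -> float:
    """c-index of the predicted relative-abundance series against a reference index."""
    if years_pred is not None or years_ref is not None:
        if years_pred is None or years_ref is None or not np.array_equal(
            np.asarray(years_pred), np.asarray(years_ref)
        ):
            raise ValueError("prediction and reference series not aligned on years")
    return c_index(relative_pred, reference_index)


def relative_abundance(totals: np.ndarray, reference_index: int = 0) -> pd.DataFrame:
    """Relative total-abundance envelopes across posterior draws/replicates.

    ``totals`` has shape ``(series, years)`` where each series is one
    trajectory of total adults (one posterior draw x replicate).  Series
    extinct at the reference year are excluded with a warning; the count of
    exclusions is stored in ``df.attrs['n_excluded']``.  Returns per-year
    median, 80% and 95% envelopes of ``total / total[reference]``.
    """
    totals = np.atleast_2d(np.asarray(totals, dtype=float))
    ref = totals[:, reference_index]
    keep = ref > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} series extinct at the reference year excluded")
    if not keep.any():
        raise ValueError("all series extinct at the reference year")
    rel = totals[keep] / ref[keep, None]
    q = np.quantile(rel, [0.5, 0.10, 0.90, 0.025, 0.975], axis=0)
    df = pd.DataFrame({
        "median": q[0], "lo80": q[1], "hi80": q[2], "lo95": q[3], "hi95": q[4],
    })
    df.attrs["n_excluded"] = n_excluded
    return df
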