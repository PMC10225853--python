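"""Spatially explicit, stochastic, two-stage population and dispersal dynamics.

The model tracks female individuals of two stages (juvenile, breeding adult)
per 1-km grid cell.  Within a simulated year the processes run in fixed
order:

1. **reproduce** - each cell produces ``Poisson(n_i * rho(n_i))`` juveniles,
   with realized fecundity from the density-dependent DCR;
2. **disperse**  - each juvenile emigrates with probability ``p_e``; an
   emigrant draws a distance from an exponential kernel with mean ``d_mean``
   and a uniform direction from its natal cell centre, settles in the
   destination cell if suitable, otherwise in a uniformly chosen suitable
   cell among the destination's eight neighbours, and otherwise dies
   (dispersal mortality is additive to annual juvenile mortality);
3. **survive_and_transition** - juveniles survive with the cell's ``s_j``,
   adults with ``s_a``; surviving juveniles mature, so next year's adults are
   the survivors of both stages.

Individuals within a stage and cell are exchangeable, so the individual-based
draws are realized as per-cell Poisson/binomial/multinomial variates -
distributionally identical to per-individual Bernoulli/Poisson draws (a
per-individual reference mode exists for equivalence testing) and much
faster; random draws touch occupied cells only.  Dispersal endpoints beyond
the grid (which should carry a boundary buffer around the region of
interest) are deaths.

Reproducibility: every random draw comes from a counter-based (Philox)
stream keyed by ``(seed, year-index, process)`` (and replicate where
applicable), so runs are exactly repeatable and replicates independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dcr

# process ids for RNG stream derivation
_INIT, _REPRO, _DISP, _SURV = 0, 1, 2, 3

_NEIGHBOURS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)], dtype=np.int64
)


def stream(seed: int, *key: int) -> np.random.Generator:
    """Counter-based RNG stream derived from a master seed and an integer key.

    The master seed occupies the high bits of a 128-bit Philox key; up to two
    16-bit key components (e.g. year index and process id) fill the low bits.
    """
    k = (int(seed) & 0x7FFFFFFFFFFFFFFF) << 64
    shift = 0
    for part in key:
        k ^= (int(part) & 0xFFFFFFFF) << shift
        shift += 32
    return np.random.Generator(np.random.Philox(key=k))


@dataclass
class PopulationState:
    """Per-cell female counts for one point in time."""

    adults: np.ndarray
    juveniles: np.ndarray
    year: int = 0

    def __post_init__(self) -> None:
        self.adults = np.asarray(self.adults, dtype=np.int64)
        self.juveniles = np.asarray(self.juveniles, dtype=np.int64)
        if self.adults.shape != self.juveniles.shape:
            raise ValueError("adult and juvenile grids must share a shape")
        if (self.adults < 0).any() or (self.juveniles < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_adults(self) -> int:
        return int(self.adults.sum())


@dataclass(frozen=True)
class DispersalParams:
    """Natal dispersal: emigration probability and mean kernel distance (km)."""

    p_e: float
    d_mean: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_e <= 1.0:
            raise ValueError("emigration probability must be in [0, 1]")
        if self.d_mean <= 0:
            raise ValueError("mean dispersal distance must be > 0")


class PopulationCeilingExceeded(RuntimeError):
    """Raised when a simulated population crosses the configured ceiling."""


def _as3d(arr):
    a = np.asarray(arr, dtype=np.int64)
    lead = a.shape[:-2]
    rows, cols = a.shape[-2:]
    return a.reshape(-1, rows, cols), lead, rows, cols


def reproduce(adults, rates: dcr.RateMaps, habitat, b: float, rng,
              per_individual: bool = False) -> np.ndarray:
    """Juvenile cohort per cell: ``Poisson(n_i * rho(n_i))``; adults unchanged.

    ``adults`` may carry leading replicate axes; ``habitat`` is broadcast.
    """
    if b <= 0:
        raise ValueError("density-dependence strength b must be > 0")
    a3, lead, rows, cols = _as3d(adults)
    h = np.asarray(habitat, dtype=float)
    juv = np.zeros_like(a3)
    idx = np.nonzero(a3)
    if idx[0].size:
        r, c = idx[1], idx[2]
        hv = h[r, c]
        suit = hv > 0
        n = a3[idx].astype(float)
        rho = np.zeros(len(n))
        rho[suit] = rates.rho_max[r[suit], c[suit]] * np.exp(
            -n[suit] * (b * 100.0 / hv[suit])
        )
        if per_individual:
            vals = np.zeros(len(n), dtype=np.int64)
            for i in range(len(n)):
                if rho[i] > 0:
                    vals[i] = int(rng.poisson(rho[i], size=int(n[i])).sum())
            juv[idx] = vals
        else:
            juv[idx] = rng.poisson(n * rho)
    return juv.reshape(np.asarray(adults).shape)


def draw_kernel(n: int, dp: DispersalParams, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``n`` dispersal events: exponential distances (km), uniform angles."""
    dist = rng.exponential(dp.d_mean, n)
    angle = rng.uniform(0.0, 2.0 * np.pi, n)
    return dist, angle


def disperse(juveniles, habitat, dp: DispersalParams, rng, cell_km: float = 1.0):
    """Natal dispersal of a juvenile cohort.

    ``juveniles`` has shape ``(..., rows, cols)`` (leading replicate axes
    allowed).  Returns ``(settled, deaths)`` where ``settled`` matches the
    input shape and ``deaths`` the leading shape (dispersal mortality per
    replicate).  Individual conservation holds exactly:
    ``settled.sum() + deaths.sum() == juveniles.sum()``.
    """
    juv3, lead, rows, cols = _as3d(juveniles)
    nrep = juv3.shape[0]
    suitable = np.asarray(habitat) > 0
    deaths = np.zeros(nrep, dtype=np.int64)
    settled = juv3.copy()
    if dp.p_e <= 0.0:
        return settled.reshape(np.asarray(juveniles).shape), deaths.reshape(lead)

    src = np.nonzero(juv3)
    if src[0].size:
        em = rng.binomial(juv3[src], dp.p_e)
        settled[src] -= em
        pos = em > 0
        counts = em[pos]
        n = int(counts.sum())
    else:
        n = 0
    if n:
        rep = np.repeat(src[0][pos], counts)
        r0 = np.repeat(src[1][pos], counts)
        c0 = np.repeat(src[2][pos], counts)
        dist, angle = draw_kernel(n, dp, rng)
        dist = dist / cell_km
        # continuous endpoint from the natal cell centre; the destination is
        # the cell containing it
        rr = np.floor(r0 + 0.5 + dist * np.sin(angle)).astype(np.int64)
        cc = np.floor(c0 + 0.5 + dist * np.cos(angle)).astype(np.int64)
        inside = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        dest_ok = np.zeros(n, dtype=bool)
        idx_in = np.nonzero(inside)[0]
        dest_ok[idx_in] = suitable[rr[idx_in], cc[idx_in]]
        lin = (rep[dest_ok] * rows + rr[dest_ok]) * cols + cc[dest_ok]

        # settlement fallback: uniformly among the suitable 8-neighbours of
        # an unsuitable (but in-grid) destination
        fail = inside & ~dest_ok
        fi = np.nonzero(fail)[0]
        died_n = int((~inside).sum())
        dead_reps = [rep[~inside]]
        if fi.size:
            nr = rr[fi, None] + _NEIGHBOURS[:, 0]
            nc = cc[fi, None] + _NEIGHBOURS[:, 1]
            valid = (nr >= 0) & (nr < rows) & (nc >= 0) & (nc < cols)
            suit = np.zeros(valid.shape, dtype=bool)
            suit[valid] = suitable[nr[valid], nc[valid]]
            k = suit.sum(axis=1)
            has = k > 0
            if has.any():
                pick = (rng.random(fi.size) * k).astype(np.int64)
                cum = np.cumsum(suit, axis=1)
                sel = np.argmax(cum > pick[:, None], axis=1)
                hi = np.nonzero(has)[0]
                lin2 = (rep[fi[hi]] * rows + nr[hi, sel[hi]]) * cols + nc[hi, sel[hi]]
                lin = np.concatenate([lin, lin2])
            dead_reps.append(rep[fi[~has]])
            died_n += int((~has).sum())
        if lin.size:
            settled += np.bincount(lin, minlength=nrep * rows * cols).reshape(
                nrep, rows, cols
            )
        if died_n:
            deaths += np.bincount(np.concatenate(dead_reps), minlength=nrep)

    return settled.reshape(np.asarray(juveniles).shape), deaths.reshape(lead)


def survive_and_transition(adults, juveniles, rates: dcr.RateMaps, rng,
                           per_individual: bool = False):
    """Annual survival and stage transition.

    Juveniles (post-dispersal, judged by their settlement cell's ``s_j``)
    that survive mature into adults; adults survive with ``s_a``.  Returns
    ``(new_adults, new_juveniles)`` with the juvenile grid all zero.
    """
    a3, lead, rows, cols = _as3d(adults)
    j3, _, _, _ = _as3d(juveniles)

    def _binom(counts, p_map):
        out = np.zeros_like(counts)
        idx = np.nonzero(counts)
        if idx[0].size:
            p = np.clip(p_map[idx[1], idx[2]], 0.0, 1.0)
            if per_individual:
                vals = np.empty(idx[0].size, dtype=np.int64)
                cnt = counts[idx]
                for i in range(idx[0].size):
                    vals[i] = int((rng.random(cnt[i]) < p[i]).sum())
                out[idx] = vals
            else:
                out[idx] = rng.binomial(counts[idx], p)
        return out

    surv_a = _binom(a3, np.asarray(rates.s_a, dtype=float))
    surv_j = _binom(j3, np.asarray(rates.s_j, dtype=float))
    shape = np.asarray(adults).shape
    return (surv_a + surv_j).reshape(shape), np.zeros(shape, dtype=np.int64)


def step_year(adults, rates: dcr.RateMaps, habitat, b: float, dp: DispersalParams,
              rngs, cell_km: float = 1.0, return_info: bool = False):
    """One annual cycle: reproduce -> disperse -> survive/transition.

    ``adults`` has shape ``(..., rows, cols)``; ``rngs`` is a triple of
    generators (one per process) or a single generator used for all three.
    Returns next year's adult grid (and, optionally, an accounting dict).
    """
    if isinstance(rngs, np.random.Generator):
        rngs = (rngs, rngs, rngs)
    r_rep, r_disp, r_surv = rngs
    juv = reproduce(adults, rates, habitat, b, r_rep)
    settled, disp_deaths = disperse(juv, habitat, dp, r_disp, cell_km=cell_km)
    new_adults, _ = survive_and_transition(adults, settled, rates, r_surv)
    if return_info:
        info = {
            "produced": int(juv.sum()),
            "settled": int(settled.sum()),
            "dispersal_deaths": int(np.asarray(disp_deaths).sum()),
            "pre_survival_adults": int(np.asarray(adults).sum()),
            "pre_survival_juveniles": int(settled.sum()),
        }
        return new_adults, info
    return new_adults


try:  # compiled annual-cycle kernel; the numpy functions above are the reference
    import numba as _numba

    @_numba.njit(cache=False)
    def _year_kernel(adults, juv_buf, rho_max, s_j, s_a, dd, suitable,
                     nbr_ids, nbr_cnt, rows, cols, p_e, d_mean_cells, seed,
                     max_count):
        """One annual cycle in place; returns 1 when the per-replicate
        offspring production crosses ``max_count`` (caller treats that as a
        population-ceiling breach and aborts)."""
        np.random.seed(seed)
        B, S = adults.shape
        two_pi = 2.0 * np.pi
        for b in range(B):
            for s in range(S):
                juv_buf[b, s] = 0
            produced_total = 0.0
            # reproduction + per-individual dispersal
            for s in range(S):
                n = adults[b, s]
                if n == 0 or not suitable[s]:
                    continue
                lam = n * rho_max[s] * np.exp(-n * dd[s])
                if lam <= 0.0:
                    continue
                if lam > max_count:
                    return 1
                produced = np.random.poisson(lam)
                produced_total += produced
                if produced_total > max_count:
                    return 1
                if produced == 0:
                    continue
                if p_e <= 0.0:
                    juv_buf[b, s] += produced
                    continue
                emig = np.random.binomial(produced, p_e)
                juv_buf[b, s] += produced - emig
                r0 = s // cols
                c0 = s % cols
                for _ in range(emig):
                    dist = np.random.exponential(d_mean_cells)
                    ang = np.random.random() * two_pi
                    rr = int(np.floor(r0 + 0.5 + dist * np.sin(ang)))
                    cc = int(np.floor(c0 + 0.5 + dist * np.cos(ang)))
                    if rr < 0 or rr >= rows or cc < 0 or cc >= cols:
                        continue  # beyond the (buffered) grid: death
                    t = rr * cols + cc
                    if suitable[t]:
                        juv_buf[b, t] += 1
                    elif nbr_cnt[t] > 0:
                        pick = int(np.random.random() * nbr_cnt[t])
                        juv_buf[b, nbr_ids[t, pick]] += 1
                    # else: no suitable neighbour, death
            # survival and stage transition
            for s in range(S):
                na = adults[b, s]
                nj = juv_buf[b, s]
                x = np.random.binomial(na, s_a[s]) if na > 0 else 0
                y = np.random.binomial(nj, s_j[s]) if nj > 0 else 0
                adults[b, s] = x + y
        return 0

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False


def _neighbour_tables(suitable_flat: np.ndarray, rows: int, cols: int):
    """Per-cell list of suitable 8-neighbour linear ids (for settlement fallback)."""
    S = rows * cols
    nbr_ids = np.zeros((S, 8), dtype=np.int64)
    nbr_cnt = np.zeros(S, dtype=np.int64)
    rr, cc = np.divmod(np.arange(S), cols)
    for dr, dc in _NEIGHBOURS:
        nr, nc = rr + dr, cc + dc
        ok = (nr >= 0) & (nr < rows) & (nc >= 0) & (nc < cols)
        lin = nr * cols + nc
        ok[ok] &= suitable_flat[lin[ok]]
        idx = np.nonzero(ok)[0]
        nbr_ids[idx, nbr_cnt[idx]] = lin[idx]
        nbr_cnt[idx] += 1
    return nbr_ids, nbr_cnt


def _simulate_fast(theta, rstack, habitat, initial_states, seeds_per_year, cell_km,
                   max_total_adults=None):
    """Run all replicates through the compiled kernel; one seed per year."""
    rows, cols = habitat.shape
    S = rows * cols
    suitable = (habitat > 0).ravel()
    nbr_ids, nbr_cnt = _neighbour_tables(suitable, rows, cols)
    h = habitat.ravel().astype(float)
    dd = np.where(suitable, theta.b * 100.0 / np.where(suitable, h, 1.0), np.inf)
    adults = initial_states.reshape(len(initial_states), S).astype(np.int64)
    juv_buf = np.zeros_like(adults)
    n_years = rstack.rho_max.shape[0]
    max_count = _offspring_cap(max_total_adults)
    out = np.empty((n_years, len(adults), rows, cols), dtype=np.int64)
    for yi in range(n_years):
        breach = _year_kernel(
            adults, juv_buf,
            np.ascontiguousarray(rstack.rho_max[yi].ravel()),
            np.ascontiguousarray(rstack.s_j[yi].ravel()),
            np.ascontiguousarray(rstack.s_a[yi].ravel()),
            dd, suitable, nbr_ids, nbr_cnt,
            rows, cols, float(theta.p_e), float(theta.d_mean) / cell_km,
            int(seeds_per_year[yi]), max_count,
        )
        if breach or (max_total_adults is not None
                      and int(adults.sum(axis=1).max()) > max_total_adults):
            raise PopulationCeilingExceeded(
                f"replicate population exceeded {max_total_adults} adults")
        out[yi] = adults.reshape(-1, rows, cols)
    return out


def _offspring_cap(max_total_adults) -> float:
    """Within-year offspring cap handed to the kernel.

    The factor 4 leaves room for legitimately juvenile-heavy years; without a
    configured ceiling a very large guard still prevents per-individual loops
    over astronomically many offspring.
    """
    if max_total_adults is None:
        return 1e9
    return 4.0 * float(max_total_adults)


def iter_years(theta, climate, habitat, initial, n_reps: int = 1, seed: int = 0,
               years=None, cell_km: float | None = None,
               max_total_adults: int | None = None):
    """Generator over the annual cycle: yields ``(year_index, adults)`` with
    ``adults`` of shape ``(n_reps, rows, cols)`` after each year's cycle.

    Runs on the compiled kernel (the consumer may stop early, e.g. when a
    likelihood bound is crossed, without paying for the remaining years).
    Raises :class:`PopulationCeilingExceeded` when any replicate's adults or
    within-year offspring production crosses the configured ceiling.
    """
    habitat = np.asarray(habitat)
    if climate.shape != habitat.shape:
        raise ValueError("climate and habitat grids do not match")
    if years is None:
        years = climate.years
    years = np.asarray(years, dtype=int)
    if cell_km is None:
        cell_km = climate.cell_km
    rstack = dcr.rate_maps_all(theta.coeffs, climate, habitat=habitat, years=years)
    rows, cols = habitat.shape
    S = rows * cols
    suitable = (habitat > 0).ravel()
    nbr_ids, nbr_cnt = _neighbour_tables(suitable, rows, cols)
    h = habitat.ravel().astype(float)
    dd = np.where(suitable, theta.b * 100.0 / np.where(suitable, h, 1.0), np.inf)

    def initial_state(rng):
        st = initial(rng) if callable(initial) else initial
        return np.asarray(st.adults, dtype=np.int64)

    adults = np.stack([initial_state(stream(seed, k, _INIT)).ravel()
                       for k in range(n_reps)])
    juv_buf = np.zeros_like(adults)
    yseeds = stream(seed, 1, _REPRO).integers(2**31 - 1, size=len(years))
    if not _HAVE_NUMBA:  # pragma: no cover - numba is installed in practice
        dp = DispersalParams(p_e=theta.p_e, d_mean=theta.d_mean)
        grid = adults.reshape(-1, rows, cols)
        for yi in range(len(years)):
            rngs = tuple(stream(seed, yi, p) for p in (_REPRO, _DISP, _SURV))
            grid = step_year(grid, rstack.at(yi), habitat, theta.b, dp, rngs,
                             cell_km=cell_km)
            _check_ceiling(grid, max_total_adults)
            yield yi, grid
        return
    max_count = _offspring_cap(max_total_adults)
    for yi in range(len(years)):
        breach = _year_kernel(
            adults, juv_buf,
            np.ascontiguousarray(rstack.rho_max[yi].ravel()),
            np.ascontiguousarray(rstack.s_j[yi].ravel()),
            np.ascontiguousarray(rstack.s_a[yi].ravel()),
            dd, suitable, nbr_ids, nbr_cnt,
            rows, cols, float(theta.p_e), float(theta.d_mean) / cell_km,
            int(yseeds[yi]), max_count,
        )
        if breach or (max_total_adults is not None
                      and int(adults.sum(axis=1).max()) > max_total_adults):
            raise PopulationCeilingExceeded(
                f"replicate population exceeded ceiling {max_total_adults}")
        yield yi, adults.reshape(-1, rows, cols)


def simulate(
    theta,
    climate,
    habitat,
    initial,
    n_reps: int = 1,
    seed: int = 0,
    years=None,
    rep_seeds=None,
    cell_km: float | None = None,
    engine: str = "auto",
    max_total_adults: int | None = None,
) -> np.ndarray:
    """Replicate IBM trajectories; returns adults with shape (year, rep, row, col).

    ``theta`` is a :class:`dcrange.calibration.ParameterVector` (or anything
    with ``coeffs``, ``b``, ``p_e``, ``d_mean``).  ``initial`` is a
    :class:`PopulationState` shared by all replicates or a callable
    ``initial(rng) -> PopulationState`` sampled independently per replicate.
    The recorded abundance for year *y* is the adult count after that year's
    full annual cycle.

    By default all replicates advance together on streams keyed by
    ``(seed, year, process)``.  Passing ``rep_seeds`` (one master seed per
    replicate) instead runs replicates on fully independent per-replicate
    streams - identical seeds then yield identical replicates.

    ``engine='auto'`` uses a compiled annual-cycle kernel (identical process
    model and distributions, different random number consumption);
    ``engine='reference'`` forces the plain numpy implementation above.
    ``max_total_adults``, when given, raises
    :class:`PopulationCeilingExceeded` as soon as any replicate's total adult
    count crosses it - a guard for calibration, where such trajectories have
    astronomically poor likelihood anyway.
    """
    habitat = np.asarray(habitat)
    if climate.shape != habitat.shape:
        raise ValueError("climate and habitat grids do not match")
    if years is None:
        years = climate.years
    years = np.asarray(years, dtype=int)
    if cell_km is None:
        cell_km = climate.cell_km
    dp = DispersalParams(p_e=theta.p_e, d_mean=theta.d_mean)
    rstack = dcr.rate_maps_all(theta.coeffs, climate, habitat=habitat, years=years)
    rows, cols = climate.shape
    use_fast = _HAVE_NUMBA if engine == "auto" else (engine == "fast")
    if engine not in ("auto", "fast", "reference"):
        raise ValueError("engine must be 'auto', 'fast' or 'reference'")
    if engine == "fast" and not _HAVE_NUMBA:
        raise RuntimeError("compiled engine requested but numba is unavailable")

    def initial_state(rng) -> np.ndarray:
        st = initial(rng) if callable(initial) else initial
        return np.asarray(st.adults, dtype=np.int64)

    out = np.empty((len(years), n_reps, rows, cols), dtype=np.int64)
    if rep_seeds is not None:
        if len(rep_seeds) != n_reps:
            raise ValueError("rep_seeds must have one entry per replicate")
        for k, rs in enumerate(rep_seeds):
            init = initial_state(stream(rs, 0, _INIT))[None]
            if use_fast:
                yseeds = stream(rs, 1, _REPRO).integers(2**31 - 1, size=len(years))
                out[:, k] = _simulate_fast(theta, rstack, habitat, init, yseeds,
                                           cell_km, max_total_adults)[:, 0]
            else:
                adults = init
                for yi in range(len(years)):
                    rngs = tuple(stream(rs, yi, p) for p in (_REPRO, _DISP, _SURV))
                    adults = step_year(adults, rstack.at(yi), habitat, theta.b, dp, rngs,
                                       cell_km=cell_km)
                    _check_ceiling(adults, max_total_adults)
                    out[yi, k] = adults[0]
        return out

    init = np.stack([initial_state(stream(seed, k, _INIT)) for k in range(n_reps)])
    if use_fast:
        yseeds = stream(seed, 1, _REPRO).integers(2**31 - 1, size=len(years))
        return _simulate_fast(theta, rstack, habitat, init, yseeds, cell_km,
                              max_total_adults)
    adults = init
    for yi in range(len(years)):
        rngs = tuple(stream(seed, yi, p) for p in (_REPRO, _DISP, _SURV))
        adults = step_year(adults, rstack.at(yi), habitat, theta.b, dp, rngs,
                           cell_km=cell_km)
        _check_ceiling(adults, max_total_adults)
        out[yi] = adults
    return out


def _check_ceiling(adults, max_total_adults):
    if max_total_adults is not None:
        if int(adults.reshape(adults.shape[0], -1).sum(axis=1).max()) > max_total_adults:
            raise PopulationCeilingExceeded(
                f"replicate population exceeded {max_total_adults} adults")
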