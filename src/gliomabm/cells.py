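"""Cell agents: PDGF dose response, phenotypes, cycling, division, activation.

Three cell kinds are modeled.  *Infected* cells over-express PDGF (secreting
it into the field and enjoying a constant autocrine boost), *recruited*
cells are normal progenitors already responding to PDGF, and *recruitable*
cells are a background field of inactive progenitors that permanently
activate into recruited cells once local paracrine PDGF exceeds
5e-4 ng/mL.

Each cell carries an inherited *potential* phenotype — intermitotic time
τ (h) and maximal migration speed v (μm/h) — copied exactly to daughters.
The *observed* phenotype is the potential scaled by the Hill-type PDGF
response γ ∈ [0, 1):

    infected:   γ = (C_PA + C_PP) / (C_PA + C_PP + K)
    recruited:  γ = C_PP / (C_PP + β K)

evaluated separately for proliferation (K_p, β_p) and migration (K_m, β_m).

For performance the population is held as a structure-of-arrays
(:class:`CellPopulation`) rather than one object per cell; a per-cell view
is available through :meth:`CellPopulation.as_dataframe`.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .tissue import TissueDomain, OutsideTissueError, EMPTY

INFECTED = 1
RECRUITED = 2

LINEAGE_NAMES = {INFECTED: "infected", RECRUITED: "recruited"}

CELL_DIAMETER_UM = 25.0
CELL_RADIUS_UM = 12.5

ACTIVATION_THRESHOLD = 5.0e-4  # ng/mL of paracrine PDGF
GAMMA_CUTOFF = 1.0e-3

TAU_MIN_H = 5.0
V_MAX_UM_H = 100.0


@dataclasses.dataclass(frozen=True)
class Phenotype:
    """Inherited potential phenotype: p_pot = 1/tau, m_pot = v."""

    tau: float  # intermitotic time, h
    v: float  # maximal migration speed, μm/h

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("intermitotic time must be positive")
        if self.v < 0:
            raise ValueError("migration speed must be non-negative")


@dataclasses.dataclass
class ResponseParams:
    K_p: float
    K_m: float
    p_a: float  # autocrine boost C_PA for infected cells
    beta_p: float
    beta_m: float
    activation_threshold: float = ACTIVATION_THRESHOLD
    gamma_cutoff: float = GAMMA_CUTOFF


def gamma_response(c_pp, lineage, K, beta, p_a):
    """Hill-type PDGF response, vectorized over cells.

    ``lineage`` may be a scalar or an int array; infected cells get the
    autocrine boost, recruited cells the lowered half-max β·K.
    """
    c_pp = np.asarray(c_pp, dtype=np.float64)
    lineage = np.asarray(lineage)
    infected = (c_pp + p_a) / (c_pp + p_a + K)
    recruited = c_pp / (c_pp + beta * K)
    out = np.where(lineage == INFECTED, infected, recruited)
    return out if out.ndim else float(out)


def observed_phenotype(tau, v, lineage, c_pp, resp: ResponseParams,
                       am_factor: float = 1.0):
    """Observed (p, m) = (γ_p/τ, γ_m·v), with the γ ≤ 0.001 activity cutoff.

    ``am_factor`` scales migration speed while an anti-migratory treatment
    is active.
    """
    g_p = gamma_response(c_pp, lineage, resp.K_p, resp.beta_p, resp.p_a)
    g_m = gamma_response(c_pp, lineage, resp.K_m, resp.beta_m, resp.p_a)
    g_p = np.where(g_p <= resp.gamma_cutoff, 0.0, g_p)
    g_m = np.where(g_m <= resp.gamma_cutoff, 0.0, g_m)
    p = g_p / np.asarray(tau, dtype=np.float64)
    m = g_m * np.asarray(v, dtype=np.float64) * am_factor
    return p, m


def advance_cycle(cycle_progress, p, dt, local_count, capacity):
    """One proliferation/quiescence update (vectorized).

    Returns ``(new_progress, quiescent, divides)``.  Cells whose density
    node holds strictly more cells than its capacity are quiescent: their
    cycle clock freezes where it is.  Others advance by ``p*dt`` and emit a
    division event when the clock reaches 1, resetting to 0.
    """
    cycle_progress = np.asarray(cycle_progress, dtype=np.float64)
    quiescent = np.asarray(local_count) > np.asarray(capacity)
    new = np.where(quiescent, cycle_progress, cycle_progress + np.asarray(p) * dt)
    divides = ~quiescent & (new >= 1.0)
    new = np.where(divides, 0.0, new)
    return new, quiescent, divides


def place_daughters(parent_x, parent_y, domain: TissueDomain, rng,
                    max_attempts: int = 10):
    """Daughter positions one cell radius from each parent at a random angle.

    Angles landing in EMPTY are redrawn up to ``max_attempts`` times; if all
    fail the daughter is placed atop its parent.
    """
    parent_x = np.asarray(parent_x, dtype=np.float64)
    parent_y = np.asarray(parent_y, dtype=np.float64)
    n = parent_x.size
    x = parent_x.copy()
    y = parent_y.copy()
    pending = np.ones(n, dtype=bool)
    for _ in range(max_attempts):
        if not pending.any():
            break
        idx = np.nonzero(pending)[0]
        ang = rng.uniform(0.0, 2.0 * np.pi, size=idx.size)
        tx = parent_x[idx] + CELL_RADIUS_UM * np.cos(ang)
        ty = parent_y[idx] + CELL_RADIUS_UM * np.sin(ang)
        ok = domain.in_tissue(tx, ty)
        good = idx[ok]
        x[good] = tx[ok]
        y[good] = ty[ok]
        pending[good] = False
    return x, y


def maybe_activate(c_pp_local, threshold: float = ACTIVATION_THRESHOLD):
    """Recruitable cells activate (permanently) when local PDGF > threshold."""
    return np.asarray(c_pp_local) > threshold


def draw_phenotypes(n: int, tau_mean: float, tau_sd: float, v_mean: float,
                    v_sd: float, rng):
    """Draw n potential phenotypes.

    τ ~ Normal(τ̄, σ_τ) truncated to [5 h, ∞); v ~ Normal(v̄, σ_v) truncated
    to [0, 100] μm/h.  σ = 0 collapses to the homogeneous model.
    """
    if tau_sd == 0:
        tau = np.full(n, max(tau_mean, TAU_MIN_H), dtype=np.float64)
    else:
        a = (TAU_MIN_H - tau_mean) / tau_sd
        tau = stats.truncnorm.rvs(a, np.inf, loc=tau_mean, scale=tau_sd,
                                  size=n, random_state=rng)
    if v_sd == 0:
        v = np.full(n, min(max(v_mean, 0.0), V_MAX_UM_H), dtype=np.float64)
    else:
        a = (0.0 - v_mean) / v_sd
        b = (V_MAX_UM_H - v_mean) / v_sd
        v = stats.truncnorm.rvs(a, b, loc=v_mean, scale=v_sd, size=n,
                                random_state=rng)
    return tau, v


class CellPopulation:
    """Structure-of-arrays container for the active (infected + recruited) cells."""

    _FIELDS = ("x", "y", "tau", "v", "cycle", "heading", "persist", "speed")

    def __init__(self, capacity: int = 1024):
        self._cap = capacity
        self.n = 0
        self._next_id = 0
        for f in self._FIELDS:
            setattr(self, f, np.zeros(capacity, dtype=np.float64))
        self.lineage = np.zeros(capacity, dtype=np.int8)
        self.quiescent = np.zeros(capacity, dtype=bool)
        self.moving = np.zeros(capacity, dtype=bool)
        self.alive = np.zeros(capacity, dtype=bool)
        self.hex_idx = np.zeros(capacity, dtype=np.int64)
        self.dens_idx = np.zeros(capacity, dtype=np.int64)
        self.cell_id = np.zeros(capacity, dtype=np.int64)
        self.parent_id = np.full(capacity, -1, dtype=np.int64)

    def _grow(self, need: int) -> None:
        new_cap = self._cap
        while new_cap < need:
            new_cap *= 2
        for name in (*self._FIELDS, "lineage", "quiescent", "moving", "alive",
                     "hex_idx", "dens_idx", "cell_id", "parent_id"):
            arr = getattr(self, name)
            grown = np.zeros(new_cap, dtype=arr.dtype)
            if name == "parent_id":
                grown[:] = -1
            grown[: self.n] = arr[: self.n]
            setattr(self, name, grown)
        self._cap = new_cap

    def add(self, x, y, tau, v, lineage, parent_id=None) -> np.ndarray:
        """Append cells; returns their slot indices."""
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        k = x.size
        if self.n + k > self._cap:
            self._grow(self.n + k)
        sl = slice(self.n, self.n + k)
        self.x[sl] = x
        self.y[sl] = np.atleast_1d(y)
        self.tau[sl] = np.atleast_1d(tau)
        self.v[sl] = np.atleast_1d(v)
        self.lineage[sl] = np.atleast_1d(lineage)
        self.cycle[sl] = 0.0
        self.quiescent[sl] = False
        self.moving[sl] = False
        self.heading[sl] = 0.0
        self.persist[sl] = 0.0
        self.speed[sl] = 0.0
        self.alive[sl] = True
        ids = self._next_id + np.arange(k, dtype=np.int64)
        self.cell_id[sl] = ids
        self.parent_id[sl] = -1 if parent_id is None else np.atleast_1d(parent_id)
        self._next_id += k
        self.n += k
        return np.arange(sl.start, sl.stop)

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self.alive[: self.n]))

    def alive_index(self) -> np.ndarray:
        return np.nonzero(self.alive[: self.n])[0]

    def compact(self) -> None:
        """Drop dead slots (called occasionally by the engine)."""
        keep = np.nonzero(self.alive[: self.n])[0]
        for name in (*self._FIELDS, "lineage", "quiescent", "moving", "alive",
                     "hex_idx", "dens_idx", "cell_id", "parent_id"):
            arr = getattr(self, name)
            arr[: keep.size] = arr[keep]
        self.n = keep.size

    def as_dataframe(self):
        import pandas as pd

        idx = self.alive_index()
        return pd.DataFrame(
            {
                "id": self.cell_id[idx],
                "parent_id": self.parent_id[idx],
                "lineage": [LINEAGE_NAMES[int(l)] for l in self.lineage[idx]],
                "x_um": self.x[idx],
                "y_um": self.y[idx],
                "tau_h": self.tau[idx],
                "v_um_per_h": self.v[idx],
                "cycle_progress": self.cycle[idx],
                "quiescent": self.quiescent[idx],
                "state": np.where(self.moving[idx], "MOVING", "STOPPED"),
            }
        )


class RecruitableField:
    """Static background field of inactive recruitable progenitors."""

    def __init__(self, x: np.ndarray, y: np.ndarray, domain: TissueDomain):
        self.x = np.asarray(x, dtype=np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        if self.x.size:
            self.hex_idx = domain._nearest_hex_unchecked(self.x, self.y)
        else:
            self.hex_idx = np.zeros(0, dtype=np.int64)
        self.inactive = np.ones(self.x.size, dtype=bool)

    @property
    def n_inactive(self) -> int:
        return int(np.count_nonzero(self.inactive))

    def pop_activated(self, conc: np.ndarray, threshold: float = ACTIVATION_THRESHOLD):
        """Return positions of newly activated cells and mark them consumed."""
        idx = np.nonzero(self.inactive)[0]
        if idx.size == 0:
            return np.zeros(0), np.zeros(0)
        hot = maybe_activate(conc[self.hex_idx[idx]], threshold)
        act = idx[hot]
        self.inactive[act] = False
        return self.x[act], self.y[act]


def _uniform_points_in_disc(n, site, radius, domain, rng, max_rounds=200):
    """n points uniform in the disc ∩ tissue (rejection sampling)."""
    x0, y0 = site
    xs = np.empty(0)
    ys = np.empty(0)
    for _ in range(max_rounds):
        if xs.size >= n:
            break
        m = max(2 * (n - xs.size), 16)
        r = radius * np.sqrt(rng.uniform(size=m))
        ang = rng.uniform(0, 2 * np.pi, size=m)
        tx = x0 + r * np.cos(ang)
        ty = y0 + r * np.sin(ang)
        ok = domain.in_tissue(tx, ty)
        xs = np.concatenate([xs, tx[ok]])
        ys = np.concatenate([ys, ty[ok]])
    if xs.size < n:
        raise OutsideTissueError("injection disc does not intersect enough tissue")
    return xs[:n], ys[:n]


def init_population(domain: TissueDomain, params, rng):
    """Initial condition: 100 infected + 100 recruited cells in the injection
    disc, plus the recruitable background field.

    Recruitable cells are seeded per density node as Poisson with mean
    ``ρ_R % × local capacity``, uniformly placed within their node square
    (re-drawn off EMPTY pixels).
    """
    site = params.injection_site_xy(domain)
    if not bool(domain.in_tissue(*site)[0]):
        raise OutsideTissueError("injection site outside tissue")
    pop = CellPopulation()
    for lineage in (INFECTED, RECRUITED):
        x, y = _uniform_points_in_disc(params.n_initial_cells, site,
                                       params.injection_radius, domain, rng)
        tau, v = draw_phenotypes(params.n_initial_cells, params.tau_mean,
                                 params.tau_sd, params.v_mean, params.v_sd, rng)
        pop.add(x, y, tau, v, lineage)

    cap = domain.capacity_map(params.kappa)
    mean_counts = params.rho_r / 100.0 * cap
    counts = rng.poisson(mean_counts)
    rxs, rys = [], []
    s = domain.density_spacing
    for node in np.nonzero(counts)[0]:
        k = int(counts[node])
        r, c = divmod(node, domain.dens_ncols)
        got = 0
        for _ in range(20):
            if got >= k:
                break
            tx = rng.uniform(c * s, min((c + 1) * s, domain.width_um), size=k)
            ty = rng.uniform(r * s, min((r + 1) * s, domain.height_um), size=k)
            ok = domain.in_tissue(tx, ty)
            take = min(k - got, int(ok.sum()))
            rxs.append(tx[ok][:take])
            rys.append(ty[ok][:take])
            got += take
    rx = np.concatenate(rxs) if rxs else np.zeros(0)
    ry = np.concatenate(rys) if rys else np.zeros(0)
    recruitables = RecruitableField(rx, ry, domain)
    return pop, recruitables
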