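"""Stop-and-go persistent random walk with white-matter anisotropy.

Cells alternate runs and stops.  When a cell's persistence clock expires it
flips a (configurable) coin for its next state, samples a fresh persistence
time, and — if moving — picks a new heading: uniform on [0, 2π) in gray
matter, a Normal(0, σ_θ) deviation about the current heading in white
matter, where runs also last 1.5× longer.

Run/stop durations default to exponential distributions with the means
measured from the ex-vivo tracking data (42.6 min moving, 70.1 min
stopped); an empirical table of durations can be plugged in instead.

Movement per step is a straight segment of length m·dt.  Segments landing
in EMPTY space are retried at up to 10 random angles, escalating the
distance by one cell diameter per round up to 3 diameters.  A move into a
density node at/above carrying capacity is allowed only if that node is
currently less crowded than the origin node; these capacity decisions are
taken one cell at a time in randomized order with the density counters
updated transactionally (a numba kernel).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from numba import njit

from .tissue import TissueDomain, EMPTY, WHITE

MOVE_TIME_MEAN_MIN = 42.6
STOP_TIME_MEAN_MIN = 70.1
WHITE_PERSISTENCE_MULTIPLIER = 1.5
CELL_DIAMETER_UM = 25.0


@dataclasses.dataclass
class PersistenceModel:
    """Sampling model for run/stop persistence times (hours)."""

    move_time_mean: float = MOVE_TIME_MEAN_MIN / 60.0
    stop_time_mean: float = STOP_TIME_MEAN_MIN / 60.0
    move_prob: float = 0.5  # coin for the next state at each reset
    family: str = "exponential"
    empirical_move_h: np.ndarray | None = None
    empirical_stop_h: np.ndarray | None = None

    def __post_init__(self):
        if self.move_time_mean <= 0 or self.stop_time_mean <= 0:
            raise ValueError("persistence means must be positive")
        if self.family not in ("exponential", "empirical"):
            raise ValueError("family must be 'exponential' or 'empirical'")

    def sample(self, moving: np.ndarray, rng) -> np.ndarray:
        """Persistence times for cells whose next state is given by ``moving``."""
        n = moving.size
        if self.family == "empirical":
            mv = self.empirical_move_h
            st = self.empirical_stop_h
            out = np.where(moving,
                           rng.choice(mv, size=n) if mv is not None else 0.0,
                           rng.choice(st, size=n) if st is not None else 0.0)
            return out
        scale = np.where(moving, self.move_time_mean, self.stop_time_mean)
        return rng.exponential(scale)


@dataclasses.dataclass
class TurningModel:
    """Heading choice at a persistence reset.

    Gray matter: uniform on [0, 2π).  White matter: Normal(0, σ_θ) deviation
    about the current heading (persistent random walk along fiber tracts).
    """

    sigma_theta_deg: float = 20.0

    def __post_init__(self):
        if not (0.0 <= self.sigma_theta_deg <= 45.0):
            raise ValueError("σ_θ must lie in [0°, 45°]")

    def sample(self, current_heading: np.ndarray, in_white: np.ndarray, rng):
        n = current_heading.size
        uniform = rng.uniform(0.0, 2.0 * np.pi, size=n)
        deviation = rng.normal(0.0, np.deg2rad(self.sigma_theta_deg), size=n)
        return np.where(in_white, current_heading + deviation, uniform)


def update_persistence(moving, heading, persist, tissue_class, dt, persistence:
                       PersistenceModel, turning: TurningModel, rng):
    """Advance persistence clocks by dt; reset expired cells (vectorized).

    Returns updated ``(moving, heading, persist)``.  The white-matter 1.5×
    multiplier applies to moving runs only.  The tissue class is the one at
    the cell's current position.
    """
    moving = np.asarray(moving, dtype=bool).copy()
    heading = np.asarray(heading, dtype=np.float64).copy()
    persist = np.asarray(persist, dtype=np.float64) - dt
    expired = persist <= 0.0
    if expired.any():
        idx = np.nonzero(expired)[0]
        new_moving = rng.uniform(size=idx.size) < persistence.move_prob
        tau = persistence.sample(new_moving, rng)
        in_white = np.asarray(tissue_class)[idx] == WHITE
        tau = np.where(new_moving & in_white,
                       tau * WHITE_PERSISTENCE_MULTIPLIER, tau)
        heading[idx] = turning.sample(heading[idx], in_white, rng)
        moving[idx] = new_moving
        persist[idx] = tau
    return moving, heading, persist


def propose_moves(x, y, heading, step_len, domain: TissueDomain, rng,
                  n_angle_attempts: int = 10, max_extra_diameters: int = 3):
    """Resolve EMPTY-avoidance: final proposed positions and headings.

    The first attempt is ``step_len`` along the current heading; failures
    retry random angles at the same distance, then escalate the distance by
    one cell diameter per round.  Cells with no valid target stay put.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    heading = np.asarray(heading, dtype=np.float64).copy()
    step_len = np.asarray(step_len, dtype=np.float64)
    px = x + step_len * np.cos(heading)
    py = y + step_len * np.sin(heading)
    ok = domain.in_tissue(px, py)
    px = np.where(ok, px, x)
    py = np.where(ok, py, y)
    pending = ~ok
    for extra in range(max_extra_diameters + 1):
        if not pending.any():
            break
        dist = step_len + extra * CELL_DIAMETER_UM
        for _ in range(n_angle_attempts):
            idx = np.nonzero(pending)[0]
            if idx.size == 0:
                break
            ang = rng.uniform(0.0, 2.0 * np.pi, size=idx.size)
            d = dist[idx] if dist.ndim else dist
            tx = x[idx] + d * np.cos(ang)
            ty = y[idx] + d * np.sin(ang)
            good = domain.in_tissue(tx, ty)
            hit = idx[good]
            px[hit] = tx[good]
            py[hit] = ty[good]
            heading[hit] = ang[good]
            pending[hit] = False
    return px, py, heading


@njit(cache=True)
def _resolve_density_kernel(order, from_node, to_node, counts, capacity):
    """Transactional capacity check in randomized cell order.

    A cross-node move into a node at/above capacity succeeds only if the
    target currently holds fewer cells than the origin.  ``counts`` is
    updated in place; returns a move-allowed mask aligned with the inputs.
    """
    n = order.size
    allowed = np.zeros(n, dtype=np.bool_)
    for k in range(n):
        i = order[k]
        src = from_node[i]
        dst = to_node[i]
        if src == dst:
            allowed[i] = True
            continue
        if counts[dst] >= capacity[dst] and counts[dst] >= counts[src]:
            continue
        counts[src] -= 1
        counts[dst] += 1
        allowed[i] = True
    return allowed


def attempt_moves(x, y, heading, m, dt, domain: TissueDomain, counts,
                  capacity, rng):
    """Full movement update for a batch of moving cells.

    Returns ``(new_x, new_y, new_heading)``; ``counts`` (per density node)
    is updated in place for the cells that moved across nodes.
    """
    step_len = np.asarray(m, dtype=np.float64) * dt
    px, py, new_heading = propose_moves(x, y, heading, step_len, domain, rng)
    from_node = domain._nearest_density_unchecked(np.asarray(x, dtype=np.float64),
                                                  np.asarray(y, dtype=np.float64))
    to_node = domain._nearest_density_unchecked(px, py)
    order = rng.permutation(px.size)
    allowed = _resolve_density_kernel(order, from_node, to_node,
                                      counts, capacity)
    new_x = np.where(allowed, px, x)
    new_y = np.where(allowed, py, y)
    new_heading = np.where(allowed, new_heading, heading)
    return new_x, new_y, new_heading


def apply_anti_migratory(speeds, factor: float = 0.1):
    """Scale effective migration speeds while the AM treatment is on."""
    if not (0.0 < factor <= 1.0):
        raise ValueError("anti-migratory factor must lie in (0, 1]")
    return np.asarray(speeds, dtype=np.float64) * factor


def simulate_free_walk(n_cells, v, dt, duration_h, rng,
                       persistence: PersistenceModel | None = None,
                       turning: TurningModel | None = None,
                       tissue_class: int | None = None):
    """Unconstrained walkers on an infinite plane (test/diagnostic utility).

    Returns an array of positions with shape ``(n_steps+1, n_cells, 2)``.
    ``tissue_class`` fixes the turning/persistence rule (GRAY by default).
    """
    from .tissue import GRAY

    persistence = persistence or PersistenceModel()
    turning = turning or TurningModel()
    cls = np.full(n_cells, GRAY if tissue_class is None else tissue_class)
    n_steps = int(round(duration_h / dt))
    x = np.zeros(n_cells)
    y = np.zeros(n_cells)
    moving = np.zeros(n_cells, dtype=bool)
    heading = rng.uniform(0, 2 * np.pi, size=n_cells)
    persist = np.zeros(n_cells)
    out = np.zeros((n_steps + 1, n_cells, 2))
    for k in range(n_steps):
        moving, heading, persist = update_persistence(
            moving, heading, persist, cls, dt, persistence, turning, rng)
        step = np.where(moving, v * dt, 0.0)
        x = x + step * np.cos(heading)
        y = y + step * np.sin(heading)
        out[k + 1, :, 0] = x
        out[k + 1, :, 1] = y
    return out
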