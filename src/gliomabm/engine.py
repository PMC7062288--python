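"""Simulation engine: the per-step loop, treatments, and whole runs.

Each time step (default 0.25 h) executes, in order:

1. rebuild the per-density-node cell counts;
2. activation sweep of the recruitable background field;
3. the cell loop — quiescence/cycle advance, divisions, migration, PDGF
   secretion (infected cells) and consumption (all active cells);
4. field decay, then 5. diffusion;
6. anti-proliferative kill if the treatment is active;

after which time advances by dt.  All randomness flows from a single seed
through named substreams (init / division / migration) so that runs are
bit-reproducible: same parameters + seed ⇒ identical event logs.

Treatments: the anti-proliferative drug (AP) removes every active
non-quiescent cell with inherited intermitotic time below 60 h at each step
while active (quiescent cells are spared regardless of τ); the
anti-migratory drug (AM) scales every cell's effective speed to 10%.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import cells as _cells
from . import migration as _migration
from .cells import (CellPopulation, RecruitableField, ResponseParams,
                    INFECTED, RECRUITED, observed_phenotype, advance_cycle,
                    place_daughters, draw_phenotypes, init_population)
from .migration import PersistenceModel, TurningModel
from .pdgf import PDGFField
from .tissue import TissueDomain

#: Table of admissible search ranges for the 16 uncertain parameters.
TABLE1_RANGES: dict[str, tuple[float, float]] = {
    "rho_r": (0.1, 5.0),            # recruitable cell density, % of capacity
    "sigma_theta": (0.0, 45.0),     # white-matter directionality deviation, deg
    "p_0": (100.0, 600.0),          # initial PDGF bolus, ng/mL
    "D_p": (1.0e-6, 1.0e-3),        # PDGF diffusion coefficient, cm^2/day
    "r_d": (0.0, 0.5),              # PDGF decay rate, 1/day
    "r_s": (10.0, 400.0),           # PDGF secretion rate, ng/mL/cell/day
    "r_c": (0.0, 1.0),              # PDGF consumption, fraction of r_s
    "p_a": (0.1, 50.0),             # autocrine boost, ng/mL
    "K_p": (5.0, 300.0),            # half-max proliferation response, ng/mL
    "K_m": (5.0, 300.0),            # half-max migration response, ng/mL
    "beta_p": (0.1, 1.0),           # recruited proliferation sensitivity
    "beta_m": (0.1, 1.0),           # recruited migration sensitivity
    "tau_mean": (20.0, 100.0),      # mean intermitotic time, h
    "tau_sd": (0.0, 100.0),         # sd intermitotic time, h
    "v_mean": (0.0, 100.0),         # mean migration speed, μm/h
    "v_sd": (0.0, 100.0),           # sd migration speed, μm/h
}

SEARCH_PARAM_NAMES = tuple(TABLE1_RANGES)


@dataclasses.dataclass
class ParameterSet:
    """The 16 searched parameters plus fixed model constants."""

    rho_r: float = 2.0
    sigma_theta: float = 20.0
    p_0: float = 300.0
    D_p: float = 1.0e-4
    r_d: float = 0.05
    r_s: float = 200.0
    r_c: float = 0.01
    p_a: float = 10.0
    K_p: float = 50.0
    K_m: float = 50.0
    beta_p: float = 0.5
    beta_m: float = 0.5
    tau_mean: float = 40.0
    tau_sd: float = 20.0
    v_mean: float = 25.0
    v_sd: float = 25.0
    # fixed constants
    kappa: float = 100.0            # carrying capacity per 100 μm gray node
    dt: float = 0.25                # h
    n_initial_cells: int = 100      # per lineage (infected and recruited)
    injection_radius: float = 300.0  # μm
    injection_site: tuple[float, float] | None = None  # μm; None = domain center
    bolus_radius: float = 300.0     # μm
    move_prob: float = 0.5
    move_time_mean_h: float = _migration.MOVE_TIME_MEAN_MIN / 60.0
    stop_time_mean_h: float = _migration.STOP_TIME_MEAN_MIN / 60.0
    quiescent_cells_migrate: bool = True
    ap_threshold: float = 60.0      # h
    am_factor: float = 0.1

    def validate(self, strict: bool = False) -> list[str]:
        """Check the searched parameters against their admissible ranges."""
        problems = []
        for name, (lo, hi) in TABLE1_RANGES.items():
            val = getattr(self, name)
            if not (lo <= val <= hi):
                problems.append(f"{name}={val} outside [{lo}, {hi}]")
        if problems and strict:
            raise ValueError("; ".join(problems))
        for p in problems:
            warnings.warn(p)
        return problems

    def injection_site_xy(self, domain: TissueDomain) -> tuple[float, float]:
        if self.injection_site is not None:
            return tuple(self.injection_site)
        return (domain.width_um / 2.0, domain.height_um / 2.0)

    def response_params(self) -> ResponseParams:
        return ResponseParams(K_p=self.K_p, K_m=self.K_m, p_a=self.p_a,
                              beta_p=self.beta_p, beta_m=self.beta_m)

    def replace(self, **kwargs) -> "ParameterSet":
        return dataclasses.replace(self, **kwargs)

    def homogeneous_counterpart(self) -> "ParameterSet":
        """Same means, no cell-intrinsic heterogeneity (σ_τ = σ_v = 0)."""
        return self.replace(tau_sd=0.0, v_sd=0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        d = dict(d)
        if d.get("injection_site") is not None:
            d["injection_site"] = tuple(d["injection_site"])
        return cls(**d)


@dataclasses.dataclass
class TreatmentSchedule:
    """Which drugs are on and when (days)."""

    kind: str = "none"  # none | AP | AM | AP+AM
    start_day: float = 14.0
    end_day: float = 42.0

    def __post_init__(self):
        if self.kind not in ("none", "AP", "AM", "AP+AM"):
            raise ValueError(f"unknown treatment kind {self.kind!r}")
        if self.kind != "none" and not self.start_day < self.end_day:
            raise ValueError("treatment start must precede end")

    def active(self, time_h: float) -> bool:
        return (self.kind != "none"
                and self.start_day * 24.0 <= time_h < self.end_day * 24.0)

    def ap_active(self, time_h: float) -> bool:
        return self.active(time_h) and "AP" in self.kind

    def am_active(self, time_h: float) -> bool:
        return self.active(time_h) and "AM" in self.kind


@dataclasses.dataclass
class Snapshot:
    """Frozen view of one timepoint, consumed by the metrics module."""

    day: float
    x: np.ndarray
    y: np.ndarray
    tau: np.ndarray
    v: np.ndarray
    lineage: np.ndarray
    cycle: np.ndarray
    quiescent: np.ndarray
    c_pp: np.ndarray          # local paracrine PDGF per cell
    counts: np.ndarray        # per-density-node cell counts (flat)
    capacity: np.ndarray      # per-density-node carrying capacity (flat)
    dens_idx: np.ndarray      # per-cell flat density-node id
    dens_shape: tuple[int, int]
    spacing_mm: float
    n_inactive_recruitable: int


class Simulation:
    """One running instance of the model on a tissue domain."""

    def __init__(self, domain: TissueDomain, params: ParameterSet,
                 schedule: TreatmentSchedule | None = None, seed: int = 0,
                 check_invariants: bool = False):
        params.validate(strict=False)
        self.domain = domain
        self.params = params
        self.schedule = schedule or TreatmentSchedule()
        self.seed = seed
        self.check_invariants = check_invariants
        ss = np.random.SeedSequence(seed)
        init_ss, div_ss, mig_ss = ss.spawn(3)
        self.rng_init = np.random.default_rng(init_ss)
        self.rng_division = np.random.default_rng(div_ss)
        self.rng_migration = np.random.default_rng(mig_ss)

        self.time_h = 0.0
        self.capacity = domain.capacity_map(params.kappa)
        self.counts = np.zeros(domain.n_density, dtype=np.int64)
        self.persistence = PersistenceModel(
            move_time_mean=params.move_time_mean_h,
            stop_time_mean=params.stop_time_mean_h,
            move_prob=params.move_prob)
        self.turning = TurningModel(sigma_theta_deg=params.sigma_theta)
        self.resp = params.response_params()

        self.pop, self.recruitables = init_population(domain, params, self.rng_init)
        idx = self.pop.alive_index()
        self.pop.hex_idx[idx] = domain._nearest_hex_unchecked(
            self.pop.x[idx], self.pop.y[idx])
        self.pop.dens_idx[idx] = domain._nearest_density_unchecked(
            self.pop.x[idx], self.pop.y[idx])

        self.field = PDGFField(domain, D_p=params.D_p, r_d=params.r_d,
                               r_s=params.r_s, r_c=params.r_c)
        self.field.deposit_initial_bolus(
            params.p_0, params.injection_site_xy(domain), params.bolus_radius)

        # event log: per-event integer records + running totals
        self.events: dict[str, list] = {"division": [], "activation": [], "kill": []}
        self.totals = {"divisions": 0, "activations": 0, "kills": 0}
        self.division_hooks: list = []  # callables(parent_ids, child_ids)

    # ------------------------------------------------------------------ step
    def step(self, dt: float | None = None) -> None:
        dt = self.params.dt if dt is None else dt
        dom = self.domain
        pop = self.pop
        idx = pop.alive_index()

        # 1. density counts
        pop.dens_idx[idx] = dom._nearest_density_unchecked(pop.x[idx], pop.y[idx])
        self.counts = np.bincount(pop.dens_idx[idx], minlength=dom.n_density)
        if self.check_invariants:
            assert self.counts.sum() == idx.size, "density partition broken"

        # 2. activation sweep of the recruitable field
        ax, ay = self.recruitables.pop_activated(self.field.conc,
                                                 self.resp.activation_threshold)
        if ax.size:
            tau, v = draw_phenotypes(ax.size, self.params.tau_mean,
                                     self.params.tau_sd, self.params.v_mean,
                                     self.params.v_sd, self.rng_init)
            new = pop.add(ax, ay, tau, v, RECRUITED)
            pop.hex_idx[new] = dom._nearest_hex_unchecked(ax, ay)
            pop.dens_idx[new] = dom._nearest_density_unchecked(ax, ay)
            np.add.at(self.counts, pop.dens_idx[new], 1)
            self.events["activation"].append(
                np.column_stack([np.full(new.size, round(self.time_h * 100)),
                                 pop.cell_id[new]]))
            self.totals["activations"] += int(new.size)
            idx = pop.alive_index()

        # 3. cell loop — observed phenotype at local PDGF
        am = self.schedule.am_active(self.time_h)
        c_pp = self.field.conc[pop.hex_idx[idx]]
        p, m = observed_phenotype(pop.tau[idx], pop.v[idx], pop.lineage[idx],
                                  c_pp, self.resp,
                                  am_factor=self.params.am_factor if am else 1.0)

        # 3a. quiescence + cycle + division
        new_cycle, quiescent, divides = advance_cycle(
            pop.cycle[idx], p, dt, self.counts[pop.dens_idx[idx]],
            self.capacity[pop.dens_idx[idx]])
        pop.cycle[idx] = new_cycle
        pop.quiescent[idx] = quiescent
        if divides.any():
            parents = idx[divides]
            cx, cy = place_daughters(pop.x[parents], pop.y[parents], dom,
                                     self.rng_division)
            children = pop.add(cx, cy, pop.tau[parents], pop.v[parents],
                               pop.lineage[parents],
                               parent_id=pop.cell_id[parents])
            pop.hex_idx[children] = dom._nearest_hex_unchecked(cx, cy)
            pop.dens_idx[children] = dom._nearest_density_unchecked(cx, cy)
            np.add.at(self.counts, pop.dens_idx[children], 1)
            rec = np.column_stack([
                np.full(children.size, round(self.time_h * 100)),
                pop.cell_id[parents], pop.cell_id[children]])
            self.events["division"].append(rec)
            self.totals["divisions"] += int(children.size)
            for hook in self.division_hooks:
                hook(pop.cell_id[parents], pop.cell_id[children])
            idx = pop.alive_index()
            # recompute phenotype arrays including the newborns
            c_pp = self.field.conc[pop.hex_idx[idx]]
            p, m = observed_phenotype(pop.tau[idx], pop.v[idx],
                                      pop.lineage[idx], c_pp, self.resp,
                                      am_factor=self.params.am_factor if am else 1.0)

        # 3b. migration
        cls = dom.tissue_class_at(pop.x[idx], pop.y[idx])
        pop.moving[idx], pop.heading[idx], pop.persist[idx] = \
            _migration.update_persistence(
                pop.moving[idx], pop.heading[idx], pop.persist[idx], cls, dt,
                self.persistence, self.turning, self.rng_migration)
        may_move = pop.moving[idx] & (m > 0)
        if not self.params.quiescent_cells_migrate:
            may_move &= ~pop.quiescent[idx]
        movers = idx[may_move]
        if movers.size:
            nx, ny, nh = _migration.attempt_moves(
                pop.x[movers], pop.y[movers], pop.heading[movers],
                m[may_move], dt, dom, self.counts, self.capacity,
                self.rng_migration)
            pop.x[movers] = nx
            pop.y[movers] = ny
            pop.heading[movers] = nh
            pop.hex_idx[movers] = dom._nearest_hex_unchecked(nx, ny)
            pop.dens_idx[movers] = dom._nearest_density_unchecked(nx, ny)

        # 3c. PDGF secretion (infected only) and consumption (all active)
        infected = idx[pop.lineage[idx] == INFECTED]
        self.field.secrete(pop.hex_idx[infected], dt)
        self.field.consume(pop.hex_idx[idx], dt)

        # 4-5. field decay then diffusion
        self.field.decay(dt)
        self.field.diffuse(dt)

        # 6. anti-proliferative kill
        if self.schedule.ap_active(self.time_h):
            self.apply_anti_proliferative()

        self.time_h += dt

    def apply_anti_proliferative(self, threshold: float | None = None) -> None:
        """Kill every active non-quiescent cell with τ below the threshold."""
        threshold = self.params.ap_threshold if threshold is None else threshold
        pop = self.pop
        idx = pop.alive_index()
        doomed = idx[(~pop.quiescent[idx]) & (pop.tau[idx] < threshold)]
        if doomed.size:
            pop.alive[doomed] = False
            np.add.at(self.counts, pop.dens_idx[doomed], -1)
            self.events["kill"].append(np.column_stack([
                np.full(doomed.size, round(self.time_h * 100)),
                pop.cell_id[doomed]]))
            self.totals["kills"] += int(doomed.size)
            if pop.n and pop.n_alive < 0.75 * pop.n:
                pop.compact()

    # ------------------------------------------------------------------ runs
    @property
    def day(self) -> float:
        return self.time_h / 24.0

    def run_until(self, day: float, dt: float | None = None) -> None:
        dt_h = self.params.dt if dt is None else dt
        n = int(round((day * 24.0 - self.time_h) / dt_h))
        for _ in range(max(n, 0)):
            self.step(dt_h)

    def snapshot(self) -> Snapshot:
        pop = self.pop
        idx = pop.alive_index()
        return Snapshot(
            day=self.day,
            x=pop.x[idx].copy(), y=pop.y[idx].copy(),
            tau=pop.tau[idx].copy(), v=pop.v[idx].copy(),
            lineage=pop.lineage[idx].copy(), cycle=pop.cycle[idx].copy(),
            quiescent=pop.quiescent[idx].copy(),
            c_pp=self.field.conc[pop.hex_idx[idx]].copy(),
            counts=self.counts.copy(), capacity=self.capacity.copy(),
            dens_idx=pop.dens_idx[idx].copy(),
            dens_shape=(self.domain.dens_nrows, self.domain.dens_ncols),
            spacing_mm=self.domain.density_spacing / 1000.0,
            n_inactive_recruitable=self.recruitables.n_inactive,
        )

    def event_log_arrays(self) -> dict[str, np.ndarray]:
        return {k: (np.concatenate(v) if v else np.zeros((0, 2), dtype=np.int64))
                for k, v in self.events.items()}


@dataclasses.dataclass
class SimulationResult:
    params: ParameterSet
    schedule: TreatmentSchedule
    seed: int
    snapshots: dict[float, Snapshot]
    totals: dict[str, int]

    def metric_report(self, day: float):
        from .metrics import compute_report

        am = self.schedule.am_active(day * 24.0)
        return compute_report(self.snapshots[day],
                              self.params.response_params(),
                              am_factor=self.params.am_factor if am else 1.0)

    def diameter(self, day: float, threshold: float = 0.10) -> float:
        from .metrics import snapshot_diameter

        return snapshot_diameter(self.snapshots[day], threshold=threshold)


def run(domain: TissueDomain, params: ParameterSet,
        schedule: TreatmentSchedule | None = None,
        record_days: tuple[float, ...] = (5.0, 10.0, 17.0),
        seed: int = 0) -> SimulationResult:
    """Simulate to the last recorded day, capturing snapshots along the way."""
    sim = Simulation(domain, params, schedule, seed=seed)
    snaps: dict[float, Snapshot] = {}
    days = sorted(set(float(d) for d in record_days))
    if not days or days[0] > 0.0:
        snaps[0.0] = sim.snapshot()
    for d in days:
        if d > 0.0:
            sim.run_until(d)
        snaps[d] = sim.snapshot()
    return SimulationResult(params=params, schedule=sim.schedule, seed=seed,
                            snapshots=snaps, totals=dict(sim.totals))
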