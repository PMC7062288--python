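"""Virtual cell tracking and single-cell track statistics.

Tracks mirror the ex-vivo experiment: positions of selected cells (and
their progeny) recorded every 3 minutes over a ~25 h window, taken from the
tumor rim where cells are sparse enough to follow.  The same statistics
apply to simulated tracks and to experimental track tables in the same
long CSV format (cell_id, lineage, t_h, x_um, y_um, divided).

Definitions follow the experimental analysis:

* per-cell speed = total distance traveled / total time spent moving
  (frames whose displacement falls below the stop resolution are stops and
  are excluded from the denominator);
* proliferation rate = divisions / (cells at start × observation hours),
  reported in %/h;
* run/stop segmentation groups consecutive like frames; turning angles are
  between successive run headings.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cells import LINEAGE_NAMES

FRAME_H = 0.05  # 3-minute tracking cadence
STOP_RESOLUTION_UM = 1.0  # per frame: 1 μm / 3 min = 20 μm/h floor

TRACK_COLUMNS = ("cell_id", "lineage", "t_h", "x_um", "y_um", "divided")


def load_track_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns {sorted(missing)}")
    return df


def record_tracks(sim, n_cells: int, duration_h: float = 25.0,
                  cadence_h: float = FRAME_H, region=(0.01, 0.50),
                  rng=None) -> pd.DataFrame:
    """Track ``n_cells`` rim cells through ``duration_h`` of simulation.

    The rim is the set of density nodes between ``region[0]`` and
    ``region[1]`` of carrying capacity.  The simulation is advanced with
    ``cadence_h`` steps; daughters of tracked cells are tracked from their
    birth and flagged ``divided`` (as is the mother's track).  If fewer
    than ``n_cells`` are available in the region all of them are tracked
    (with a warning).
    """
    import warnings

    rng = np.random.default_rng(0) if rng is None else rng
    pop = sim.pop
    idx = pop.alive_index()
    counts = np.bincount(pop.dens_idx[idx], minlength=sim.capacity.size)
    frac = np.zeros(counts.size)
    ok = sim.capacity > 0
    frac[ok] = counts[ok] / sim.capacity[ok]
    node_in_rim = (frac >= region[0]) & (frac <= region[1])
    candidates = idx[node_in_rim[pop.dens_idx[idx]]]
    if candidates.size < n_cells:
        warnings.warn(f"only {candidates.size} cells in the rim; tracking all")
        chosen = candidates
    else:
        chosen = rng.choice(candidates, size=n_cells, replace=False)
    tracked = set(int(i) for i in pop.cell_id[chosen])
    divided: set[int] = set()

    def on_division(parent_ids, child_ids):
        for pid, cid in zip(parent_ids, child_ids):
            if int(pid) in tracked:
                tracked.add(int(cid))
                divided.add(int(pid))
                divided.add(int(cid))

    sim.division_hooks.append(on_division)
    rows = []
    n_frames = int(round(duration_h / cadence_h))
    t0 = sim.time_h

    def capture():
        live = pop.alive_index()
        sel = live[np.isin(pop.cell_id[live], list(tracked))]
        for i in sel:
            rows.append((int(pop.cell_id[i]), LINEAGE_NAMES[int(pop.lineage[i])],
                         sim.time_h - t0, pop.x[i], pop.y[i]))

    capture()
    for _ in range(n_frames):
        sim.step(cadence_h)
        capture()
    sim.division_hooks.remove(on_division)
    df = pd.DataFrame(rows, columns=["cell_id", "lineage", "t_h", "x_um", "y_um"])
    df["divided"] = df["cell_id"].isin(divided)
    return df


def _per_cell_frames(track: pd.DataFrame):
    t = track["t_h"].to_numpy()
    if t.size >= 2 and not np.all(np.diff(t) > 0):
        raise ValueError("track times must be strictly increasing per cell")
    dx = np.diff(track["x_um"].to_numpy())
    dy = np.diff(track["y_um"].to_numpy())
    return np.diff(t), np.hypot(dx, dy), np.arctan2(dy, dx)


def per_cell_speed(track: pd.DataFrame,
                   resolution_um: float = STOP_RESOLUTION_UM) -> float:
    """Distance traveled over time spent moving (μm/h); NaN if never moving."""
    dt, disp, _ = _per_cell_frames(track)
    moving = disp >= resolution_um
    if not moving.any():
        return float("nan")
    return float(disp[moving].sum() / dt[moving].sum())


def run_stop_segmentation(track: pd.DataFrame,
                          resolution_um: float = STOP_RESOLUTION_UM) -> pd.DataFrame:
    """Segment one track into runs and stops.

    Frames with displacement below ``resolution_um`` are STOP frames;
    maximal blocks of consecutive like frames become segments.  Returns one
    row per segment: kind, n_frames, duration_h, mean_speed_um_h (runs),
    net_heading_rad (runs).
    """
    dt, disp, _ = _per_cell_frames(track)
    if disp.size == 0:
        return pd.DataFrame(columns=["kind", "n_frames", "duration_h",
                                     "mean_speed_um_h", "net_heading_rad"])
    moving = disp >= resolution_um
    x = track["x_um"].to_numpy()
    y = track["y_um"].to_numpy()
    boundaries = np.nonzero(np.diff(moving))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [moving.size]])
    rows = []
    for s, e in zip(starts, ends):
        dur = float(dt[s:e].sum())
        if moving[s]:
            rows.append(("run", e - s, dur, float(disp[s:e].sum() / dur),
                         float(np.arctan2(y[e] - y[s], x[e] - x[s]))))
        else:
            rows.append(("stop", e - s, dur, float("nan"), float("nan")))
    return pd.DataFrame(rows, columns=["kind", "n_frames", "duration_h",
                                       "mean_speed_um_h", "net_heading_rad"])


def msd(tracks: pd.DataFrame, max_lag_frames: int | None = None,
        cadence_h: float = FRAME_H) -> pd.DataFrame:
    """Mean squared displacement averaged over cells and time origins."""
    lags: dict[int, list] = {}
    for _, tr in tracks.groupby("cell_id"):
        x = tr["x_um"].to_numpy()
        y = tr["y_um"].to_numpy()
        n = x.size
        top = n - 1 if max_lag_frames is None else min(max_lag_frames, n - 1)
        for lag in range(1, top + 1):
            d2 = (x[lag:] - x[:-lag]) ** 2 + (y[lag:] - y[:-lag]) ** 2
            lags.setdefault(lag, []).append(d2.mean())
    rows = [(lag * cadence_h, float(np.mean(v))) for lag, v in sorted(lags.items())]
    return pd.DataFrame(rows, columns=["lag_h", "msd_um2"])


@dataclasses.dataclass
class PopulationStats:
    n_cells: int
    mean_speed_um_h: float
    sd_speed_um_h: float
    mean_run_h: float
    mean_stop_h: float
    proliferation_rate_pct_h: float
    turning_angles_rad: np.ndarray
    msd: pd.DataFrame


def population_stats(tracks: pd.DataFrame, n_divisions: int | None = None,
                     observation_h: float | None = None,
                     resolution_um: float = STOP_RESOLUTION_UM,
                     cadence_h: float = FRAME_H) -> PopulationStats:
    """Population-level track statistics.

    ``n_divisions`` defaults to the number of distinct divided mother cells
    inferred from the ``divided`` flag (daughter tracks start after t=0);
    the proliferation rate uses the number of cells present at the start of
    the window.
    """
    if tracks.empty:
        raise ValueError("no tracks")
    speeds = []
    run_durs, stop_durs, angles = [], [], []
    first_times = tracks.groupby("cell_id")["t_h"].min()
    n0 = int((first_times == first_times.min()).sum())
    for _, tr in tracks.groupby("cell_id"):
        s = per_cell_speed(tr, resolution_um)
        if np.isfinite(s):
            speeds.append(s)
        seg = run_stop_segmentation(tr, resolution_um)
        run_durs.extend(seg.loc[seg["kind"] == "run", "duration_h"])
        stop_durs.extend(seg.loc[seg["kind"] == "stop", "duration_h"])
        h = seg.loc[seg["kind"] == "run", "net_heading_rad"].to_numpy()
        if h.size >= 2:
            turn = np.diff(h)
            angles.append((turn + np.pi) % (2 * np.pi) - np.pi)
    if observation_h is None:
        observation_h = float(tracks["t_h"].max() - tracks["t_h"].min())
    if n_divisions is None:
        started_late = first_times > first_times.min()
        n_divisions = int(started_late.sum()) // 2
    rate = 100.0 * n_divisions / (n0 * observation_h) if n0 and observation_h else 0.0
    return PopulationStats(
        n_cells=int(tracks["cell_id"].nunique()),
        mean_speed_um_h=float(np.mean(speeds)) if speeds else float("nan"),
        sd_speed_um_h=float(np.std(speeds)) if speeds else float("nan"),
        mean_run_h=float(np.mean(run_durs)) if run_durs else float("nan"),
        mean_stop_h=float(np.mean(stop_durs)) if stop_durs else float("nan"),
        proliferation_rate_pct_h=rate,
        turning_angles_rad=(np.concatenate(angles) if angles else np.zeros(0)),
        msd=msd(tracks, cadence_h=cadence_h),
    )
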