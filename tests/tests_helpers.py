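"""Shared synthetic-track builders for the test suite."""

import numpy as np
import pandas as pd

from gliomabm.tracks import FRAME_H


def track_from_positions(x, y, cell_id=1, cadence=FRAME_H):
    t = np.arange(len(x)) * cadence
    return pd.DataFrame({"cell_id": cell_id, "lineage": "infected",
                         "t_h": t, "x_um": x, "y_um": y, "divided": False})


def alternating_walker_track(rng, cell_id=0, duration_h=25.0, v=40.0,
                             run_mean_h=42.6 / 60.0, stop_mean_h=70.1 / 60.0):
    """One walker with alternating exponential runs and stops, quantized to
    the 3-min frame cadence (a run always lasts at least one frame)."""
    x = [0.0]
    y = [0.0]
    moving = rng.uniform() < 0.5
    n_frames = int(round(duration_h / FRAME_H))
    while len(x) <= n_frames:
        dur = rng.exponential(run_mean_h if moving else stop_mean_h)
        frames = max(int(np.ceil(dur / FRAME_H)), 1)
        heading = rng.uniform(0, 2 * np.pi)
        for _ in range(frames):
            step = v * FRAME_H if moving else 0.0
            x.append(x[-1] + step * np.cos(heading))
            y.append(y[-1] + step * np.sin(heading))
        moving = not moving
    return track_from_positions(np.array(x[: n_frames + 1]),
                                np.array(y[: n_frames + 1]), cell_id=cell_id)


def alternating_tracks(rng, n_cells=500, **kw):
    return pd.concat(
        [alternating_walker_track(rng, cell_id=i, **kw) for i in range(n_cells)],
        ignore_index=True)
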