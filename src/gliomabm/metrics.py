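"""Imaging-, population-, and cell-scale summaries of a simulation snapshot.

The imaging-scale size of a tumor is its *average maximum diameter*: around
the centroid of the suprathreshold density nodes, 360 angular bins each take
the maximum radius at which the cell density still exceeds a threshold
fraction of the local carrying capacity (10% for the MRI-matched diameter),
and the diameter is twice the mean of those per-bin radii.  Each density
node contributes over the angular extent of its 100-μm square so the
discrete grid leaves no angular gaps; an equivalent-area-circle alternative
is available behind a flag.

The tumor *core* is the region at ≥50% of capacity and the *rim* extends
out to 1% of capacity; the rim size d_r is reported as the difference
between the average rim diameter and the average core diameter.

All metrics are pure functions of a snapshot.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cells import INFECTED, RECRUITED, gamma_response, observed_phenotype
from .engine import Snapshot

KI67_WINDOW_H = 20.0

OUTCOME_CLASSES = ("complete_response", "small", "medium", "large")


def _suprathreshold(counts, capacity, threshold):
    counts = np.asarray(counts, dtype=np.float64)
    capacity = np.asarray(capacity, dtype=np.float64)
    return (capacity > 0) & (counts >= threshold * capacity)


def tumor_diameter(counts, capacity, spacing_mm: float, nrows: int, ncols: int,
                   threshold: float = 0.10, n_bins: int = 360,
                   method: str = "angular") -> float:
    """Average maximum diameter (mm) of the suprathreshold region.

    ``counts``/``capacity`` are flat per-density-node arrays on an
    ``nrows x ncols`` grid with ``spacing_mm`` node spacing.  Returns 0.0
    when no node is suprathreshold.
    """
    hot = _suprathreshold(counts, capacity, threshold)
    if not hot.any():
        return 0.0
    r, c = np.divmod(np.nonzero(hot)[0], ncols)
    x = (c + 0.5) * spacing_mm
    y = (r + 0.5) * spacing_mm
    w = np.asarray(counts, dtype=np.float64)[hot]
    w = np.maximum(w, 1e-12)
    cx = float(np.average(x, weights=w))
    cy = float(np.average(y, weights=w))
    if method == "equivalent_area":
        area = int(hot.sum()) * spacing_mm**2
        return 2.0 * float(np.sqrt(area / np.pi))
    if method != "angular":
        raise ValueError("method must be 'angular' or 'equivalent_area'")
    dx = x - cx
    dy = y - cy
    rad = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    half = spacing_mm / 2.0
    r_eff = rad + half
    # angular half-extent of the node square as seen from the centroid
    halfwidth = np.where(rad <= half, np.pi, np.arctan(half / np.maximum(rad, half)))
    bin_width = 2.0 * np.pi / n_bins
    center_bin = np.floor((theta + np.pi) / bin_width).astype(np.int64) % n_bins
    span = np.ceil(halfwidth / bin_width).astype(np.int64)
    max_r = np.zeros(n_bins)
    for i in np.argsort(r_eff):
        bins = np.arange(center_bin[i] - span[i], center_bin[i] + span[i] + 1) % n_bins
        max_r[bins] = r_eff[i]
    return 2.0 * float(max_r.mean())


def core_and_rim(counts, capacity, spacing_mm, nrows, ncols,
                 core_threshold: float = 0.50, rim_threshold: float = 0.01):
    """(d_c, d_r): core diameter at ≥50% capacity and rim size beyond it."""
    d_core = tumor_diameter(counts, capacity, spacing_mm, nrows, ncols,
                            threshold=core_threshold)
    d_rim = tumor_diameter(counts, capacity, spacing_mm, nrows, ncols,
                           threshold=rim_threshold)
    return d_core, max(d_rim - d_core, 0.0)


def snapshot_diameter(snap: Snapshot, threshold: float = 0.10) -> float:
    nrows, ncols = snap.dens_shape
    return tumor_diameter(snap.counts, snap.capacity, snap.spacing_mm,
                          nrows, ncols, threshold=threshold)


def lineage_ratio(lineage) -> float:
    """Infected / recruited cell-count ratio over active cells."""
    lineage = np.asarray(lineage)
    n_r = int(np.count_nonzero(lineage == RECRUITED))
    if n_r == 0:
        raise ZeroDivisionError("no recruited cells: I/R undefined")
    return int(np.count_nonzero(lineage == INFECTED)) / n_r


def phenotype_stats(snap: Snapshot, resp, radial_bin_um: float = 100.0,
                    am_factor: float = 1.0):
    """Mean/sd of measured (p, m) and potential (1/τ, v) phenotypes.

    Measured statistics cover non-quiescent active cells only, evaluated at
    each cell's local paracrine PDGF.  Also returns radial profiles binned
    at ``radial_bin_um`` around the cell centroid (None when no cells).
    """
    sel = ~snap.quiescent
    out: dict[str, float] = {
        "n_cells": int(snap.x.size),
        "n_quiescent": int(np.count_nonzero(snap.quiescent)),
    }
    pot_p = 1.0 / snap.tau if snap.tau.size else np.zeros(0)
    pot_m = snap.v
    for key, arr in (("potential_p", pot_p), ("potential_m", pot_m)):
        out[f"{key}_mean"] = float(arr.mean()) if arr.size else float("nan")
        out[f"{key}_sd"] = float(arr.std()) if arr.size else float("nan")
    profiles = None
    if sel.any():
        p, m = observed_phenotype(snap.tau[sel], snap.v[sel], snap.lineage[sel],
                                  snap.c_pp[sel], resp, am_factor=am_factor)
        out["measured_p_mean"] = float(p.mean())
        out["measured_p_sd"] = float(p.std())
        out["measured_m_mean"] = float(m.mean())
        out["measured_m_sd"] = float(m.std())
        cx, cy = snap.x[sel].mean(), snap.y[sel].mean()
        radius = np.hypot(snap.x[sel] - cx, snap.y[sel] - cy)
        nb = max(int(np.ceil((radius.max() + 1e-9) / radial_bin_um)), 1)
        which = np.minimum((radius / radial_bin_um).astype(np.int64), nb - 1)
        denom = np.bincount(which, minlength=nb)
        safe = np.maximum(denom, 1)
        profiles = {
            "radius_mm": (np.arange(nb) + 0.5) * radial_bin_um / 1000.0,
            "measured_p": np.bincount(which, weights=p, minlength=nb) / safe,
            "measured_m": np.bincount(which, weights=m, minlength=nb) / safe,
            "potential_p": np.bincount(which, weights=pot_p[sel], minlength=nb) / safe,
            "potential_m": np.bincount(which, weights=pot_m[sel], minlength=nb) / safe,
            "n": denom,
        }
    else:
        for k in ("measured_p_mean", "measured_p_sd",
                  "measured_m_mean", "measured_m_sd"):
            out[k] = float("nan")
    return out, profiles


def ki67_index(snap: Snapshot, resp, window_h: float = KI67_WINDOW_H) -> float:
    """Percent Ki-67+ cells in the density node with the most positive cells.

    A non-quiescent cell is positive when its remaining cycle time
    ``(1 - progress) * τ / γ_p`` is at most ``window_h`` — the marker is
    expressed only over the final stretch of the cycle.  The index is the
    positive fraction within the 100-μm node holding the most positive
    cells (the "area of highest activity").
    """
    if snap.x.size == 0:
        raise ValueError("ki67_index needs at least one cell")
    g_p = gamma_response(snap.c_pp, snap.lineage, resp.K_p, resp.beta_p, resp.p_a)
    with np.errstate(divide="ignore"):
        remaining = np.where(g_p > 0, (1.0 - snap.cycle) * snap.tau / g_p, np.inf)
    positive = (~snap.quiescent) & (remaining <= window_h)
    if not positive.any():
        return 0.0
    n_nodes = snap.counts.size
    pos_per_node = np.bincount(snap.dens_idx[positive], minlength=n_nodes)
    node = int(pos_per_node.argmax())
    total = int(np.count_nonzero(snap.dens_idx == node))
    return 100.0 * pos_per_node[node] / total


def classify_outcome(diameter_mm: float) -> str:
    """Outcome class from the end-of-treatment diameter.

    Bins: <0.5 mm complete response; 0.5–2 small; 2–3 medium; >3 large.
    """
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    if diameter_mm < 0.5:
        return "complete_response"
    if diameter_mm < 2.0:
        return "small"
    if diameter_mm <= 3.0:
        return "medium"
    return "large"


@dataclasses.dataclass
class MetricReport:
    """All summaries for one snapshot."""

    day: float
    diameter_mm: float
    d_c_mm: float
    d_r_mm: float
    i_r_ratio: float | None
    ki67_percent: float
    outcome: str
    stats: dict
    counts_by_lineage: dict

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.update(d.pop("stats"))
        return d


def compute_report(snap: Snapshot, resp, am_factor: float = 1.0) -> MetricReport:
    nrows, ncols = snap.dens_shape
    diameter = tumor_diameter(snap.counts, snap.capacity, snap.spacing_mm,
                              nrows, ncols, threshold=0.10)
    d_c, d_r = core_and_rim(snap.counts, snap.capacity, snap.spacing_mm,
                            nrows, ncols)
    try:
        i_r = lineage_ratio(snap.lineage)
    except ZeroDivisionError:
        i_r = None
    stats, _ = phenotype_stats(snap, resp, am_factor=am_factor)
    ki67 = ki67_index(snap, resp) if snap.x.size else 0.0
    by_lineage = {
        "infected": int(np.count_nonzero(snap.lineage == INFECTED)),
        "recruited": int(np.count_nonzero(snap.lineage == RECRUITED)),
        "recruitable_inactive": snap.n_inactive_recruitable,
        "quiescent": int(np.count_nonzero(snap.quiescent)),
    }
    return MetricReport(day=snap.day, diameter_mm=diameter, d_c_mm=d_c,
                        d_r_mm=d_r, i_r_ratio=i_r, ki67_percent=ki67,
                        outcome=classify_outcome(diameter), stats=stats,
                        counts_by_lineage=by_lineage)
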