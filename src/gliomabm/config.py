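"""Experiment configuration, reproducible run directories, and fixtures.

An :class:`ExperimentConfig` round-trips losslessly through YAML and fully
determines a run: tissue source (raster file or synthetic spec), parameter
set, treatment schedule, snapshot days, and seed.  ``run_experiment``
executes it into an artifact directory (config copy, metrics JSON, cell /
density / field CSV snapshots, line-oriented log); re-running reproduces
identical outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from .engine import ParameterSet, TreatmentSchedule, Simulation
from .metrics import compute_report
from .tissue import TissueDomain, load_tissue_raster, make_synthetic_brain


@dataclasses.dataclass
class ExperimentConfig:
    tissue: dict  # {"file": path, "px_size": μm} or {"synthetic": {...}}
    params: ParameterSet = dataclasses.field(default_factory=ParameterSet)
    schedule: TreatmentSchedule = dataclasses.field(default_factory=TreatmentSchedule)
    record_days: tuple = (5.0, 10.0, 17.0)
    seed: int = 0
    outdir: str = "out"

    REQUIRED = ("tissue", "params", "schedule", "record_days", "seed", "outdir")

    def to_yaml(self, path) -> None:
        doc = {
            "tissue": self.tissue,
            "params": self.params.to_dict(),
            "schedule": dataclasses.asdict(self.schedule),
            "record_days": list(self.record_days),
            "seed": self.seed,
            "outdir": str(self.outdir),
        }
        if doc["params"].get("injection_site") is not None:
            doc["params"]["injection_site"] = list(doc["params"]["injection_site"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        missing = [k for k in cls.REQUIRED if k not in doc]
        if missing:
            raise ValueError(f"config missing required fields: {missing}")
        return cls(
            tissue=doc["tissue"],
            params=ParameterSet.from_dict(doc["params"]),
            schedule=TreatmentSchedule(**doc["schedule"]),
            record_days=tuple(float(d) for d in doc["record_days"]),
            seed=int(doc["seed"]),
            outdir=doc["outdir"],
        )

    def build_domain(self) -> TissueDomain:
        if "file" in self.tissue:
            return load_tissue_raster(self.tissue["file"],
                                      px_size=float(self.tissue.get("px_size", 17.4)))
        if "synthetic" in self.tissue:
            return make_synthetic_brain(**self.tissue["synthetic"])
        raise ValueError("tissue spec needs a 'file' or 'synthetic' entry")


def run_experiment(config: ExperimentConfig, outdir=None) -> pathlib.Path:
    """Execute a config into an artifact directory; returns its path."""
    out = pathlib.Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    domain = config.build_domain()
    sim = Simulation(domain, config.params, config.schedule, seed=config.seed)
    log_lines = []

    def log(msg):
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        log_lines.append(f"{stamp} {msg}")

    log(f"start seed={config.seed} cells={sim.pop.n_alive} "
        f"recruitable={sim.recruitables.n_inactive}")
    reports = {}
    days = sorted(set(float(d) for d in config.record_days) | {0.0})
    for day in days:
        if day > 0:
            sim.run_until(day)
        snap = sim.snapshot()
        am = sim.schedule.am_active(day * 24.0)
        rep = compute_report(snap, config.params.response_params(),
                             am_factor=config.params.am_factor if am else 1.0)
        reports[day] = rep
        tag = f"day{day:g}"
        sim.pop.as_dataframe().to_csv(out / f"cells_{tag}.csv", index=False)
        nrows, ncols = snap.dens_shape
        dens = pd.DataFrame({
            "node_id": np.arange(snap.counts.size),
            "row": np.arange(snap.counts.size) // ncols,
            "col": np.arange(snap.counts.size) % ncols,
            "count": snap.counts,
            "capacity": snap.capacity,
        })
        dens.to_csv(out / f"density_{tag}.csv", index=False)
        sim.field.to_dataframe().to_csv(out / f"pdgf_{tag}.csv", index=False)
        log(f"{tag} cells={sim.pop.n_alive} diam={rep.diameter_mm:.3f}mm "
            f"divisions={sim.totals['divisions']} kills={sim.totals['kills']}")
    metrics_doc = {f"day{d:g}": reports[d].to_dict() for d in days}
    metrics_doc["_meta"] = {"seed": config.seed, "package": "gliomabm"}
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics_doc, fh, indent=2, sort_keys=True, default=float)
    (out / "log.txt").write_text("\n".join(log_lines) + "\n")
    return out


def make_fixtures(outdir) -> dict[str, pathlib.Path]:
    """Write miniature fixtures: a tiny tissue map, the reference-metric CSV
    with the main-text values, and toy track tables with known statistics."""
    from .calibration import MAIN_TEXT_REFERENCE

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    dom = make_synthetic_brain(2.0, 2.0,
                               tract_spec={"center_frac": 0.5, "thickness_mm": 0.4},
                               seed=0)
    paths["tissue"] = out / "mini_brain.pgm"
    dom.write_raster(paths["tissue"])

    paths["reference"] = out / "reference_metrics.csv"
    MAIN_TEXT_REFERENCE.to_csv(paths["reference"], index=False)

    # toy track: straight line at 20 μm/h for 10 h at the 3-min cadence
    t = np.arange(0, 10.0 + 1e-9, 0.05)
    straight = pd.DataFrame({
        "cell_id": 1, "lineage": "infected", "t_h": t,
        "x_um": 20.0 * t, "y_um": 0.0, "divided": False,
    })
    # toy track: 5 h moving at 30 μm/h then 5 h stopped
    moving = t <= 5.0
    x = np.where(moving, 30.0 * t, 150.0)
    stopgo = pd.DataFrame({
        "cell_id": 2, "lineage": "recruited", "t_h": t,
        "x_um": x, "y_um": 0.0, "divided": False,
    })
    paths["tracks"] = out / "toy_tracks.csv"
    pd.concat([straight, stopgo]).to_csv(paths["tracks"], index=False)
    return paths
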