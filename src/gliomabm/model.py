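"""Model/Results front end for fitting the glioma model to reference data.

Follows the familiar two-object pattern: a :class:`PDGFGliomaModel` is
constructed from the data (a reference-metric table) and the tissue domain,
``fit()`` runs the hybrid GA / random-sampling search and returns a
:class:`PDGFGliomaResults` carrying the best-fit parameter set, its
per-metric errors, the archive of alternative fits (the virtual cohort),
and a ``summary()`` table.  Simulation and plotting hang off the results
object.

Example
-------
>>> from gliomabm import PDGFGliomaModel, make_synthetic_brain
>>> domain = make_synthetic_brain(8.0, 6.0, tract_spec={"thickness_mm": 1.0})
>>> model = PDGFGliomaModel.from_main_text(domain, mode="size")
>>> res = model.fit(budget=60, n_replicates=1, seed=0)   # doctest: +SKIP
>>> print(res.summary())                                 # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import calibration as _cal
from .calibration import (ReferenceMetrics, ga_random_search,
                          make_simulation_objective, objective)
from .engine import (ParameterSet, TreatmentSchedule, TABLE1_RANGES,
                     SEARCH_PARAM_NAMES, run)
from .tissue import TissueDomain


class PDGFGliomaModel:
    """Glioma growth model bound to reference metrics and a tissue domain.

    Parameters
    ----------
    reference : ReferenceMetrics or DataFrame with metric/value/weight columns
    domain : TissueDomain
    fixed : optional dict of parameters excluded from the search (held at
        the given values)
    base_params : defaults for the non-searched constants (κ, dt, ...)
    """

    def __init__(self, reference, domain: TissueDomain,
                 fixed: dict | None = None,
                 base_params: ParameterSet | None = None):
        if isinstance(reference, pd.DataFrame):
            reference = ReferenceMetrics(reference)
        self.reference = reference
        self.domain = domain
        self.fixed = dict(fixed or {})
        self.base_params = base_params or ParameterSet()
        self.search_names = tuple(n for n in SEARCH_PARAM_NAMES
                                  if n not in self.fixed)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, domain: TissueDomain,
                       **kwargs) -> "PDGFGliomaModel":
        return cls(ReferenceMetrics(table), domain, **kwargs)

    @classmethod
    def from_main_text(cls, domain: TissueDomain, mode: str = "size",
                       **kwargs) -> "PDGFGliomaModel":
        """Model targeting the published rat-model reference values."""
        return cls(ReferenceMetrics.main_text(mode), domain, **kwargs)

    def loglike_analogue(self, params: ParameterSet, seed: int = 0,
                         n_replicates: int = 1) -> float:
        """Negative total weighted error (%); higher is better."""
        return -objective(params, self.reference, self.domain,
                          n_replicates=n_replicates, seed=seed)

    def fit(self, budget: int = 500, n_replicates: int = 3, seed: int = 0,
            method: str = "ga", ga_fraction: float = 0.7,
            pop_size: int = 20, rescore_top: int = 0,
            rescore_replicates: int = 10) -> "PDGFGliomaResults":
        """Run the hybrid search; ``method='random'`` sets ga_fraction to 0.

        ``rescore_top`` re-evaluates that many archive leaders at
        ``rescore_replicates`` replicates before ranking (the search itself
        uses the cheaper ``n_replicates``).
        """
        if method not in ("ga", "random"):
            raise ValueError("method must be 'ga' or 'random'")
        base = self.base_params.replace(**self.fixed) if self.fixed \
            else self.base_params
        obj = make_simulation_objective(self.reference, self.domain,
                                        n_replicates=n_replicates)
        archive, trace = ga_random_search(
            obj, budget=budget, seed=seed,
            ga_fraction=0.0 if method == "random" else ga_fraction,
            pop_size=pop_size, base_params=base,
            search_names=self.search_names)
        if rescore_top and archive:
            rng = np.random.default_rng(seed + 1)
            for f in archive[:rescore_top]:
                f.total_error, details = obj(f.params, int(rng.integers(2**31)))
                f.per_metric_errors = details["errors"]
                f.simulated_values = details["values"]
            archive.sort(key=lambda f: f.total_error)
        return PDGFGliomaResults(self, archive, trace, seed=seed)

    def results_from_params(self, params: ParameterSet, seed: int = 0,
                            n_replicates: int = 3) -> "PDGFGliomaResults":
        """Results object for a known parameter set (no search)."""
        total, details = objective(params, self.reference, self.domain,
                                   n_replicates=n_replicates, seed=seed,
                                   return_details=True)
        fr = _cal.FitResult(params=params, total_error=total,
                            per_metric_errors=details["errors"],
                            simulated_values=details["values"],
                            replicate_seeds=(), rank=0)
        return PDGFGliomaResults(self, [fr], _cal.SearchTrace([], [], []),
                                 seed=seed)


class PDGFGliomaResults:
    """Fit results: best parameters, archive cohort, diagnostics, summary."""

    def __init__(self, model: PDGFGliomaModel, archive, trace, seed: int):
        if not archive:
            raise ValueError("search produced no finite-error candidates")
        self.model = model
        self.archive = archive
        self.trace = trace
        self.seed = seed

    @property
    def params(self) -> ParameterSet:
        return self.archive[0].params

    @property
    def total_error(self) -> float:
        return self.archive[0].total_error

    @property
    def per_metric_errors(self) -> dict:
        return self.archive[0].per_metric_errors

    def params_spread(self, top: int = 20) -> pd.DataFrame:
        """Mean/sd of each searched parameter over the top archive members.

        The spread is the fit's uncertainty statement: many distinct sets
        match the size dynamics equally well (practical non-identifiability
        is a property of the data, not a failure of the search).
        """
        rows = {}
        members = self.archive[:top]
        for n in self.model.search_names:
            vals = np.array([getattr(f.params, n) for f in members])
            rows[n] = (vals.mean(), vals.std())
        return pd.DataFrame(rows, index=["mean", "sd"]).T

    def cohort(self, top: int = 300):
        return [f.params for f in self.archive[:top]]

    def summary(self, top: int = 20) -> str:
        lines = ["PDGF-driven glioma model fit",
                 "=" * 58,
                 f"reference metrics : {', '.join(self.model.reference.names())}",
                 f"archive size      : {len(self.archive)}",
                 f"total error (best): {self.total_error:.2f} %",
                 "",
                 "per-metric errors (best fit):"]
        for k, v in self.per_metric_errors.items():
            sim = self.archive[0].simulated_values.get(k, float("nan"))
            lines.append(f"  {k:<22s} sim={sim:8.3f}  err={v:6.2f} %")
        lines.append("")
        lines.append(f"{'parameter':<14s}{'best':>10s}{'mean(top)':>12s}"
                     f"{'sd(top)':>10s}{'range':>20s}")
        spread = self.params_spread(top)
        for n in self.model.search_names:
            lo, hi = TABLE1_RANGES[n]
            lines.append(f"{n:<14s}{getattr(self.params, n):>10.4g}"
                         f"{spread.loc[n, 'mean']:>12.4g}"
                         f"{spread.loc[n, 'sd']:>10.4g}"
                         f"{f'[{lo:g}, {hi:g}]':>20s}")
        return "\n".join(lines)

    # ------------------------------------------------------------ follow-ups
    def simulate(self, schedule: TreatmentSchedule | None = None,
                 record_days=(5.0, 10.0, 17.0), seed: int | None = None):
        return run(self.model.domain, self.params, schedule=schedule,
                   record_days=record_days,
                   seed=self.seed if seed is None else seed)

    def cohort_experiment(self, schedule: TreatmentSchedule, top: int = 20,
                          n_runs: int = 3, seed: int = 0, **kwargs):
        from .calibration import cohort_experiment

        return cohort_experiment(self.cohort(top), self.model.domain,
                                 schedule, n_runs=n_runs, seed=seed, **kwargs)

    def plot_growth(self, record_days=(0.0, 5.0, 10.0, 17.0), seed=None,
                    ax=None):
        """Simulated diameter trajectory against the reference points."""
        import matplotlib.pyplot as plt

        from .metrics import snapshot_diameter

        res = self.simulate(record_days=record_days, seed=seed)
        days = sorted(res.snapshots)
        diams = [snapshot_diameter(res.snapshots[d]) for d in days]
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(days, diams, "o-", label="simulated")
        ref = self.model.reference.table
        size_rows = ref[ref["metric"].str.startswith("diameter_")]
        ref_days = [float(m.split("_")[1].rstrip("d")) for m in size_rows["metric"]]
        ax.plot(ref_days, size_rows["value"], "ks", label="reference")
        ax.set_xlabel("days post injection")
        ax.set_ylabel("tumor diameter (mm)")
        ax.legend()
        return ax

    def plot_convergence(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.trace.generation, self.trace.best_error, label="best")
        ax.plot(self.trace.generation, self.trace.archive_mean_error,
                label="archive mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("total weighted error (%)")
        ax.legend()
        return ax
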