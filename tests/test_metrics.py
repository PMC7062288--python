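import numpy as np
import pytest

from gliomabm.cells import INFECTED, RECRUITED, ResponseParams
from gliomabm.engine import Snapshot
from gliomabm.metrics import (classify_outcome, core_and_rim, ki67_index,
                              lineage_ratio, phenotype_stats,
                              snapshot_diameter, tumor_diameter)

SPACING = 0.1  # mm
GRID = (40, 40)


def disc_grid(radius_mm, level, center=(2.0, 2.0), kappa=100.0):
    """Flat counts/capacity arrays with a disc at `level` x capacity."""
    nrows, ncols = GRID
    r, c = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    x = (c + 0.5) * SPACING
    y = (r + 0.5) * SPACING
    counts = np.zeros(nrows * ncols)
    inside = (x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius_mm**2
    counts[inside.ravel()] = level * kappa
    capacity = np.full(nrows * ncols, kappa)
    return counts, capacity


def make_snapshot(**kw):
    n = kw.pop("n", 4)
    base = dict(
        day=17.0,
        x=np.linspace(100, 400, n), y=np.full(n, 200.0),
        tau=np.full(n, 40.0), v=np.full(n, 25.0),
        lineage=np.full(n, INFECTED, dtype=np.int8),
        cycle=np.zeros(n), quiescent=np.zeros(n, dtype=bool),
        c_pp=np.full(n, 1e6),
        counts=np.zeros(GRID[0] * GRID[1]),
        capacity=np.full(GRID[0] * GRID[1], 100.0),
        dens_idx=np.zeros(n, dtype=np.int64),
        dens_shape=GRID, spacing_mm=SPACING,
        n_inactive_recruitable=0,
    )
    base.update(kw)
    return Snapshot(**base)


RESP = ResponseParams(K_p=50.0, K_m=50.0, p_a=0.0, beta_p=1.0, beta_m=1.0)


class TestTumorDiameter:
    def test_full_density_disc(self):
        counts, cap = disc_grid(1.0, 1.0)
        d = tumor_diameter(counts, cap, SPACING, *GRID)
        assert d == pytest.approx(2.0, abs=0.15)

    def test_empty_grid_zero(self):
        counts = np.zeros(GRID[0] * GRID[1])
        cap = np.full_like(counts, 100.0)
        assert tumor_diameter(counts, cap, SPACING, *GRID) == 0.0

    def test_subthreshold_disc_zero(self):
        counts, cap = disc_grid(1.0, 0.05)
        assert tumor_diameter(counts, cap, SPACING, *GRID, threshold=0.10) == 0.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        counts, cap = disc_grid(1.5, 1.0)
        counts *= rng.uniform(0.0, 1.0, size=counts.size)
        diams = [tumor_diameter(counts, cap, SPACING, *GRID, threshold=t)
                 for t in (0.01, 0.1, 0.3, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(diams, diams[1:]))

    def test_equivalent_area_alternative(self):
        counts, cap = disc_grid(1.0, 1.0)
        d = tumor_diameter(counts, cap, SPACING, *GRID,
                           method="equivalent_area")
        assert d == pytest.approx(2.0, abs=0.1)


class TestCoreAndRim:
    def test_uniform_full_disc_has_no_rim(self):
        counts, cap = disc_grid(1.0, 1.0)
        d_c, d_r = core_and_rim(counts, cap, SPACING, *GRID)
        assert d_r == pytest.approx(0.0, abs=0.2)

    def test_core_plus_annulus_oracle(self):
        # 1-mm-radius core at 60% capacity inside a 2-mm-radius annulus at 5%
        core, cap = disc_grid(1.0, 0.60)
        shell, _ = disc_grid(2.0, 0.05)
        counts = np.maximum(core, shell)
        d_c, d_r = core_and_rim(counts, cap, SPACING, *GRID)
        assert d_c == pytest.approx(2.0, abs=0.2)
        assert d_c + d_r == pytest.approx(4.0, abs=0.2)
        assert d_r == pytest.approx(2.0, abs=0.3)

    def test_all_zero_grid(self):
        counts = np.zeros(GRID[0] * GRID[1])
        cap = np.full_like(counts, 100.0)
        assert core_and_rim(counts, cap, SPACING, *GRID) == (0.0, 0.0)


class TestLineageRatio:
    def test_balanced(self):
        lin = np.array([INFECTED] * 100 + [RECRUITED] * 100)
        assert lineage_ratio(lin) == 1.0

    def test_experimental_benchmark(self):
        # 80% of labeled cells recruited at 17 d corresponds to I/R = 0.25
        lin = np.array([INFECTED] * 20 + [RECRUITED] * 80)
        assert lineage_ratio(lin) == pytest.approx(0.25)

    def test_zero_recruited_signaled(self):
        with pytest.raises(ZeroDivisionError):
            lineage_ratio(np.array([INFECTED] * 5))


class TestPhenotypeStats:
    def test_homogeneous_saturated(self):
        snap = make_snapshot(n=50, x=np.linspace(100, 3000, 50),
                             c_pp=np.full(50, 1e9))
        stats, profiles = phenotype_stats(snap, RESP)
        assert stats["measured_p_mean"] == pytest.approx(1 / 40.0, rel=1e-5)
        assert stats["measured_m_mean"] == pytest.approx(25.0, rel=1e-5)
        assert stats["measured_p_sd"] == pytest.approx(0.0, abs=1e-9)
        assert profiles is not None

    def test_zero_pdgf_recruited_population_measures_zero(self):
        snap = make_snapshot(n=10, lineage=np.full(10, RECRUITED, dtype=np.int8),
                             c_pp=np.zeros(10))
        stats, _ = phenotype_stats(snap, RESP)
        assert stats["measured_p_mean"] == 0.0
        assert stats["measured_m_mean"] == 0.0

    def test_two_phenotype_weighted_average(self):
        tau = np.array([20.0] * 30 + [80.0] * 10)
        v = np.array([10.0] * 30 + [50.0] * 10)
        snap = make_snapshot(n=40, tau=tau, v=v, c_pp=np.full(40, 1e9),
                             x=np.linspace(0, 400, 40) + 100)
        stats, _ = phenotype_stats(snap, RESP)
        assert stats["measured_p_mean"] == pytest.approx(
            (30 / 20.0 + 10 / 80.0) / 40, rel=1e-5)
        assert stats["measured_m_mean"] == pytest.approx(
            (30 * 10.0 + 10 * 50.0) / 40, rel=1e-5)
        assert stats["potential_m_mean"] == pytest.approx(20.0)

    def test_quiescent_cells_excluded_from_measured(self):
        q = np.zeros(10, dtype=bool)
        q[:5] = True
        tau = np.array([20.0] * 5 + [40.0] * 5)
        snap = make_snapshot(n=10, tau=tau, quiescent=q, c_pp=np.full(10, 1e9))
        stats, _ = phenotype_stats(snap, RESP)
        assert stats["measured_p_mean"] == pytest.approx(1 / 40.0, rel=1e-4)


class TestKi67:
    def test_all_quiescent_zero(self):
        snap = make_snapshot(n=10, quiescent=np.ones(10, dtype=bool))
        assert ki67_index(snap, RESP) == 0.0

    @pytest.mark.parametrize("tau,expected", [(40.0, 50.0), (100.0, 20.0)])
    def test_uniform_phase_expectation(self, tau, expected, rng):
        # Ki-67 window of 20 h out of a tau-hour cycle at gamma = 1
        n = 4000
        snap = make_snapshot(n=n, tau=np.full(n, tau),
                             cycle=rng.uniform(0, 1, size=n),
                             c_pp=np.full(n, 1e12),
                             x=rng.uniform(0, 90, size=n),
                             y=rng.uniform(0, 90, size=n))
        got = ki67_index(snap, RESP)
        se = 100 * np.sqrt(expected / 100 * (1 - expected / 100) / n)
        assert got == pytest.approx(expected, abs=4 * se)

    def test_highest_activity_node_selected(self):
        # node 0: 2 of 4 positive; node 1: 3 of 10 positive -> node 1 wins
        cycle = np.array([0.9] * 2 + [0.1] * 2 + [0.9] * 3 + [0.1] * 7)
        dens_idx = np.array([0] * 4 + [1] * 10, dtype=np.int64)
        snap = make_snapshot(n=14, tau=np.full(14, 40.0), cycle=cycle,
                             c_pp=np.full(14, 1e12), dens_idx=dens_idx,
                             x=np.zeros(14), y=np.zeros(14))
        assert ki67_index(snap, RESP) == pytest.approx(30.0)


class TestOutcome:
    @pytest.mark.parametrize("d,cls", [
        (0.1, "complete_response"),
        (0.49, "complete_response"),
        (1.0, "small"),
        (2.5, "medium"),
        (3.2, "large"),
    ])
    def test_bins(self, d, cls):
        assert classify_outcome(d) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome(-1.0)
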