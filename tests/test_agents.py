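import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gliomabm.cells import (ACTIVATION_THRESHOLD, INFECTED, RECRUITED,
                            CellPopulation, Phenotype, ResponseParams,
                            advance_cycle, draw_phenotypes, gamma_response,
                            init_population, maybe_activate,
                            observed_phenotype, place_daughters)
from gliomabm.engine import ParameterSet, Simulation


class TestGammaResponse:
    @pytest.mark.parametrize(
        "lineage,c_pp,K,beta,p_a,expected",
        [
            (RECRUITED, 0.0, 50.0, 0.5, 10.0, 0.0),
            (INFECTED, 50.0, 50.0, 1.0, 0.0, 0.5),   # half-max identity
            (INFECTED, 40.0, 50.0, 1.0, 10.0, 0.5),  # (10+40)/(10+40+50)
            (RECRUITED, 50.0, 50.0, 0.1, 0.0, 1.0 / 1.1),
        ],
    )
    def test_known_values(self, lineage, c_pp, K, beta, p_a, expected):
        assert gamma_response(c_pp, lineage, K, beta, p_a) == pytest.approx(expected)

    def test_bounds_and_monotonicity(self):
        c = np.linspace(0, 1e4, 2000)
        for lineage, p_a in ((INFECTED, 10.0), (RECRUITED, 0.0)):
            g = gamma_response(c, lineage, 50.0, 0.3, p_a)
            assert (g >= 0).all() and (g < 1).all()
            assert (np.diff(g) > 0).all()

    @given(c=st.floats(0, 1e6), K=st.floats(5, 300), beta=st.floats(0.1, 1.0),
           p_a=st.floats(0.1, 50), dc=st.floats(1e-6, 1e3))
    @settings(derandomize=True, max_examples=200)
    def test_response_properties_hold_everywhere(self, c, K, beta, p_a, dc):
        # bounds and strict monotonicity for both lineages at arbitrary
        # admissible parameters
        for lineage, boost in ((INFECTED, p_a), (RECRUITED, 0.0)):
            g0 = gamma_response(c, lineage, K, beta, boost)
            g1 = gamma_response(c + dc, lineage, K, beta, boost)
            assert 0.0 <= g0 < 1.0
            # non-decreasing (equality possible at float saturation)
            assert g1 >= g0

    def test_saturates_to_one(self):
        assert gamma_response(1e9, RECRUITED, 300.0, 1.0, 0.0) == pytest.approx(1.0, abs=1e-6)

    def test_recruited_activation_barrier_below_infected_baseline(self):
        # for beta < 1 the recruited response exceeds the plain Hill curve
        c = np.linspace(0.1, 500, 100)
        plain = c / (c + 50.0)
        rec = gamma_response(c, RECRUITED, 50.0, 0.4, 0.0)
        assert (rec > plain).all()


class TestObservedPhenotype:
    def resp(self, **kw):
        base = dict(K_p=50.0, K_m=50.0, p_a=0.0, beta_p=1.0, beta_m=1.0)
        base.update(kw)
        return ResponseParams(**base)

    def test_zero_response_zero_phenotype(self):
        p, m = observed_phenotype(40.0, 30.0, RECRUITED, 0.0, self.resp())
        assert p == 0.0 and m == 0.0

    def test_saturation_reaches_potential(self):
        p, m = observed_phenotype(40.0, 30.0, INFECTED, 1e9, self.resp())
        assert p == pytest.approx(1 / 40.0, rel=1e-6)
        assert m == pytest.approx(30.0, rel=1e-6)

    def test_half_max_arithmetic(self):
        # tau = 50 h at gamma_p = 0.5 gives p = 0.01 /h
        p, _ = observed_phenotype(50.0, 0.0, INFECTED, 50.0, self.resp())
        assert p == pytest.approx(0.01)

    def test_gamma_cutoff_suppresses_activity(self):
        # recruited response just below the 0.1% cutoff is silenced
        r = self.resp(beta_p=1.0, beta_m=1.0)
        c = 0.04  # gamma ~ 8e-4 with K = 50
        p, m = observed_phenotype(40.0, 30.0, RECRUITED, c, r)
        assert p == 0.0 and m == 0.0

    def test_anti_migratory_factor_scales_speed_only(self):
        p1, m1 = observed_phenotype(40.0, 30.0, INFECTED, 1e9, self.resp())
        p2, m2 = observed_phenotype(40.0, 30.0, INFECTED, 1e9, self.resp(),
                                    am_factor=0.1)
        assert p2 == p1
        assert m2 == pytest.approx(0.1 * m1)


class TestCycle:
    def test_over_capacity_freezes_cycle(self):
        new, q, div = advance_cycle(0.4, 0.02, 1.0, local_count=101, capacity=100)
        assert q and not div and new == 0.4

    def test_at_capacity_not_quiescent(self):
        _, q, _ = advance_cycle(0.0, 0.02, 1.0, local_count=100, capacity=100)
        assert not q

    def test_zero_rate_never_progresses(self):
        new, q, div = advance_cycle(0.7, 0.0, 1e6, local_count=0, capacity=100)
        assert new == 0.7 and not div

    def test_division_event_and_reset(self):
        new, _, div = advance_cycle(0.995, 0.01, 1.0, local_count=5, capacity=100)
        assert div and new == 0.0

    def test_quiescence_blocks_division_even_at_threshold(self):
        new, q, div = advance_cycle(0.9999, 1.0, 1.0, local_count=200, capacity=100)
        assert q and not div and new == 0.9999


class TestDivision:
    def test_daughter_one_radius_away(self, gray_domain, rng):
        x, y = place_daughters([1000.0], [1000.0], gray_domain, rng)
        d = np.hypot(x[0] - 1000.0, y[0] - 1000.0)
        assert d == pytest.approx(12.5)

    def test_daughter_angles_uniform(self, gray_domain, rng):
        n = 10_000
        x, y = place_daughters(np.full(n, 1000.0), np.full(n, 1000.0),
                               gray_domain, rng)
        ang = np.arctan2(y - 1000.0, x - 1000.0)
        counts, _ = np.histogram(ang, bins=20, range=(-np.pi, np.pi))
        chi2 = ((counts - n / 20) ** 2 / (n / 20)).sum()
        assert chi2 < sps.chi2.ppf(0.999, df=19)

    def test_daughter_never_in_empty(self, rng):
        from gliomabm.tissue import make_synthetic_brain

        dom = make_synthetic_brain(
            2.0, 2.0, ventricle_spec=[{"x_frac": 0.5, "y_frac": 0.5,
                                       "radius_mm": 0.2}], seed=0)
        # parents hugging the ventricle wall
        px = np.full(500, 1000.0 - 205.0)
        py = np.full(500, 1000.0)
        x, y = place_daughters(px, py, dom, rng)
        assert dom.in_tissue(x, y).all()


class TestActivation:
    @pytest.mark.parametrize("c,expected", [
        (0.0, False),
        (ACTIVATION_THRESHOLD, False),  # strict inequality at the threshold
        (6e-4, True),
    ])
    def test_threshold_rule(self, c, expected):
        assert bool(maybe_activate(c)) is expected


class TestPhenotypeDraws:
    def test_zero_sigma_homogeneous(self, rng):
        tau, v = draw_phenotypes(50, 40.0, 0.0, 25.0, 0.0, rng)
        assert (tau == 40.0).all() and (v == 25.0).all()

    def test_truncation_bounds(self, rng):
        tau, v = draw_phenotypes(5000, 20.0, 60.0, 10.0, 60.0, rng)
        assert (tau >= 5.0).all()
        assert (v >= 0.0).all() and (v <= 100.0).all()

    def test_phenotype_validation(self):
        with pytest.raises(ValueError):
            Phenotype(tau=-1.0, v=10.0)
        with pytest.raises(ValueError):
            Phenotype(tau=10.0, v=-1.0)


class TestInitPopulation:
    def test_initial_counts(self, gray_domain, rng):
        params = ParameterSet()
        pop, rec = init_population(gray_domain, params, rng)
        assert int((pop.lineage[:pop.n] == INFECTED).sum()) == 100
        assert int((pop.lineage[:pop.n] == RECRUITED).sum()) == 100

    def test_recruitable_seeding_density(self, gray_domain, rng):
        params = ParameterSet(rho_r=2.0, kappa=100.0)
        _, rec = init_population(gray_domain, params, rng)
        n_nodes = int((gray_domain.capacity_map(100.0) > 0).sum())
        # Poisson with mean 2 per gray node
        mean = rec.n_inactive / n_nodes
        assert mean == pytest.approx(2.0, rel=0.15)

    def test_heritability_along_lineages(self, gray_domain):
        # run a short, PDGF-saturated simulation and check every daughter
        # carries its parent's exact phenotype
        params = ParameterSet(tau_mean=25.0, tau_sd=15.0, v_mean=10.0,
                              v_sd=10.0, rho_r=0.1, p_0=600.0, K_p=5.0,
                              r_d=0.0, dt=0.25)
        sim = Simulation(gray_domain, params, seed=5)
        sim.run_until(3.0)
        pop = sim.pop
        by_id = {int(pop.cell_id[i]): i for i in range(pop.n)}
        children = [i for i in range(pop.n) if pop.parent_id[i] >= 0]
        assert len(children) > 20
        for i in children:
            j = by_id[int(pop.parent_id[i])]
            assert pop.tau[i] == pop.tau[j]
            assert pop.v[i] == pop.v[j]
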