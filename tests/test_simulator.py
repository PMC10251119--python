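"""Simulator unit and property tests.

Oracles used here: closed-form Monod arithmetic, the exponential-growth
closed form for the division-threshold crossing time, and maximum/comparison
principles for the diffusion-reaction steady state.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftbalance.rng import ParkMiller
from driftbalance.simulator import (
    BASE_KINETICS, Cell, ConfigError, Kinetics, Population, SimulationConfig,
    diameter_to_mass, divide, grow_step, init_population,
    monod_rate, relax, run, run_to_rows, solve_substrate,
)

BULK = 1.0e-4


# ---------------------------------------------------------------- kinetics

class TestMonod:
    def test_half_saturation_identity(self):
        assert monod_rate(BASE_KINETICS, BASE_KINETICS.K_s) == pytest.approx(0.5)

    def test_zero_substrate(self):
        assert monod_rate(BASE_KINETICS, 0.0) == 0.0

    def test_study_parameter_point(self):
        # mu_max=1/h, K_s=3.5e-5, S=1e-4 -> 1e-4 / 1.35e-4
        assert monod_rate(BASE_KINETICS, 1.0e-4) == pytest.approx(0.740740740, abs=1e-6)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            monod_rate(BASE_KINETICS, -1e-9)

    @given(st.floats(min_value=0, max_value=1.0, allow_nan=False),
           st.floats(min_value=0, max_value=1.0, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_monotone(self, s1, s2):
        r1, r2 = monod_rate(BASE_KINETICS, s1), monod_rate(BASE_KINETICS, s2)
        assert 0 <= r1 < BASE_KINETICS.mu_max
        if s1 <= s2:
            assert r1 <= r2

    def test_kinetics_validation(self):
        with pytest.raises(ConfigError):
            Kinetics(mu_max=0.0, K_s=1e-5, yield_=0.61)
        with pytest.raises(ConfigError):
            Kinetics(mu_max=1.0, K_s=-1e-5, yield_=0.61)


# ----------------------------------------------------------- initialisation

class TestInitPopulation:
    def test_2x2_grid_wrapped_neighbour_distances(self):
        cfg = SimulationConfig(n_initial=4, spacing=2.5, seed=1)
        popn, _ = init_population(cfg)
        L = cfg.domain_xy
        assert L == pytest.approx(2 * 2.5e-6)
        pitch = 2.5e-6
        for a in range(4):
            dists = []
            for b in range(4):
                if a == b:
                    continue
                d = popn.positions[a] - popn.positions[b]
                d[0] -= L * round(d[0] / L)
                d[1] -= L * round(d[1] / L)
                dists.append(np.linalg.norm(d))
            assert min(dists) == pytest.approx(pitch)

    def test_3x3_grid_domain_edge(self):
        cfg = SimulationConfig(n_initial=9, spacing=10.0, seed=1)
        assert cfg.domain_xy == pytest.approx(30e-6)
        popn, fld = init_population(cfg)
        assert popn.n == 9
        assert sorted(popn.lineages) == list(range(1, 10))

    def test_non_square_population_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_initial=5, spacing=5.0, seed=1)

    def test_field_uniform_at_bulk(self):
        cfg = SimulationConfig(n_initial=4, spacing=5.0, seed=1)
        _, fld = init_population(cfg)
        assert np.all(fld.concentrations == cfg.bulk_concentration)

    def test_founders_rest_on_substratum(self):
        cfg = SimulationConfig(n_initial=9, spacing=5.0, seed=1)
        popn, _ = init_population(cfg)
        assert np.allclose(popn.positions[:, 2], cfg.initial_diameter / 2)


# ----------------------------------------------------------------- division

def _parent(mass_factor=2.5):
    mass = float(diameter_to_mass(1.36e-6)) * mass_factor
    # well above the substratum so the z-clamp cannot shift a daughter
    return Cell(np.array([2e-6, 2e-6, 5e-6]), mass, lineage_id=3,
                kinetics=BASE_KINETICS)


class TestDivide:
    def test_mass_conserved_exactly_and_fraction_bounds(self):
        rng = ParkMiller(99)
        for _ in range(200):
            parent = _parent()
            d1, d2 = divide(parent, rng)
            assert d1.mass + d2.mass == parent.mass  # exact float equality
            assert 0.4 * parent.mass <= d1.mass <= 0.6 * parent.mass

    def test_lineage_and_kinetics_inherited(self):
        d1, d2 = divide(_parent(), ParkMiller(5))
        assert d1.lineage_id == d2.lineage_id == 3
        assert d1.kinetics == d2.kinetics == BASE_KINETICS

    def test_daughters_tangent_centred_on_parent(self):
        parent = _parent()
        d1, d2 = divide(parent, ParkMiller(17))
        sep = np.linalg.norm(d1.position - d2.position)
        assert sep == pytest.approx((d1.diameter + d2.diameter) / 2, rel=1e-9)
        mid = (d1.position + d2.position) / 2
        # centred on the parent except for the substratum clamp in z
        assert mid[:2] == pytest.approx(parent.position[:2], rel=1e-9)

    def test_below_threshold_rejected(self):
        small = Cell(np.zeros(3) + 1e-6, float(diameter_to_mass(1.0e-6)),
                     1, BASE_KINETICS)
        with pytest.raises(ValueError):
            divide(small, ParkMiller(1))

    def test_split_fractions_uniform(self):
        # Monte-Carlo check of the stated U(0.4, 0.6) biomass allocation
        from scipy import stats

        rng = ParkMiller(2024)
        fs = []
        parent = _parent()
        for _ in range(5000):
            d1, _d2 = divide(parent, rng)
            fs.append(d1.mass / parent.mass)
        ks = stats.kstest(fs, "uniform", args=(0.4, 0.2))
        assert ks.pvalue > 0.01


# --------------------------------------------------------------- relaxation

class TestRelax:
    L = 20e-6
    H = 2e-4

    def test_overlapping_pair_separated(self):
        d = 1.2e-6
        pos = np.array([[5e-6, 5e-6, 1e-6], [5e-6 + 1.0e-6, 5e-6, 1e-6]])
        diam = np.array([d, d])  # overlap 0.2 um
        out = relax(pos, diam, self.L, self.L, self.H)
        gap = np.linalg.norm(out[0] - out[1]) - d
        assert gap >= -1e-3 * d

    def test_non_overlapping_fixed_point(self):
        pos = np.array([[2e-6, 2e-6, 1e-6], [8e-6, 8e-6, 1e-6]])
        diam = np.array([1.2e-6, 1.2e-6])
        out = relax(pos.copy(), diam, self.L, self.L, self.H)
        assert np.allclose(out, pos)

    def test_push_across_periodic_boundary_wraps(self):
        d = 1.2e-6
        pos = np.array([[0.1e-6, 5e-6, 1e-6], [self.L - 0.2e-6, 5e-6, 1e-6]])
        diam = np.array([d, d])  # overlapping across the x boundary
        out = relax(pos, diam, self.L, self.L, self.H)
        assert np.all(out[:, 0] >= 0) and np.all(out[:, 0] < self.L)
        dx = out[0, 0] - out[1, 0]
        dx -= self.L * round(dx / self.L)
        gap = abs(dx) - d
        assert gap >= -1e-3 * d

    def test_substratum_keeps_centres_above_radius(self):
        d = 1.2e-6
        pos = np.array([[5e-6, 5e-6, 0.6e-6], [5e-6, 5e-6, 1.2e-6]])
        diam = np.array([d, d])
        out = relax(pos, diam, self.L, self.L, self.H)
        assert np.all(out[:, 2] >= d / 2 - 1e-12)


# ---------------------------------------------------------------- substrate

def _field(cfg):
    _, fld = init_population(cfg)
    return fld


def _single_colony_popn(cfg, n_cells=8, mass_factor=1.0):
    m = float(diameter_to_mass(cfg.initial_diameter)) * mass_factor
    rng = np.random.default_rng(1)
    pos = np.column_stack([
        np.full(n_cells, cfg.domain_xy / 2) + rng.normal(0, 2e-7, n_cells),
        np.full(n_cells, cfg.domain_xy / 2) + rng.normal(0, 2e-7, n_cells),
        np.abs(rng.normal(1e-6, 5e-7, n_cells)) + 5e-7,
    ])
    pos[:, :2] %= cfg.domain_xy
    return Population(
        positions=pos, masses=np.full(n_cells, m),
        lineages=np.ones(n_cells, dtype=np.int64),
        mu_max=np.full(n_cells, 1.0), K_s=np.full(n_cells, 3.5e-5),
        yield_=0.61,
    )


class TestSolveSubstrate:
    cfg = SimulationConfig(n_initial=4, spacing=10.0, seed=1)

    def test_zero_biomass_gives_uniform_bulk(self):
        empty = Population(
            positions=np.zeros((0, 3)), masses=np.zeros(0),
            lineages=np.zeros(0, dtype=np.int64), mu_max=np.zeros(0),
            K_s=np.zeros(0), yield_=0.61,
        )
        out = solve_substrate(_field(self.cfg), empty, self.cfg, dt=0.1)
        assert np.all(out.concentrations == BULK)

    def test_bounds_and_vertical_monotonicity_over_colony(self):
        popn = _single_colony_popn(self.cfg, n_cells=30, mass_factor=2.0)
        out = solve_substrate(_field(self.cfg), popn, self.cfg, dt=0.1)
        S = out.concentrations
        assert np.all(S >= 0) and np.all(S <= BULK + 1e-18)
        # maximum principle: S nonincreasing from the top boundary down the
        # vertical through the colony
        ix = int(popn.positions[0, 0] / out.voxel_edges[0])
        iy = int(popn.positions[0, 1] / out.voxel_edges[1])
        column = S[ix, iy, :]
        assert np.all(np.diff(column) >= -1e-12)
        assert column[-1] == pytest.approx(BULK)

    def test_doubling_uptake_weakly_decreases_field(self):
        # comparison-principle oracle: more sink, less substrate everywhere
        popn = _single_colony_popn(self.cfg, n_cells=10)
        out1 = solve_substrate(_field(self.cfg), popn, self.cfg, dt=0.1)
        heavier = _single_colony_popn(self.cfg, n_cells=10, mass_factor=2.0)
        out2 = solve_substrate(_field(self.cfg), heavier, self.cfg, dt=0.1)
        assert np.all(out2.concentrations <= out1.concentrations + 1e-15)

    def test_rejects_nonpositive_dt(self):
        popn = _single_colony_popn(self.cfg)
        with pytest.raises(ValueError):
            solve_substrate(_field(self.cfg), popn, self.cfg, dt=0.0)


# ------------------------------------------------------------------- growth

class TestGrowStep:
    def test_division_threshold_crossing_time_closed_form(self):
        # at constant S = bulk, mu = 0.740740...; mass ~ d^3 grows as
        # exp(mu t), so d reaches 1.36 um at t* = ln(1.36^3) / mu = 1.2451 h
        cfg = SimulationConfig(n_initial=4, spacing=10.0, seed=1,
                               division_diameter=1e-5)  # division disabled
        popn, fld = init_population(cfg)
        popn.positions = popn.positions[:1]
        popn.masses = popn.masses[:1]
        popn.lineages = popn.lineages[:1]
        popn.mu_max, popn.K_s = popn.mu_max[:1], popn.K_s[:1]
        rng = ParkMiller(1)
        dt, t = 0.01, 0.0
        while float(popn.diameters[0]) < 1.36e-6:
            popn = grow_step(popn, fld, dt, rng, cfg)
            t += dt
        mu = monod_rate(BASE_KINETICS, BULK)
        t_star = math.log(1.36**3) / mu
        assert t == pytest.approx(t_star, abs=dt)

    def test_zero_dt_is_identity(self, tiny_run_config):
        popn, fld = init_population(tiny_run_config)
        before = popn.masses.copy()
        out = grow_step(popn, fld, 0.0, ParkMiller(1), tiny_run_config)
        assert np.array_equal(out.masses, before)

    def test_biomass_never_decreases(self, tiny_run_config):
        popn, fld = init_population(tiny_run_config)
        rng = ParkMiller(2)
        for _ in range(5):
            before = popn.masses.sum()
            popn = grow_step(popn, fld, 0.05, rng, tiny_run_config)
            assert popn.masses.sum() >= before


# ------------------------------------------------------------------ full run

class TestRun:
    def test_seed_determinism_bitwise(self, tiny_run_config, tiny_run_result):
        again = run(tiny_run_config)
        assert np.array_equal(again.final_fractions,
                              tiny_run_result.final_fractions)
        assert again.loser_id == tiny_run_result.loser_id
        assert again.n_steps == tiny_run_result.n_steps
        assert again.status == tiny_run_result.status

    def test_fractions_sum_to_one(self, tiny_run_result):
        assert tiny_run_result.final_fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert tiny_run_result.loser_id == (
            int(np.argmin(tiny_run_result.final_fractions)) + 1
        )

    def test_growth_uptake_ledger_consistency(self):
        # per step, biomass gained must equal yield * substrate consumed by
        # the reaction term (discretisation tolerance 1%)
        cfg = SimulationConfig(n_initial=4, spacing=5.0, seed=5,
                               stop_volume_fraction=0.01)
        diag = {}
        run(cfg, diagnostics=diag)
        gained = np.array(diag["delta_biomass"])
        consumed = np.array(diag["substrate_consumed"])
        rel = np.abs(gained - BASE_KINETICS.yield_ * consumed) / gained
        assert np.max(rel) < 0.01

    def test_stop_criterion_reached_not_overshot_much(self, tiny_run_config,
                                                      tiny_run_result):
        frac = tiny_run_result.stop_volume_fraction
        target = tiny_run_config.stop_volume_fraction
        assert target <= frac < target * 1.25

    def test_step_cap_raises(self):
        cfg = SimulationConfig(n_initial=4, spacing=5.0, seed=1,
                               stop_volume_fraction=0.5, max_steps=3)
        with pytest.raises(RuntimeError, match="step cap"):
            run(cfg)

    def test_run_table_rows_schema(self, tiny_run_result):
        rows = run_to_rows(tiny_run_result, "toy")
        assert len(rows) == 4
        assert sum(r["is_loser"] for r in rows) == 1
        assert all(r["dKs_pct"] == 0.0 and r["dmu_pct"] == 0.0 for r in rows)
        total = sum(r["final_fraction"] for r in rows)
        assert total == pytest.approx(1.0, abs=1e-9)


# -------------------------------------------------- dimensionless invariance

def test_density_scaling_symmetry_is_exact():
    """The biomass density is a convention only up to the concentration
    scale: co-scaling density, bulk concentration and K_s by one factor is
    an exact symmetry of the model (all concentrations scale linearly and
    the Monod ratio is unchanged).  With a power-of-two factor the symmetry
    is bit-exact in floating point, so the whole trajectory must replay."""
    base = SimulationConfig(n_initial=4, spacing=5.0, seed=13,
                            stop_volume_fraction=0.01)
    scaled = SimulationConfig(
        n_initial=4, spacing=5.0, seed=13, stop_volume_fraction=0.01,
        density=2 * base.density,
        bulk_concentration=2 * base.bulk_concentration,
        base_kinetics=Kinetics(mu_max=1.0, K_s=2 * 3.5e-5, yield_=0.61),
    )
    r1, r2 = run(base), run(scaled)
    assert r1.loser_id == r2.loser_id
    assert np.array_equal(r1.final_fractions, r2.final_fractions)
    assert r1.n_steps == r2.n_steps
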