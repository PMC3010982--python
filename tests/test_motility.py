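"""Migration, alignment, cell cycle and order-parameter tests."""

import math

import numpy as np
import pytest

from myoswitch import motility as mo
from myoswitch.errors import ParameterError, UndefinedResultError
from myoswitch.model_core import PhenotypeState

WORLD = (10.0, 10.0)


def cell(x, y, heading=0.0, cid=0, clock=0, length=22, P=0.0):
    return mo.Cell(
        id=cid,
        position=(x, y),
        heading=heading,
        cycle_clock=clock,
        cycle_length=length,
        state=PhenotypeState(P=P),
        founder_class="low",
    )


class TestNeighbourSet:
    def test_lone_cell_has_no_neighbours(self):
        c = cell(5, 5)
        assert mo.neighbor_set([c], c, 1.5, WORLD) == []

    def test_distance_exactly_radius_is_included(self):
        a, b = cell(1, 1), cell(3.5, 1)
        assert b in mo.neighbor_set([a, b], a, 2.5, WORLD)
        assert a in mo.neighbor_set([a, b], b, 2.5, WORLD)

    def test_periodic_wrap_across_edges(self):
        # distance across the seam of a 10x10 world: (0.5,5) to (9.5,5) is 1
        a, b = cell(0.5, 5), cell(9.5, 5)
        assert b in mo.neighbor_set([a, b], a, 1.5, WORLD)
        # and the corner wrap: (0.2,0.2) to (9.8,9.8) is sqrt(0.32) ~ 0.57
        c, d = cell(0.2, 0.2), cell(9.8, 9.8)
        assert d in mo.neighbor_set([c, d], c, 0.6, WORLD)
        assert d not in mo.neighbor_set([c, d], c, 0.5, WORLD)


class TestUpdateHeading:
    def test_solitary_cell_moves_randomly(self, rng):
        mp = mo.MotilityParams()
        draws = {mo.update_heading(cell(5, 5), [], mp, rng) for _ in range(50)}
        assert len(draws) == 50
        assert all(0 <= h < 2 * math.pi for h in draws)

    def test_noise_free_alignment_gives_axis_or_antiaxis(self, rng):
        mp = mo.MotilityParams(eta=0.0)
        theta0 = 0.7
        nbrs = [cell(5, 5 + 0.1 * k, heading=theta0) for k in range(1, 4)]
        for _ in range(20):
            h = mo.update_heading(cell(5, 5), nbrs, mp, rng)
            assert min(
                abs(h - theta0), abs(h - (theta0 + math.pi)), abs(h - (theta0 - math.pi))
            ) < 1e-9

    def test_nematic_equivalence_of_opposite_headings(self, rng):
        # neighbours split between theta and theta+pi define the same axis
        mp = mo.MotilityParams(eta=0.0)
        theta0 = 1.1
        nbrs = [cell(5, 5.1, heading=theta0), cell(5, 4.9, heading=theta0 + math.pi)]
        h = mo.update_heading(cell(5, 5), nbrs, mp, rng)
        assert min(abs(h - theta0), abs(h - (theta0 + math.pi))) < 1e-9

    def test_balanced_axes_fall_back_to_previous_heading(self, rng):
        # perpendicular axes cancel in the doubled-angle sum
        mp = mo.MotilityParams(eta=0.0)
        focal = cell(5, 5, heading=0.42)
        nbrs = [cell(5, 5.1, heading=0.0), cell(5, 4.9, heading=math.pi / 2)]
        assert mo.update_heading(focal, nbrs, mp, rng) == pytest.approx(0.42)


class TestSpeedAndPosition:
    def test_speed_positive_and_mean_matches(self, rng):
        mp = mo.MotilityParams(mean_speed=1.0)
        draws = np.array([mo.step_speed(mp, rng) for _ in range(100_000)])
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(1.0, abs=0.01)
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(1.0, abs=0.02)  # exponential: CV = 1

    @pytest.mark.parametrize(
        "pos, heading, speed, expected",
        [
            ((3.0, 3.0), 0.3, 0.0, (3.0, 3.0)),
            ((9.5, 5.0), 0.0, 1.0, (0.5, 5.0)),   # wraps
            ((3.0, 3.0), math.pi / 2, 2.0, (3.0, 5.0)),
        ],
    )
    def test_advance_position(self, pos, heading, speed, expected):
        got = mo.advance_position(pos, heading, speed, WORLD)
        assert got[0] == pytest.approx(expected[0], abs=1e-12)
        assert got[1] == pytest.approx(expected[1], abs=1e-12)


class TestAdvanceCycle:
    def test_clock_increments_before_division(self, rng):
        pp = mo.PopulationParams()
        out = mo.advance_cycle(cell(5, 5, clock=3, length=22), 1, pp, rng, WORLD)
        assert len(out) == 1 and out[0].cycle_clock == 4

    def test_crowded_mother_defers_with_clock_held(self, rng):
        pp = mo.PopulationParams(crowding_cap=5)
        out = mo.advance_cycle(cell(5, 5, clock=22, length=22), 9, pp, rng, WORLD)
        assert len(out) == 1 and out[0].cycle_clock == 22

    def test_resource_starved_mother_defers(self, rng):
        pp = mo.PopulationParams(R_div=27.0)
        out = mo.advance_cycle(cell(5, 5, clock=22, length=22), 1, pp, rng, WORLD, local_R=10.0)
        assert len(out) == 1 and out[0].cycle_clock == 22

    def test_division_yields_two_daughters_nearby(self, rng):
        pp = mo.PopulationParams()
        mother = cell(5, 5, clock=22, length=22, P=7.5)
        out = mo.advance_cycle(mother, 1, pp, rng, WORLD, patch_size=1.0, local_R=90.0)
        assert len(out) == 2
        for d in out:
            assert d.cycle_clock == 0
            assert pp.cycle_min <= d.cycle_length <= pp.cycle_max
            assert d.state.P == 7.5
            assert d.founder_class == mother.founder_class
            assert abs(d.position[0] - 5) <= 0.5 and abs(d.position[1] - 5) <= 0.5

    def test_death_removes_cell(self):
        pp = mo.PopulationParams(death_rate=0.999999)
        rng = np.random.default_rng(0)
        assert mo.advance_cycle(cell(5, 5), 1, pp, rng, WORLD) == []


class TestNematicOrder:
    def test_identical_headings_give_one(self):
        cells = [cell(1, 1, 0.8), cell(1.2, 1, 0.8), cell(1, 1.2, 0.8)]
        assert mo.nematic_order(cells, 1.0, WORLD) == pytest.approx(1.0)

    def test_antiparallel_headings_still_give_one(self):
        cells = [cell(1, 1, 0.8), cell(1.2, 1, 0.8 + math.pi), cell(1, 1.2, 0.8)]
        assert mo.nematic_order(cells, 1.0, WORLD) == pytest.approx(1.0)

    def test_uniform_random_headings_give_near_zero(self, rng):
        n = 10_000
        xs = rng.uniform(0, 10, n)
        ys = rng.uniform(0, 10, n)
        headings = rng.uniform(0, 2 * math.pi, n)
        # global neighbourhood: radius covering the whole periodic world
        val = mo.nematic_order_arrays(xs, ys, headings, 7.0, WORLD)
        assert val < 0.05

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(UndefinedResultError):
            mo.nematic_order([cell(1, 1)], 1.0, WORLD)


def test_uncapped_growth_doubling_time_matches_cycle_length():
    """Exponential-phase doubling time ~ mean cycle length (22 steps)."""
    import copy

    from myoswitch.config import DEFAULTS, _build
    from myoswitch.simulator import run_simulation

    times = []
    for seed in range(10):
        d = copy.deepcopy(DEFAULTS)
        d["world"].update(nx=80, ny=80)
        d["population"].update(crowding_cap=10_000, R_div=0.0, death_rate=0.0)
        d["field"].update(u=0.5)  # negligible depletion: no resource brake
        d["run"].update(n_founders=24, n_steps=80, record_steps=[], seed=seed)
        res = run_simulation(_build(d))
        # fit log2(population) over the exponential window
        t = np.arange(20, 81)
        y = np.log2(res.population[20:81])
        slope = np.polyfit(t, y, 1)[0]
        times.append(1.0 / slope)
    assert np.mean(times) == pytest.approx(22.0, abs=2.0)


def test_alignment_raises_nematic_order_in_dense_population():
    """Paired seeded runs: aligned model beats random-migration control."""
    import copy

    from myoswitch.config import DEFAULTS, _build
    from myoswitch.simulator import _Engine

    diffs = []
    for seed in range(10):
        orders = {}
        for aligned in (True, False):
            d = copy.deepcopy(DEFAULTS)
            d["world"].update(nx=15, ny=15)
            d["motility"]["alignment_enabled"] = aligned
            d["population"].update(crowding_cap=10_000)
            d["run"].update(n_founders=250, n_steps=25, record_steps=[], seed=seed)
            eng = _Engine(_build(d))
            for _ in range(25):
                eng.step()
            orders[aligned] = mo.nematic_order_arrays(
                eng.x, eng.y, eng.heading, 1.5, (15.0, 15.0)
            )
        diffs.append(orders[True] - orders[False])
    assert np.mean(diffs) > 0.2
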