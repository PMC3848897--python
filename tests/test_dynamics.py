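"""Update rules: metabolic function, claims, lottery, decay, diffusion,
and the generation/run drivers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oracle
from mrmsim import (
    ConfigurationError,
    LatticeState,
    MEAN_FIELD,
    Neighborhood,
    SimulationParams,
    claim,
    default_types,
    diffusion_events_per_generation,
    init_grid,
    metabolic_function,
    occupancy_probabilities,
    run_generation,
    run_simulation,
    tm_rotate_block,
    update_empty_site,
    update_occupied_site,
)
from mrmsim.core import rng_state_from_seed
from mrmsim.dynamics import _Packed
from mrmsim import _kernels
from mrmsim.fixtures import fixture_params, make_fixture


class TestMetabolicFunction:
    def test_missing_metabolic_type_shuts_metabolism_down(self):
        assert metabolic_function([0, 0, 3, 7, 2], [1, 2, 3, 4]) == 0.0

    def test_all_ones_gives_unity(self):
        assert metabolic_function([0, 1, 1, 1, 1], [1, 2, 3, 4]) == 1.0

    def test_geometric_mean_of_counts(self):
        # (2*8*4*1)**(1/4) = 64**0.25
        M = metabolic_function([0, 2, 8, 4, 1], [1, 2, 3, 4])
        assert M == pytest.approx(64 ** 0.25, rel=1e-12)
        assert M == pytest.approx(2.8284271247461903, rel=1e-12)

    def test_product_mode_skips_the_root(self):
        assert metabolic_function([0, 2, 8], [1, 2], mode="product") == 16.0

    def test_parasite_counts_never_enter(self):
        # type 3 is a parasite: huge count must not change M
        a = metabolic_function([0, 2, 3, 0], [1, 2])
        b = metabolic_function([0, 2, 3, 99], [1, 2])
        assert a == b

    def test_empty_metabolic_set_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            metabolic_function([0, 1], [])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 30), min_size=1, max_size=8))
    def test_geometric_mean_bounded_by_extremes(self, counts):
        x = [0] + counts
        ids = list(range(1, len(counts) + 1))
        M = metabolic_function(x, ids)
        assert min(counts) - 1e-9 <= M <= max(counts) + 1e-9


class TestClaimsAndProbabilities:
    def test_claim_is_rate_times_metabolism(self):
        assert claim(9.0, 0.0) == 0.0
        assert claim(3.0, 1.0) == 3.0
        assert claim(5.0, 2.8284271) == pytest.approx(14.1421355, rel=1e-6)

    def test_no_claimant_means_site_stays_empty(self):
        p_e, p_f = occupancy_probabilities([], 2.0)
        assert p_e == 1.0 and p_f.size == 0

    def test_single_claimant_even_odds(self):
        p_e, p_f = occupancy_probabilities([2.0], 2.0)
        assert p_e == 0.5 and p_f[0] == 0.5

    def test_zero_total_convention(self):
        p_e, p_f = occupancy_probabilities([0.0, 0.0], 0.0)
        assert p_e == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=0, max_size=30),
        st.floats(0.01, 10),
    )
    def test_normalisation_is_exact(self, claims, C_e):
        p_e, p_f = occupancy_probabilities(claims, C_e)
        assert p_e + p_f.sum() == pytest.approx(1.0, abs=1e-12)


class TestElementaryUpdates:
    def test_occupied_site_never_decays_at_zero_rate(self, tiny_params):
        state = make_fixture("uniform_t1")
        p = fixture_params("uniform_t1", p_d=0.0)
        assert all(
            update_occupied_site(state, (2, 2), p) == 1 for _ in range(200)
        )

    def test_occupied_site_always_decays_at_unit_rate(self):
        state = make_fixture("uniform_t1")
        p = fixture_params("uniform_t1", p_d=1.0)
        assert all(
            update_occupied_site(state, (2, 2), p) == 0 for _ in range(200)
        )

    def test_decay_frequency_matches_rate(self):
        state = make_fixture("uniform_t1")
        p = fixture_params("uniform_t1", p_d=0.2)
        n = 100_000
        hits = sum(update_occupied_site(state, (0, 0), p) == 0 for _ in range(n))
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(hits - n * 0.2) < 4 * sd

    def test_update_empty_requires_empty_site(self):
        state = make_fixture("uniform_t1")
        with pytest.raises(ValueError):
            update_empty_site(state, (0, 0), fixture_params("uniform_t1"))

    def test_isolated_empty_site_stays_empty(self):
        grid = np.zeros((8, 8), dtype=np.int8)
        state = LatticeState(grid, rng_state_from_seed(0))
        p = fixture_params("uniform_t1")
        assert update_empty_site(state, (4, 4), p) == 0

    def test_incomplete_metabolism_blocks_all_replication(self):
        """With one metabolic type absent everywhere, every claim is zero and
        the empty site stays empty with probability one."""
        state = make_fixture("incomplete")
        p = fixture_params("incomplete")
        probs = oracle.empty_site_distribution(state.grid, (0, 0), p)
        assert probs[0] == 1.0
        assert all(update_empty_site(state, (0, 0), p) == 0 for _ in range(300))


class TestDiffusion:
    def test_rotation_permutation_table(self):
        # block (a b / c d) rotated clockwise becomes (c a / d b)
        grid = np.zeros((4, 4), dtype=np.int8)
        grid[0, 0], grid[0, 1], grid[1, 0], grid[1, 1] = 1, 2, 3, 4
        state = LatticeState(grid, rng_state_from_seed(0))
        tm_rotate_block(state, (0, 0), "right")
        assert grid[0, 0] == 3 and grid[0, 1] == 1
        assert grid[1, 0] == 4 and grid[1, 1] == 2

    def test_four_rotations_restore_block(self, rng):
        grid = rng.integers(0, 5, (6, 6)).astype(np.int8)
        state = LatticeState(grid.copy(), rng_state_from_seed(0))
        for _ in range(4):
            tm_rotate_block(state, (4, 4), "left")  # wraps around the torus
        assert np.array_equal(state.grid, grid)

    def test_left_then_right_is_identity(self, rng):
        grid = rng.integers(0, 3, (6, 6)).astype(np.int8)
        state = LatticeState(grid.copy(), rng_state_from_seed(0))
        tm_rotate_block(state, (2, 3), "left")
        tm_rotate_block(state, (2, 3), "right")
        assert np.array_equal(state.grid, grid)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_rotation_sequences_conserve_type_counts(self, seed):
        r = np.random.default_rng(seed)
        grid = r.integers(0, 4, (8, 8)).astype(np.int8)
        before = np.bincount(grid.ravel(), minlength=4)
        state = LatticeState(grid, rng_state_from_seed(seed))
        for _ in range(50):
            anchor = (int(r.integers(0, 8)), int(r.integers(0, 8)))
            tm_rotate_block(state, anchor, r.choice(["left", "right"]))
        assert np.array_equal(np.bincount(grid.ravel(), minlength=4), before)

    @pytest.mark.parametrize(
        "D,L,expected", [(0.0, 300, 0), (1.0, 300, 22_500), (100.0, 10, 2_500)]
    )
    def test_diffusion_event_budget(self, D, L, expected):
        assert diffusion_events_per_generation(D, L) == expected


class TestGenerationDriver:
    def test_generation_executes_exactly_L2_updates_and_budgeted_rotations(self):
        p = SimulationParams(
            L=300, t_max=1, D=1.0, seed=1,
            r_spec=Neighborhood("von_neumann"), h_spec=Neighborhood("von_neumann"),
        )
        res = run_simulation(p)
        assert res.n_site_updates == 90_000
        assert res.n_rotations == 22_500

    def test_same_seed_is_bit_identical(self, tiny_params):
        p = tiny_params.replace(D=2.0, t_max=30)
        a = run_simulation(p)
        b = run_simulation(p)
        assert np.array_equal(a.per_type_final, b.per_type_final)
        assert all(
            np.array_equal(x.counts, y.counts) and x.empties == y.empties
            for x, y in zip(a.census_series, b.census_series)
        )

    def test_pure_diffusion_conserves_census(self):
        """With decay off and an overwhelming empty-site claim, only
        rotations act and per-type counts are frozen."""
        p = SimulationParams(
            L=16, t_max=10, D=5.0, p_d=0.0, C_e=1e308, seed=9,
            r_spec=Neighborhood("von_neumann"), h_spec=Neighborhood("moore", 3),
        )
        res = run_simulation(p)
        first = res.census_series[0]
        for c in res.census_series:
            assert np.array_equal(c.counts, first.counts)

    def test_census_conservation_every_generation(self, tiny_params):
        res = run_simulation(tiny_params.replace(D=1.0))
        for c in res.census_series:
            assert c.total() == 16 * 16

    def test_all_empty_start_collapses_immediately(self, tiny_params):
        res = run_simulation(tiny_params.replace(init_occupancy=0.0, t_max=0))
        assert res.outcome == "collapsed"
        assert res.final_density == 0.0

    def test_single_metabolic_type_percolates(self):
        """A one-type community is a contact-like process and persists at
        study rates."""
        p = SimulationParams(
            L=50, types=default_types(1), t_max=200, seed=2,
            r_spec=Neighborhood("moore", 3), h_spec=Neighborhood("moore", 3),
        )
        res = run_simulation(p)
        assert res.outcome == "coexistent"
        assert res.final_density > 0.3

    def test_run_generation_matches_run_simulation_first_step(self, tiny_params):
        state = init_grid(tiny_params)
        state, census = run_generation(state, tiny_params, t=0)
        res = run_simulation(tiny_params.replace(t_max=1, early_stop=False))
        assert np.array_equal(census.counts, res.census_series[-1].counts)

    def test_schedule_and_sampling_variants_run(self, tiny_params):
        for schedule in ("interleaved", "diffusion_after"):
            for sampling in ("with_replacement", "permutation"):
                p = tiny_params.replace(
                    D=1.0, t_max=5, schedule=schedule, update_sampling=sampling
                )
                res = run_simulation(p)
                assert res.census_series[-1].total() == 256


class TestPathEquivalence:
    """The engine has two claim-evaluation routes: direct metabolic-window
    scans and the incrementally maintained per-site count table. They must
    produce bit-identical trajectories."""

    @pytest.mark.parametrize("h", ["N", "3", "5"])
    def test_direct_and_counted_paths_identical(self, h):
        p = SimulationParams(
            L=20, t_max=25, D=6.0, seed=13,
            r_spec=Neighborhood("moore", 5), h_spec=Neighborhood.from_label(h),
        )
        grids = []
        for uc in (True, False):
            pk = _Packed(p)
            pk.use_counts = uc
            st_ = init_grid(p)
            g = st_.type_counts(p.n_types).astype(np.int64)
            hc = pk.hcounts(st_.grid) if uc else np.zeros((1, 1, 1), np.int8)
            cen = np.zeros((p.t_max, p.n_types + 1), dtype=np.int64)
            pk.run(st_, g, p.t_max, cen, False, hcounts=hc)
            grids.append(st_.grid.copy())
        assert np.array_equal(grids[0], grids[1])

    def test_incremental_count_table_stays_consistent(self):
        p = SimulationParams(
            L=20, t_max=40, D=10.0, seed=21,
            r_spec=Neighborhood("moore", 3), h_spec=Neighborhood("moore", 5),
        )
        pk = _Packed(p)
        pk.use_counts = True
        st_ = init_grid(p)
        g = st_.type_counts(p.n_types).astype(np.int64)
        hc = pk.hcounts(st_.grid)
        cen = np.zeros((p.t_max, p.n_types + 1), dtype=np.int64)
        pk.run(st_, g, p.t_max, cen, False, hcounts=hc)
        ref = _kernels.recount_hcounts(
            st_.grid, pk.h_off, pk.met_slot, len(pk.met_ids), pk.wrap, pk.pad
        )
        assert np.array_equal(hc, ref)


class TestEmptySiteDistribution:
    """Sampled empty-site outcomes against the independent brute-force
    probability oracle (fast sanity version; the full chi-squared gate runs
    in the acceptance suite)."""

    def test_complete_vn_fixture_matches_oracle(self):
        state = make_fixture("complete_vn")
        p = fixture_params("complete_vn")
        probs = oracle.empty_site_distribution(state.grid, (4, 4), p)
        n = 20_000
        outcomes = np.array([update_empty_site(state, (4, 4), p) for _ in range(n)])
        freq = np.bincount(outcomes, minlength=p.n_types + 1) / n
        sd = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) < 5 * sd + 1e-12)

    def test_mean_field_claims_use_global_counts(self):
        state = make_fixture("complete_vn")
        p = fixture_params("complete_vn", h_spec=MEAN_FIELD)
        probs = oracle.empty_site_distribution(state.grid, (4, 4), p)
        n = 20_000
        outcomes = np.array([update_empty_site(state, (4, 4), p) for _ in range(n)])
        freq = np.bincount(outcomes, minlength=p.n_types + 1) / n
        sd = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) < 5 * sd + 1e-12)

    def test_parasite_claims_gated_by_metabolic_context(self):
        """In the parasite-pocket fixture a parasite deep inside its own
        cluster has no complete metabolic window, hence zero claim."""
        state = make_fixture("parasite_pocket")
        p = fixture_params("parasite_pocket")
        grid = state.grid.copy()
        grid[3, 3] = 0  # carve an empty site inside the parasite cluster
        probs = oracle.empty_site_distribution(grid, (3, 3), p)
        # the parasite neighbours (type 4) retain claims only if their own
        # 3x3 windows contain all of types 1..3; verify oracle agreement
        st_ = LatticeState(grid, state.rng_state)
        n = 20_000
        outcomes = np.array([update_empty_site(st_, (3, 3), p) for _ in range(n)])
        freq = np.bincount(outcomes, minlength=p.n_types + 1) / n
        sd = np.sqrt(probs * (1 - probs) / n)
        assert np.all(np.abs(freq - probs) < 5 * sd + 1e-12)
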