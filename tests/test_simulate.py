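"""Simulator behaviour: determinism, degenerate cases, analytic expectations."""

import numpy as np
import pandas as pd
import pytest

from scdispense import (
    DispensingSimParams,
    MockCommunityParams,
    cluster,
    build_distance,
    default_layout,
    make_dual_fluorophore_fixture,
    simulate_ani_matrix,
    simulate_dispensed_wells,
    simulate_experiment,
    simulate_mock_dispense,
    simulate_plate,
    simulate_wash_series,
)
from scdispense.layout import PlateLayout, normalize_well_id, well_ids


class TestLayout:
    def test_default_layout_roles(self):
        layout = default_layout()
        assert len(layout.dispensed_wells) == 88
        assert all(int(w[1:]) <= 11 for w in layout.dispensed_wells)
        assert layout.blank_wells == ["A12", "B12", "C12"]
        assert layout.ntc_wells == ["D12", "E12", "F12", "G12"]
        assert layout.wells_with_role("positive") == ["H12"]
        assert len(layout.role_map) == 96

    def test_incomplete_role_map_rejected(self):
        roles = {w: "dispensed" for w in well_ids()[:-1]}
        with pytest.raises(ValueError, match="every well"):
            PlateLayout(role_map=roles)

    @pytest.mark.parametrize(
        "raw,expected", [("a01", "A1"), ("H12", "H12"), ("b9", "B9")]
    )
    def test_well_id_normalization(self, raw, expected):
        assert normalize_well_id(raw) == expected

    def test_bad_well_id(self):
        with pytest.raises(ValueError):
            normalize_well_id("I1")


class TestSimulatePlate:
    def test_noise_free_all_green_singles(self):
        # degenerate case: no empties, no multis, all cells green, zero noise
        params = DispensingSimParams(
            empty_fraction=0.0,
            multi_fraction=0.0,
            color_prop=1.0,
            bg_sd=0.0,
            signal_sd=0.0,
            seed=1,
        )
        readings, truth = simulate_plate(params)
        layout = default_layout()
        dispensed = set(layout.dispensed_wells)
        sub = readings[readings["well"].isin(dispensed)]
        green = sub[sub["channel"] == "green"]["intensity"]
        red = sub[sub["channel"] == "red"]["intensity"]
        assert len(green) == 88
        assert np.allclose(green, params.bg_mean + params.signal_mean)
        assert np.allclose(red, params.bg_mean)

    def test_controls_have_no_cells(self):
        params = DispensingSimParams(seed=5)
        _, truth = simulate_plate(params)
        layout = default_layout()
        controls = set(layout.blank_wells) | set(layout.ntc_wells)
        assert (truth.loc[truth["well"].isin(controls), "n_cells"] == 0).all()

    def test_truth_color_counts_sum(self):
        _, truth = simulate_plate(DispensingSimParams(seed=7))
        assert (truth["n_green"] + truth["n_red"] == truth["n_cells"]).all()

    def test_seed_reproducibility(self):
        params = DispensingSimParams(seed=11)
        r1, t1 = simulate_experiment(params, n_plates=2)
        r2, t2 = simulate_experiment(params, n_plates=2)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError, match="empty_fraction"):
            DispensingSimParams(empty_fraction=1.5)

    def test_dual_fraction_matches_collision_expectation(self):
        # exactly-two model: P(dual | non-empty) = 2 p (1-p) m
        m, p, n = 0.2, 0.5, 100_000
        params = DispensingSimParams(
            empty_fraction=0.0, multi_fraction=m, color_prop=p, seed=42
        )
        counts = simulate_dispensed_wells(params, n)
        expected = 2 * p * (1 - p) * m
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(counts.n_dual / counts.n_nonempty - expected) < 3 * se

    def test_plate_and_bulk_simulators_agree(self):
        # the per-plate simulator's truth tallies match the analytic dual rate
        m, p = 0.3, 0.5
        params = DispensingSimParams(
            empty_fraction=0.0, multi_fraction=m, color_prop=p, seed=9
        )
        readings, truth = simulate_experiment(params, n_plates=60)
        disp = truth[truth["well"].map(lambda w: int(w[1:]) <= 11)]
        dual = ((disp["n_green"] > 0) & (disp["n_red"] > 0)).sum()
        n = len(disp)
        expected = 2 * p * (1 - p) * m
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(dual / n - expected) < 4 * se


class TestFixture:
    def test_exact_class_counts(self, dual_fixture):
        readings, truth, meta = dual_fixture
        assert meta["class_counts"] == {
            "green_only": 225,
            "red_only": 225,
            "dual": 27,
            "empty": 51,
        }
        disp = truth[truth["well"].map(lambda w: int(w[1:]) <= 11)]
        assert len(disp) == 528
        assert ((disp["n_green"] > 0) & (disp["n_red"] > 0)).sum() == 27
        assert (disp["n_cells"] > 0).sum() == 477

    @pytest.mark.parametrize("seed", [1, 7, 12345, 2**30])
    def test_exact_tallies_for_any_seed(self, seed):
        # the separation between signal, background and threshold is built
        # into the noise construction, so the tallies never depend on the seed
        from scdispense import classify_experiment

        readings, _, _ = make_dual_fluorophore_fixture(seed=seed)
        _, _, c = classify_experiment(readings)
        assert (c.n_green_only, c.n_red_only, c.n_dual, c.n_empty) == (225, 225, 27, 51)

    def test_fixture_deterministic(self):
        r1, t1, _ = make_dual_fluorophore_fixture(seed=0)
        r2, t2, _ = make_dual_fluorophore_fixture(seed=0)
        pd.testing.assert_frame_equal(r1, r2)

    def test_overfull_fixture_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            make_dual_fluorophore_fixture(n_plates=1, n_green_only=80, n_red_only=80)


class TestMockDispense:
    def test_unbiased_preserves_proportions(self):
        props = (0.4, 0.3, 0.2, 0.1)
        params = MockCommunityParams(
            species=("a", "b", "c", "d"),
            input_proportions=props,
            n_droplets=200_000,
            seed=3,
        )
        table = simulate_mock_dispense(params)
        se = np.sqrt(np.array(props) * (1 - np.array(props)) / params.n_droplets)
        assert np.all(np.abs(table["post"] - table["pre"]) < 4 * se)

    def test_bias_weight_shifts_expectation(self):
        # one doubled weight: post proportion -> w a / sum(w a)
        props = np.full(9, 1 / 9)
        weights = np.ones(9)
        weights[0] = 2.0
        params = MockCommunityParams(
            species=tuple(f"sp{i}" for i in range(9)),
            input_proportions=tuple(props),
            bias_weights=tuple(weights),
            n_droplets=100_000,
            seed=4,
        )
        table = simulate_mock_dispense(params)
        expected = weights * props / (weights * props).sum()
        se = np.sqrt(expected * (1 - expected) / params.n_droplets)
        assert np.all(np.abs(table["post"].to_numpy() - expected) < 4 * se)

    def test_zero_proportion_stays_zero(self):
        params = MockCommunityParams(
            species=("a", "b"), input_proportions=(1.0, 0.0), n_droplets=1000, seed=1
        )
        table = simulate_mock_dispense(params)
        assert table.loc[table["species"] == "b", "post"].item() == 0.0

    def test_zero_survivors_is_error(self):
        params = MockCommunityParams(
            species=("a",), input_proportions=(1.0,), viability=(0.0,),
            n_droplets=100, seed=1,
        )
        with pytest.raises(ValueError, match="degenerate"):
            simulate_mock_dispense(params)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MockCommunityParams(species=("a", "b"), input_proportions=(0.5, 0.4))


class TestWashSeriesSim:
    def test_noise_free_geometric(self):
        ws = simulate_wash_series(1000.0, retention=0.1, n_washes=3, noise_sd=0.0)
        assert ws.leftover_rates == pytest.approx((100.0, 10.0, 1.0))

    def test_retention_bounds(self):
        with pytest.raises(ValueError, match="retention"):
            simulate_wash_series(100.0, retention=1.0, n_washes=3)
        with pytest.raises(ValueError, match="retention"):
            simulate_wash_series(100.0, retention=0.0, n_washes=3)


class TestANISimulator:
    def test_single_lineage_all_identical(self):
        sim = simulate_ani_matrix(1, 3, within_ani_low=100.0, seed=0)
        assert (sim.ani.to_numpy() == 100.0).all()
        dist = build_distance(sim.ani, sim.aligned_fraction)
        assert len(cluster(dist, 99.9)) == 1

    def test_three_separated_blocks_recovered(self):
        sim = simulate_ani_matrix(3, 3, between_ani=97.0, seed=1)
        dist = build_distance(sim.ani, sim.aligned_fraction)
        parts = cluster(dist, 99.9)
        assert len(parts) == 3
        recovered = {frozenset(g for g in sim.genome_ids if sim.true_lineage[g] == k)
                     for k in range(3)}
        assert set(parts) == recovered

    def test_block_structure_and_symmetry(self):
        sim = simulate_ani_matrix(2, 4, between_ani=95.0, seed=2)
        a = sim.ani.to_numpy()
        assert np.allclose(a, a.T)
        assert np.all(np.diag(a) == 100.0)
        for i, gi in enumerate(sim.genome_ids):
            for j, gj in enumerate(sim.genome_ids):
                if i != j and sim.true_lineage[gi] == sim.true_lineage[gj]:
                    assert a[i, j] >= 99.9
                elif i != j:
                    assert a[i, j] < 99.0

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError):
            simulate_ani_matrix(0, 3)
        with pytest.raises(ValueError):
            simulate_ani_matrix(2, [3, 0])
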