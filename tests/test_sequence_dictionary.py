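"""Signal simulation, default train, grid construction and compression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcmrf import (
    SequenceTrain,
    TissueParams,
    build_dictionary,
    build_grid,
    compress,
    default_train,
    simulate_signal,
    simulate_signals,
)


class TestDefaultTrain:
    def test_schedule_ranges(self, train50):
        assert train50.n_frames == 50
        assert train50.flip_angle_deg.min() == pytest.approx(34.0)
        assert train50.flip_angle_deg.max() == pytest.approx(86.0)
        assert train50.te_ms.min() == pytest.approx(21.0)
        assert train50.te_ms.max() == pytest.approx(81.5)
        assert train50.tr_ms.min() == pytest.approx(3530.0)
        assert train50.tr_ms.max() == pytest.approx(6570.0)

    def test_inversion_rate_near_three_per_minute(self, train50):
        # 50 frames span ~252.5 s, so ~3/min means 12 or 13 pulses
        assert train50.duration_ms == pytest.approx(252500.0)
        assert train50.inversion_times_ms.size in (12, 13)
        rate = train50.inversion_times_ms.size / (train50.duration_ms / 60000.0)
        assert abs(rate - 3.0) < 0.25

    def test_single_frame_and_invalid(self):
        t1 = default_train(1)
        assert t1.n_frames == 1
        assert t1.inversion_times_ms.size == 0  # < 1 TR of cumulative time
        with pytest.raises(ValueError):
            default_train(0)

    def test_round_trip_through_text_table(self, train50):
        again = SequenceTrain.from_table(train50.to_table())
        np.testing.assert_allclose(again.flip_angle_deg, train50.flip_angle_deg)
        np.testing.assert_allclose(again.te_ms, train50.te_ms)
        np.testing.assert_allclose(again.tr_ms, train50.tr_ms)
        np.testing.assert_allclose(again.inversion_times_ms, train50.inversion_times_ms)


class TestSimulateSignal:
    def test_zero_flip_angles_give_zero_signal(self):
        train = SequenceTrain(np.zeros(5), np.full(5, 25.0), np.full(5, 4000.0))
        sig = simulate_signal(train, TissueParams(1000, 100))
        np.testing.assert_array_equal(sig, 0.0)

    def test_single_90_degree_pulse_closed_form(self):
        train = SequenceTrain([90.0], [30.0], [4000.0])
        tissue = TissueParams(800.0, 60.0, m0=2.5)
        sig = simulate_signal(train, tissue)
        assert sig[0] == pytest.approx(2.5 * np.exp(-30.0 / 60.0), rel=1e-12)

    def test_scale_equivariance_is_exact(self, train50):
        base = simulate_signal(train50, TissueParams(900, 80, m0=1.0))
        scaled = simulate_signal(train50, TissueParams(900, 80, m0=3.7))
        np.testing.assert_array_equal(scaled, 3.7 * base)

    def test_long_tr_limit_matches_saturation_recovery(self):
        # TR = 50*T1 and no inversions: every frame starts from equilibrium
        t1, t2s, b1 = 200.0, 50.0, 0.9
        n = 6
        train = SequenceTrain(
            np.full(n, 40.0), np.full(n, 25.0), np.full(n, 50 * t1)
        )
        sig = simulate_signal(train, TissueParams(t1, t2s, b1))
        expected = np.sin(np.deg2rad(40.0) * b1) * np.exp(-25.0 / t2s)
        np.testing.assert_allclose(sig, expected, rtol=1e-3)

    def test_long_t2star_shapes_nearly_degenerate(self, train50):
        # the protocol's TE range barely separates T2* = 150 ms from 1 s
        a = simulate_signal(train50, TissueParams(1000, 150))
        b = simulate_signal(train50, TissueParams(1000, 1000))
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert 1 - cos < 0.01

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        t1=st.floats(40, 4000),
        ratio=st.floats(0.01, 1.0),
        b1=st.floats(0.65, 1.35),
    )
    def test_signal_positivity(self, t1, ratio, b1):
        train = default_train(20)
        sig = simulate_signal(train, TissueParams(t1, max(t1 * ratio, 1.0), b1))
        assert np.all(sig >= 0)

    def test_inversion_efficiency_bounds(self):
        with pytest.raises(ValueError):
            SequenceTrain([40.0], [25.0], [4000.0], inversion_efficiency=0.0)

    def test_te_must_precede_tr(self):
        with pytest.raises(ValueError):
            SequenceTrain([40.0], [50.0], [40.0])


class TestBuildGrid:
    def test_protocol_grid_cardinality(self):
        grid = build_grid()
        assert grid.t1_values_ms.size == 101
        assert grid.t2star_values_ms.size == 132
        assert grid.n_b1 == 15
        assert grid.n_pairs == 8772
        assert grid.n_entries == 131580

    def test_geometric_step_is_uniform(self):
        grid = build_grid()
        ratios = grid.t1_values_ms[1:] / grid.t1_values_ms[:-1]
        np.testing.assert_allclose(ratios, 1.05, rtol=1e-12)

    def test_single_point_grid(self):
        grid = build_grid((100, 100), (100, 100), 0.05, (1, 1), 0.05)
        assert grid.n_entries == 1

    def test_all_pairs_admissible(self):
        grid = build_grid()
        assert np.all(grid.pair_t1_ms >= grid.pair_t2star_ms)

    def test_empty_admissible_set_raises(self):
        with pytest.raises(ValueError):
            build_grid((5, 10), (20, 30), 0.05, (1, 1), 0.05)


class TestBuildDictionary:
    def test_atoms_unit_norm(self, desk_dict):
        norms = np.linalg.norm(desk_dict.atoms, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_single_entry_matches_direct_simulation(self, train50):
        grid = build_grid((500, 500), (80, 80), 0.05, (1, 1), 0.05)
        d = build_dictionary(train50, grid)
        sig = simulate_signal(train50, TissueParams(grid.pair_t1_ms[0], grid.pair_t2star_ms[0]))
        np.testing.assert_allclose(d.atoms[:, 0], sig / np.linalg.norm(sig), atol=1e-12)
        assert d.norms[0] == pytest.approx(np.linalg.norm(sig))

    def test_slice_timing_offsets_change_short_t1_atoms(self, train50, tiny_grid):
        d0 = build_dictionary(train50, tiny_grid, slice_offset_ms=0.0)
        d1 = build_dictionary(train50, tiny_grid, slice_offset_ms=1500.0)
        short = np.argmin(tiny_grid.pair_t1_ms)
        assert not np.allclose(d0.atoms[:, short], d1.atoms[:, short], atol=1e-6)


class TestCompress:
    def test_full_rank_preserves_inner_products(self, tiny_dict):
        cd = compress(tiny_dict, tiny_dict.n_frames)
        gram_full = tiny_dict.atoms.T @ tiny_dict.atoms
        gram_comp = cd.atoms.T @ cd.atoms
        np.testing.assert_allclose(gram_comp, gram_full, atol=1e-10)

    def test_truncation_error_bounded_by_singular_value(self, tiny_dict, rng):
        rank = 6
        cd = compress(tiny_dict, rank)
        sig = tiny_dict.atoms @ rng.random(tiny_dict.n_entries)
        full = tiny_dict.atoms.T @ sig
        comp = cd.atoms.T @ cd.compress_data(sig)
        bound = cd.singular_values[rank] * np.linalg.norm(sig) + 1e-9
        assert np.abs(full - comp).max() <= bound

    def test_rank10_matching_equivalent_to_full(self, desk_dict, rng):
        """Compressed matching may land on a different index inside the
        degenerate long-T2* plateau, but the atom it picks is always the
        same signal as the full-space choice to within the truncation."""
        cd = compress(desk_dict, 10)
        idx = rng.choice(desk_dict.n_entries, size=400, replace=False)
        sig = desk_dict.atoms[:, idx]
        full_best = np.argmax(np.abs(desk_dict.atoms.T @ sig), axis=0)
        comp_best = np.argmax(np.abs(cd.atoms.T @ (cd.projector @ sig)), axis=0)
        cos = np.sum(desk_dict.atoms[:, full_best] * desk_dict.atoms[:, comp_best], axis=0)
        assert np.all(cos >= 0.999)
        assert np.mean(full_best == comp_best) >= 0.5

    def test_rank_bounds(self, tiny_dict):
        with pytest.raises(ValueError):
            compress(tiny_dict, 0)
        with pytest.raises(ValueError):
            compress(tiny_dict, tiny_dict.n_frames + 1)
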