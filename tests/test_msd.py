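"""MSD computation, multi-rate stitching, linear fits, and plateau analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confinedspt.msd import (
    CombinedMSD,
    MSDCurve,
    TrackTooShortError,
    combine_rates,
    confinement_from_plateau,
    ensemble_msd,
    ensemble_msd_from_frames,
    fit_linear_msd,
    read_combined_msd,
    trajectory_msd,
    write_combined_msd,
)
from confinedspt.simulate import SimulationConfig, Trajectory, _chart_paths


def _track(positions, rate=1.0, pad_to=10):
    """Build a Trajectory, padding by repeating the last point if needed."""
    pos = list(positions)
    while len(pos) < pad_to:
        pos.append(pos[-1])
    pos = np.asarray(pos, dtype=float)
    return Trajectory(id="t", frame_rate=rate,
                      times=np.arange(len(pos)) / rate, positions=pos)


def brute_force_msd(positions, max_lag):
    """Independent all-pairs double-loop oracle."""
    out = []
    for n in range(1, max_lag + 1):
        acc = [np.sum((positions[i + n] - positions[i]) ** 2)
               for i in range(len(positions) - n)]
        out.append(np.mean(acc))
    return np.array(out)


class TestTrajectoryMSD:
    def test_hand_enumerated_square_path(self):
        # unit square cycle (0,0),(1,0),(1,1),(0,1): every lag-1 pair is an
        # edge (1 μm²), every lag-2 pair a diagonal (2 μm²), lag-3 an edge again
        c = trajectory_msd(_square_cycle_track(), max_delay_frames=3)
        assert np.allclose(c.msd, [1.0, 2.0, 1.0])
        assert np.allclose(c.delays, [1.0, 2.0, 3.0])

    def test_constant_position_gives_zero(self):
        c = trajectory_msd(_track([(2.0, -1.0)] * 12), max_delay_frames=4)
        assert np.allclose(c.msd, 0.0)

    def test_nine_frame_track_rejected(self):
        tr = Trajectory(id="short", frame_rate=1.0, times=np.arange(9.0),
                        positions=np.zeros((9, 2)))
        with pytest.raises(TrackTooShortError):
            trajectory_msd(tr)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_exactly_matches_brute_force_all_pairs(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.normal(0, 1, (20, 2))
        tr = Trajectory(id="r", frame_rate=10.0, times=np.arange(20) / 10.0,
                        positions=pos)
        c = trajectory_msd(tr, max_delay_frames=19)
        assert np.array_equal(c.msd, brute_force_msd(pos, 19))


def _square_cycle_track(n_frames=12):
    """Track cycling the unit square at 1 Hz (satisfies the 10-frame floor)."""
    square = [(0, 0), (1, 0), (1, 1), (0, 1)]
    pos = np.array([square[i % 4] for i in range(n_frames)], dtype=float)
    return Trajectory(id="sq", frame_rate=1.0, times=np.arange(float(n_frames)),
                      positions=pos)


class TestEnsembleMSD:
    def test_identical_tracks_reproduce_curve_with_zero_sem(self):
        tr = _track([(0, 0), (0.1, 0), (0.2, 0.1), (0.1, 0.2)] * 3, pad_to=12)
        ens = ensemble_msd([tr, tr, tr], max_delay_frames=3)
        single = trajectory_msd(tr, max_delay_frames=3)
        assert np.allclose(ens.msd, single.msd)
        assert np.allclose(ens.sem, 0.0)

    def test_two_track_mean_and_sem(self):
        # per-track MSD(lag 1) of 1.0 and 3.0 → mean 2.0, sem 1.0
        a = _track([(i * 1.0, 0.0) for i in range(12)])  # steps of 1 → msd(1)=1
        b = _track([(i * np.sqrt(3.0), 0.0) for i in range(12)])  # msd(1)=3
        ens = ensemble_msd([a, b], max_delay_frames=1)
        assert ens.msd[0] == pytest.approx(2.0)
        assert ens.sem[0] == pytest.approx(1.0)

    def test_mixed_frame_rates_rejected(self):
        a = _track([(0, 0)] * 12, rate=100.0)
        b = _track([(0, 0)] * 12, rate=60.0)
        with pytest.raises(ValueError, match="mixed frame rates"):
            ensemble_msd([a, b])

    def test_short_tracks_skipped_not_fatal(self):
        good = _track([(0, 0)] * 12)
        short = Trajectory(id="s", frame_rate=1.0, times=np.arange(5.0),
                           positions=np.zeros((5, 2)))
        ens = ensemble_msd([good, short], max_delay_frames=2)
        assert ens.n_tracks == 1

    def test_array_path_equals_object_path(self, rng):
        frames = rng.normal(0, 0.1, (40, 30, 2))
        tracks = [
            Trajectory(id=f"t{i}", frame_rate=120.0,
                       times=np.arange(30) / 120.0, positions=frames[i])
            for i in range(40)
        ]
        a = ensemble_msd(tracks, max_delay_frames=10)
        b = ensemble_msd_from_frames(frames, 120.0, max_delay_frames=10)
        assert np.allclose(a.msd, b.msd, atol=1e-14)
        assert np.allclose(a.sem, b.sem, atol=1e-14)


class TestCombineRates:
    def _line_curve(self, rate, n, D=1.0, offset=0.0):
        delays = np.arange(1, n + 1) / rate
        return MSDCurve(frame_rate=rate, delays=delays,
                        msd=4 * D * delays + offset,
                        sem=np.full(n, 1e-3), n_tracks=50)

    def test_single_exact_line_anchored_to_origin(self):
        c = self._line_curve(1000.0, 10, D=1.0, offset=0.01)
        comb = combine_rates([c])
        assert comb.shifts_applied[1000.0] == pytest.approx(-0.01)
        assert np.allclose(comb.msd, 4 * 1.0 * comb.delays, atol=1e-12)

    def test_constant_offsets_removed_without_discontinuity(self):
        fast = self._line_curve(1000.0, 10, offset=0.02)
        slow = self._line_curve(400.0, 10, offset=0.05)
        comb = combine_rates([fast, slow])
        assert np.allclose(comb.msd, 4 * comb.delays, atol=1e-12)

    def test_invariant_under_arbitrary_constant_shifts(self, rng):
        base = [self._line_curve(1000.0, 10), self._line_curve(260.0, 10),
                self._line_curve(60.0, 10)]
        shifted = [
            MSDCurve(frame_rate=c.frame_rate, delays=c.delays,
                     msd=c.msd + off, sem=c.sem, n_tracks=c.n_tracks)
            for c, off in zip(base, rng.uniform(0.0, 0.3, 3))
        ]
        a, b = combine_rates(base), combine_rates(shifted)
        assert np.allclose(a.msd, b.msd, atol=1e-12)

    def test_no_overlap_raises(self):
        fast = self._line_curve(1000.0, 3)  # delays up to 3 ms
        slow = self._line_curve(10.0, 5)  # delays from 100 ms
        with pytest.raises(ValueError, match="overlap"):
            combine_rates([fast, slow], anchor_points=3)

    def test_round_trip_file_io(self, tmp_path):
        comb = combine_rates([self._line_curve(1000.0, 10),
                              self._line_curve(120.0, 10)])
        path = tmp_path / "msd.tsv"
        write_combined_msd(comb, path)
        loaded = read_combined_msd(path)
        assert np.allclose(loaded.msd, comb.msd)
        assert np.allclose(loaded.delays, comb.delays)
        assert loaded.shifts_applied == pytest.approx(comb.shifts_applied)


class TestLinearFit:
    def test_exact_line_recovered(self):
        delays = np.arange(1, 7) / 1000.0
        curve = MSDCurve(frame_rate=1000.0, delays=delays,
                         msd=4.0 * delays + 0.0025, sem=np.zeros(6))
        fit = fit_linear_msd(curve, n_points=6)
        assert fit.D == pytest.approx(1.0)
        assert fit.delta_sq == pytest.approx(0.0025)
        assert fit.localization_precision == pytest.approx(0.025)

    def test_zero_slope_gives_zero_D(self):
        delays = np.arange(1, 7) / 1000.0
        curve = MSDCurve(frame_rate=1000.0, delays=delays,
                         msd=np.full(6, 0.01), sem=np.zeros(6))
        assert fit_linear_msd(curve).D == pytest.approx(0.0)

    def test_noise_floor_yields_50nm_precision(self):
        # 500 stationary tracks with 50 nm noise → δ² ≈ 4σ² = 0.01 μm²
        rng = np.random.default_rng(3)
        frames = np.zeros((500, 30, 2)) + rng.normal(0, 0.05, (500, 30, 2))
        curve = ensemble_msd_from_frames(frames, 1000.0, max_delay_frames=10)
        fit = fit_linear_msd(curve, n_points=6)
        assert fit.delta_sq == pytest.approx(0.01, rel=0.1)
        assert fit.localization_precision == pytest.approx(0.05, rel=0.05)


class TestPlateau:
    def _flat_curve(self, level, n=20):
        delays = np.arange(1, n + 1) / 100.0
        return MSDCurve(frame_rate=100.0, delays=delays,
                        msd=np.full(n, level), sem=np.zeros(n))

    def test_printed_formula(self):
        est = confinement_from_plateau(self._flat_curve(0.03))
        assert est.detected
        assert est.L == pytest.approx(0.3)
        assert est.R == pytest.approx(0.15)

    def test_zero_plateau(self):
        est = confinement_from_plateau(self._flat_curve(0.0))
        assert est.detected and est.L == 0.0

    def test_rising_curve_flagged(self):
        delays = np.arange(1, 21) / 100.0
        curve = MSDCurve(frame_rate=100.0, delays=delays, msd=4.0 * delays,
                         sem=np.zeros(20))
        assert not confinement_from_plateau(curve).detected

    def test_disc_confinement_bias_of_square_law(self, rng):
        # for a circular domain the equilibrium plateau is R², so the square-
        # domain L²/3 rule recovers √3/2 ≈ 0.87 of the true radius (brute-force
        # chart simulation as oracle)
        R = 0.18
        paths = _chart_paths(3000, 1200, 5e-4, 5.0, R, rng)
        frames = paths[:, ::2, :]  # 1000 Hz sampling of the chart coordinates
        curve = ensemble_msd_from_frames(frames, 1000.0, max_delay_frames=300)
        est = confinement_from_plateau(curve)
        assert est.detected
        assert est.R == pytest.approx(np.sqrt(3.0) / 2.0 * R, rel=0.05)
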