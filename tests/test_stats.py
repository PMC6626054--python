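import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormscreen import (
    PopulationSpec,
    SimConfig,
    SpeedRecord,
    animal_speed,
    group_summary,
    simulate_population,
    window_track,
)

from conftest import make_track


class TestWindowTrack:
    def test_final_two_minutes_of_full_recording(self):
        t = np.arange(6000) / 10.0  # 600 s at 10 fps
        tr = make_track(0.01 * t, np.zeros_like(t), t=t)
        sub = window_track(tr)
        assert sub.t_s[0] == pytest.approx(480.0)
        assert sub.t_s[-1] == pytest.approx(599.9)
        assert len(sub) == 1200

    def test_track_outside_window_yields_nothing(self):
        t = np.linspace(0.0, 299.0, 100)
        tr = make_track(0.01 * t, np.zeros_like(t), t=t)
        assert window_track(tr, 480.0, 600.0) is None

    def test_window_covering_track_is_identity(self):
        t = np.linspace(0.0, 10.0, 11)
        tr = make_track(t, t, t=t)
        sub = window_track(tr, 0.0, 10.5)
        assert np.array_equal(sub.t_s, tr.t_s)
        assert np.array_equal(sub.x_mm, tr.x_mm)

    def test_invalid_window_raises(self):
        tr = make_track([0.0, 1.0], [0.0, 0.0])
        with pytest.raises(ValueError):
            window_track(tr, 5.0, 5.0)


class TestAnimalSpeed:
    def test_stationary_track_has_zero_speed(self):
        tr = make_track([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        assert animal_speed(tr).speed_mm_s == 0.0

    def test_hand_computed_three_point_track(self):
        # 3-4-5 step of 0.05 mm then no motion over 2 s total
        tr = make_track([0.0, 0.03, 0.03], [0.0, 0.04, 0.04], t=[0.0, 1.0, 2.0])
        rec = animal_speed(tr)
        assert rec.speed_mm_s == pytest.approx(0.025)
        assert rec.duration_s == pytest.approx(2.0)

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError):
            animal_speed(make_track([0.0], [0.0], t=[0.0]))


def rec(speed, duration, animal_id=0):
    return SpeedRecord(animal_id=animal_id, region=0, speed_mm_s=speed, duration_s=duration)


class TestGroupSummary:
    def test_hand_computed_weighted_mean(self):
        s = group_summary([rec(2.0, 1.0), rec(4.0, 3.0, 1)])
        assert s.mean_mm_s == pytest.approx(3.5)
        assert s.n == 2

    def test_equal_durations_reduce_to_unweighted_statistics(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0.01, 0.2, size=25)
        s = group_summary([rec(x, 120.0, i) for i, x in enumerate(v)])
        assert s.mean_mm_s == pytest.approx(v.mean())
        assert s.sd_mm_s == pytest.approx(v.std(ddof=1))
        assert s.sem_mm_s == pytest.approx(v.std(ddof=1) / np.sqrt(len(v)))
        assert s.median_mm_s == pytest.approx(np.median(v))

    def test_histogram_covers_all_speeds(self):
        s = group_summary([rec(0.005, 1.0), rec(0.037, 1.0, 1)], bin_width_mm_s=0.01)
        assert s.hist_counts.sum() == 2
        assert s.hist_edges[-1] >= 0.037

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_summary([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(0.0, 1.0),  # speed
                st.floats(1.0, 600.0),  # duration
            ),
            min_size=1,
            max_size=12,
        ),
        split_frac=st.floats(0.05, 0.95),
        idx=st.integers(0, 11),
    )
    def test_split_invariance_of_weighted_mean(self, data, split_frac, idx):
        """Replacing a track by two contiguous sub-tracks must not move the
        duration-weighted group mean: (d1+d2)/(t1+t2) = (v1 t1 + v2 t2)/(t1+t2)."""
        records = [rec(v, d, i) for i, (v, d) in enumerate(data)]
        whole = group_summary(records)
        i = idx % len(records)
        v, d = records[i].speed_mm_s, records[i].duration_s
        d1 = split_frac * d
        # contiguous halves of a constant-speed track share its speed
        halves = [rec(v, d1, 100), rec(v, d - d1, 101)]
        split = group_summary(records[:i] + halves + records[i + 1 :])
        if whole.mean_mm_s > 0:
            assert abs(split.mean_mm_s - whole.mean_mm_s) < 1e-12 * whole.mean_mm_s
        else:
            assert split.mean_mm_s == whole.mean_mm_s

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, scale):
        """Multiplying all coordinates by c multiplies speed, mean, SD and
        SEM by c."""
        t = np.linspace(0.0, 30.0, 31)
        rng = np.random.default_rng(5)
        tracks = [
            make_track(np.cumsum(rng.normal(0, 0.05, 31)),
                       np.cumsum(rng.normal(0, 0.05, 31)), t=t, animal_id=i)
            for i in range(6)
        ]
        base = group_summary([animal_speed(tr) for tr in tracks])
        scaled_tracks = [
            make_track(tr.x_mm * scale, tr.y_mm * scale, t=t, animal_id=tr.animal_id)
            for tr in tracks
        ]
        scaled = group_summary([animal_speed(tr) for tr in scaled_tracks])
        assert scaled.mean_mm_s == pytest.approx(scale * base.mean_mm_s, rel=1e-9)
        assert scaled.sd_mm_s == pytest.approx(scale * base.sd_mm_s, rel=1e-9)
        assert scaled.sem_mm_s == pytest.approx(scale * base.sem_mm_s, rel=1e-9)


def test_parameter_recovery_weighted_mean_within_three_sem(layout):
    """On a noiseless simulated population the weighted mean should sit
    within 3 weighted SEMs of the ground-truth group mean."""
    spec = PopulationSpec(n_animals=200, median_speed_mm_s=0.043)
    tracks = simulate_population(spec, layout, SimConfig(seed=31, duration_s=200.0))
    records = [animal_speed(tr) for tr in tracks]
    s = group_summary(records)
    # population mean of the log-normal speed law
    truth = spec.median_speed_mm_s * np.exp(spec.speed_sigma_log**2 / 2.0)
    assert abs(s.mean_mm_s - truth) < 3.0 * s.sem_mm_s
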