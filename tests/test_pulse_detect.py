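import numpy as np
import pytest

from divpulse.distmodels import DistanceMatrix
from divpulse.errors import BandwidthError, CalibrationError, MappingError
from divpulse.pulse_detect import (
    CalibrationConfig,
    DensityCurve,
    DistanceSample,
    calibrate,
    collect_pairwise_sample,
    find_modes,
    gaussian_kde,
    map_nodes_to_events,
    nrd0_bandwidth,
)
from divpulse.treebuild import BranchingTimes


def _dm(n, rng):
    d = rng.uniform(0.05, 0.6, (n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0)
    return DistanceMatrix([f"t{i}" for i in range(n)], d, np.full((n, n), 100.0))


class TestCollectSample:
    def test_n_choose_two(self, rng):
        s = collect_pairwise_sample(_dm(5, rng))
        assert s.n == 10 and s.scale == "distance"

    def test_exclusion_slices_matrix(self, rng):
        dm = _dm(6, rng)
        s = collect_pairwise_sample(dm, exclude=["t0", "t3"])
        keep = [1, 2, 4, 5]
        expected = dm.d[np.ix_(keep, keep)][np.triu_indices(4, 1)]
        assert np.allclose(np.sort(s.values), np.sort(expected))

    def test_too_few_retained_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 3"):
            collect_pairwise_sample(_dm(5, rng), exclude=["t0", "t1", "t2"])

    def test_unknown_exclusion_rejected(self, rng):
        with pytest.raises(KeyError):
            collect_pairwise_sample(_dm(5, rng), exclude=["zz"])


# the reference values below were produced by R: bw.nrd0(x) and density(x)
# with default settings, for x = (1.0,1.2,2.3,3.1,4.5,2.2,3.3,0.7,2.9,3.8)
R_SAMPLE = np.array([1.0, 1.2, 2.3, 3.1, 4.5, 2.2, 3.3, 0.7, 2.9, 3.8])
R_NRD0 = 0.7122834956
R_POINTS = {  # index (0-based) -> (x, y) of R's 512-point grid
    0: (-1.43685049, 0.0008520379),
    99: (0.12733033, 0.0865203354),
    255: (2.59210010, 0.2578280715),
    399: (4.86727219, 0.0763047600),
    511: (6.63685049, 0.0006502206),
}


class TestGaussianKde:
    def test_bandwidth_rule_matches_r(self):
        assert nrd0_bandwidth(R_SAMPLE) == pytest.approx(R_NRD0, rel=1e-9)

    def test_density_matches_r_defaults(self):
        # shift by +10 so the zero-truncation is inactive and the grid
        # matches R's (translation changes neither bandwidth nor shape)
        curve = gaussian_kde(DistanceSample(R_SAMPLE + 10.0))
        assert curve.h == pytest.approx(R_NRD0, rel=1e-9)
        assert curve.x[0] == pytest.approx(10 - 1.43685049, rel=1e-7)
        assert curve.x[-1] == pytest.approx(10 + 6.63685049, rel=1e-7)
        for i, (x, y) in R_POINTS.items():
            assert curve.x[i] == pytest.approx(10 + x, rel=1e-7)
            assert curve.f[i] == pytest.approx(y, rel=5e-3, abs=1e-5)

    def test_integral_close_to_one(self, rng):
        curve = gaussian_kde(DistanceSample(rng.exponential(0.3, size=200)))
        assert 0.98 <= curve.integral <= 1.0 + 1e-9

    def test_degenerate_sample_with_explicit_h(self):
        curve = gaussian_kde(DistanceSample(np.zeros(50)), bandwidth=0.1)
        ev = find_modes(curve)
        assert len(ev) == 1
        assert ev.events[0].peak == pytest.approx(0.0, abs=curve.delta)
        assert curve.integral == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_sample_without_h_is_an_error(self):
        with pytest.raises(BandwidthError, match="explicit"):
            gaussian_kde(DistanceSample(np.zeros(50)))

    def test_bimodal_mixture_detected(self, rng):
        x = np.concatenate(
            [rng.normal(1.0, 0.05, 50), rng.normal(3.0, 0.05, 50)]
        )
        curve = gaussian_kde(DistanceSample(np.abs(x)))
        ev = find_modes(curve)
        peaks = sorted(e.peak for e in ev.events)
        assert len(ev) == 2
        assert peaks[0] == pytest.approx(1.0, abs=0.15)
        assert peaks[1] == pytest.approx(3.0, abs=0.15)
        # the inter-mode boundary sits near the valley at 2
        assert ev.events[0].lower == pytest.approx(2.0, abs=0.5)

    def test_order_invariance(self, rng):
        v = rng.exponential(1.0, 60)
        c1 = gaussian_kde(DistanceSample(v))
        c2 = gaussian_kde(DistanceSample(v[::-1].copy()))
        assert np.allclose(c1.f, c2.f)

    def test_affine_equivariance(self, rng):
        v = rng.exponential(1.0, 60) + 0.5
        c = 3.7
        c1 = gaussian_kde(DistanceSample(v), bandwidth=0.2)
        c2 = gaussian_kde(DistanceSample(c * v), bandwidth=0.2 * c)
        m1 = find_modes(c1).peaks
        m2 = find_modes(c2).peaks
        assert np.allclose(m2, c * m1, rtol=1e-6)


def _curve(f, x0=0.0, dx=1.0, scale="time"):
    f = np.asarray(f, dtype=float)
    x = x0 + dx * np.arange(f.size)
    return DensityCurve(x=x, f=f, h=1.0, n=100, scale=scale)


def _oracle_mode_count(f):
    """Independent enumeration of strict local maxima with plateau collapse."""
    f = np.asarray(f)
    # compress equal runs, track whether ends rise/fall
    vals = [f[0]]
    for v in f[1:]:
        if v != vals[-1]:
            vals.append(v)
    count = 0
    for i, v in enumerate(vals):
        left = i == 0 or vals[i - 1] < v
        right = i == len(vals) - 1 or vals[i + 1] < v
        if left and right:
            count += 1
    return count


class TestFindModes:
    def test_single_gaussian_mode(self):
        x = np.linspace(-4, 4, 301)
        f = np.exp(-0.5 * x * x)
        curve = DensityCurve(x=x, f=f / np.trapezoid(f, x), h=0.5, n=100, scale="distance")
        ev = find_modes(curve)
        assert len(ev) == 1
        assert abs(ev.events[0].peak) <= curve.delta

    def test_monotone_decreasing_peaks_at_left_end(self):
        ev = find_modes(_curve([5, 4, 3, 2, 1]))
        assert len(ev) == 1 and ev.events[0].peak == 0.0

    def test_plateau_collapses_to_midpoint(self):
        ev = find_modes(_curve([1, 2, 3, 3, 3, 2, 1]))
        assert len(ev) == 1
        assert ev.events[0].peak == 3.0  # midpoint of indices 2..4

    def test_mode_count_matches_oracle(self, rng):
        for _ in range(20):
            f = np.abs(rng.normal(size=40)).round(1)  # rounding makes plateaus
            ev = find_modes(_curve(f))
            assert len(ev) == _oracle_mode_count(f)

    def test_intervals_tile_grid(self, rng):
        f = np.abs(rng.normal(size=100)) + 0.1
        ev = find_modes(_curve(f))
        lo = min(e.lower for e in ev.events)
        hi = max(e.upper for e in ev.events)
        assert lo == 0.0 and hi == 99.0
        # consecutive (descending) events share boundaries
        for older, younger in zip(ev.events[:-1], ev.events[1:]):
            assert older.lower == younger.upper


class TestCalibration:
    def test_rate_division_convention(self):
        s = DistanceSample(np.array([0.5437, 0.0]))
        cal = CalibrationConfig(rate=4.6e-3, pairwise_divisor=2)
        t = calibrate(s, cal)
        assert t.scale == "time"
        assert t.values[0] == pytest.approx(59.1, abs=0.01)
        assert t.values[1] == 0.0

    def test_divisor_one_doubles_ages(self):
        s = DistanceSample(np.array([0.5437]))
        t = calibrate(s, CalibrationConfig(rate=4.6e-3, pairwise_divisor=1))
        assert t.values[0] == pytest.approx(118.2, abs=0.05)

    def test_curve_calibration_preserves_mass(self, rng):
        curve = gaussian_kde(DistanceSample(rng.exponential(0.2, 100)))
        t = calibrate(curve, CalibrationConfig(rate=4.6e-3))
        assert t.integral == pytest.approx(curve.integral, rel=1e-9)
        assert t.h == pytest.approx(curve.h / (2 * 4.6e-3))

    def test_named_split_fixed_point(self, rng):
        n = 8
        d = rng.uniform(0.1, 0.2, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        # deepen the split between the two halves
        d[:4, 4:] += 0.4
        d[4:, :4] += 0.4
        dm = DistanceMatrix([f"t{i}" for i in range(n)], d, np.full((n, n), 10.0))
        cal = CalibrationConfig(
            split_taxa=tuple(f"t{i}" for i in range(4)), split_age=56.5
        )
        sample = collect_pairwise_sample(dm)
        t = calibrate(sample, cal, dm=dm)
        cross = dm.d[np.ix_(range(4), range(4, 8))].mean()
        r = cal.resolve_rate(dm=dm)
        assert cross / (2 * r) == pytest.approx(56.5)

    def test_exactly_one_calibration_source(self):
        with pytest.raises(CalibrationError):
            CalibrationConfig(rate=1e-3, split_taxa=("a",), split_age=5.0)
        with pytest.raises(CalibrationError):
            CalibrationConfig()
        with pytest.raises(CalibrationError):
            CalibrationConfig(rate=-1.0)


class TestNodeEventMap:
    def _events(self):
        from divpulse.pulse_detect import Event, EventSet

        return EventSet(
            events=[
                Event(peak=55.0, lower=45.0, upper=70.0, peak_density=0.1),
                Event(peak=30.0, lower=20.0, upper=45.0, peak_density=0.2),
            ],
            scale="time",
            delta=0.1,
            bandwidth=1.0,
        )

    def test_interval_membership(self):
        bt = BranchingTimes(np.array([55.0, 40.0, 30.0, 10.0]), n_tips=5)
        m = map_nodes_to_events(bt, self._events(), delta=0.0)
        assert m.event_counts == [1, 2]
        assert m.n_unassigned == 1
        assert m.shared_counts == [0]

    def test_boundary_node_shared(self):
        bt = BranchingTimes(np.array([45.0, 44.0]), n_tips=3)
        m = map_nodes_to_events(bt, self._events(), delta=0.5)
        assert m.shared_counts == [1]
        assert m.event_counts == [1, 2]  # the 45.0 node counts for both

    def test_empty_event_set_rejected(self):
        from divpulse.pulse_detect import EventSet

        bt = BranchingTimes(np.array([1.0]), n_tips=2)
        with pytest.raises(MappingError):
            map_nodes_to_events(
                bt, EventSet(events=[], scale="time", delta=0.1, bandwidth=1.0)
            )
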