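import numpy as np
import pytest

from shagcarpet.edge_detect import (
    Edge,
    detect_edge,
    detect_edges,
    edge_budget,
    estimate_edge_centers,
    select_edges,
)
from shagcarpet.shag import ShagCarpet
from shagcarpet.simulate import make_ideal_edge_carpet


def _step_carpet(n_rows=200, n_t=100, dt=1.0, step_col=50, tilt_cols=0.0, amp=1.0):
    """Rows step from -amp/2 to +amp/2; row r steps at step_col + tilt."""
    data = np.empty((n_rows, n_t))
    cols = np.arange(n_t)
    for r in range(n_rows):
        c = step_col + tilt_cols * (1.0 - r / (n_rows - 1))
        data[r] = np.where(cols >= c, amp / 2, -amp / 2)
    delays = step_col * dt + tilt_cols * dt * (1.0 - np.arange(n_rows) / (n_rows - 1))
    return ShagCarpet(
        data=data, order=np.arange(n_rows), delays_sorted=delays,
        quality_sorted=np.ones(n_rows), dt=dt,
    )


class TestEdgeBudget:
    def test_paper_configuration(self):
        assert edge_budget(360.0, 0.1) == 36

    def test_arithmetic(self):
        assert edge_budget(100.0, 0.05) == 5

    def test_zero_budget_warns(self):
        with pytest.warns(UserWarning):
            assert edge_budget(10.0, 0.01) == 0

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            edge_budget(0.0, 0.1)


class TestEstimateCenters:
    def test_single_step_center(self):
        carpet = _step_carpet()
        centers = estimate_edge_centers(carpet, 1, "rising")
        assert len(centers) == 1
        assert centers[0] == pytest.approx(50.0, abs=1.5)

    def test_sinusoid_rising_centers(self):
        """A 0.05 Hz global sinusoid over 360 s has 18 rising derivative
        peaks (at the ascending zero crossings), spaced 20 s apart."""
        dt = 0.72
        t = np.arange(int(360 / dt)) * dt
        # quarter-period phase puts all 18 ascending crossings at
        # 10, 30, ..., 350 s, away from the record boundaries
        data = np.tile(np.sin(2 * np.pi * 0.05 * (t - 10.0)), (30, 1))
        carpet = ShagCarpet(
            data=data, order=np.arange(30), delays_sorted=np.zeros(30),
            quality_sorted=np.ones(30), dt=dt,
        )
        centers = estimate_edge_centers(carpet, 36, "rising")
        assert len(centers) == 18
        spacing = np.diff(centers)
        np.testing.assert_allclose(spacing, 20.0, atol=2 * dt)

    def test_flat_carpet_empty(self):
        carpet = ShagCarpet(
            data=np.zeros((10, 50)), order=np.arange(10),
            delays_sorted=np.zeros(10), quality_sorted=np.ones(10), dt=1.0,
        )
        assert len(estimate_edge_centers(carpet, 5, "rising")) == 0


class TestDetectEdge:
    def test_linear_edge_transit_recovered(self):
        """A clean linear rising edge spanning 4.5 s is recovered within
        the TR-sampling error envelope."""
        carpet = make_ideal_edge_carpet(4.5, 0.3, n_rows=500, duration=60.0)
        e = detect_edge(carpet, 30.0, window=10.0, polarity="rising")
        assert e.transit_time == pytest.approx(4.5, abs=0.3)
        assert e.r_squared > 0.99

    def test_vertical_edge_zero_transit(self):
        carpet = _step_carpet()
        e = detect_edge(carpet, 50.0, window=20.0, polarity="rising")
        assert abs(e.transit_time) <= carpet.dt

    def test_opposite_tilt_negative_transit(self):
        """An edge tilted against the sorted-delay direction reads negative."""
        carpet = _step_carpet(tilt_cols=5.0)
        flipped = ShagCarpet(
            data=carpet.data[::-1], order=carpet.order,
            delays_sorted=carpet.delays_sorted,  # keep descending convention
            quality_sorted=carpet.quality_sorted, dt=carpet.dt,
        )
        e_fwd = detect_edge(carpet, 52.0, window=20.0, polarity="rising")
        e_rev = detect_edge(flipped, 52.0, window=20.0, polarity="rising")
        assert e_fwd.transit_time > 0
        assert e_rev.transit_time < 0
        assert e_rev.transit_time == pytest.approx(-e_fwd.transit_time, abs=2 * carpet.dt)

    def test_translation_equivariance(self):
        """Shifting the carpet in time shifts centers/intercepts, not transits."""
        a = _step_carpet(step_col=40, tilt_cols=6.0)
        b = _step_carpet(step_col=55, tilt_cols=6.0)
        ea = detect_edge(a, 43.0, window=20.0, polarity="rising")
        eb = detect_edge(b, 58.0, window=20.0, polarity="rising")
        assert eb.transit_time == pytest.approx(ea.transit_time, abs=1e-9)
        assert eb.intercept - ea.intercept == pytest.approx(15.0, abs=2 * a.dt)

    def test_row_subsampling_stability(self):
        """Halving the rows of a clean linear edge changes transit < 5%."""
        carpet = make_ideal_edge_carpet(4.5, 0.3, n_rows=800, duration=60.0)
        half = ShagCarpet(
            data=carpet.data[::2], order=carpet.order[::2],
            delays_sorted=carpet.delays_sorted[::2],
            quality_sorted=carpet.quality_sorted[::2], dt=carpet.dt,
        )
        t_full = detect_edge(carpet, 30.0, window=10.0, polarity="rising").transit_time
        t_half = detect_edge(half, 30.0, window=10.0, polarity="rising").transit_time
        assert abs(t_half - t_full) / t_full < 0.05

    def test_window_outside_scan_rejected(self):
        carpet = _step_carpet()
        with pytest.raises(ValueError, match="window"):
            detect_edge(carpet, 2.0, window=20.0, polarity="rising")

    def test_degenerate_window_rejected(self):
        carpet = _step_carpet()
        with pytest.raises(ValueError):
            detect_edge(carpet, 50.0, window=1.0, polarity="rising")

    def test_oracle_equivalence_breakpoint_fit(self):
        """Full-algorithm transit equals a direct least-squares fit of the
        known continuous breakpoints, within one sample interval."""
        tr = 0.5
        carpet = make_ideal_edge_carpet(4.5, tr, n_rows=600, duration=60.0)
        e = detect_edge(carpet, 30.0, window=10.0, polarity="rising")
        rows = np.arange(600)
        true_times = carpet.delays_sorted  # step time per row
        slope, _ = np.polyfit(rows, true_times, 1)
        oracle = -slope * (600 - 1)  # descending convention: row 0 latest
        oracle = -oracle if oracle < 0 else oracle
        assert abs(abs(e.transit_time) - abs(oracle)) <= tr

    def test_monotone_noise_degradation(self):
        """Breakpoint-fit R^2 does not improve as noise grows (fixed seeds)."""
        carpet = make_ideal_edge_carpet(4.5, 0.75, n_rows=300, duration=60.0)
        rng = np.random.default_rng(0)
        noise = rng.normal(size=carpet.data.shape)
        r2 = []
        for sd in (0.0, 0.5, 1.0, 2.0):
            noisy = ShagCarpet(
                data=carpet.data + sd * noise, order=carpet.order,
                delays_sorted=carpet.delays_sorted,
                quality_sorted=carpet.quality_sorted, dt=carpet.dt,
            )
            r2.append(detect_edge(noisy, 30.0, window=10.0, polarity="rising").r_squared)
        assert all(b <= a + 0.02 for a, b in zip(r2, r2[1:]))


class TestSelectEdges:
    def _edge(self, center, polarity="rising"):
        return Edge(
            center_time=center, polarity=polarity, rows=np.arange(2),
            times=np.zeros(2), slope=0.0, intercept=0.0, transit_time=1.0,
            r_squared=1.0,
        )

    def test_contrast_floor_excludes(self):
        """An edge with global-signal contrast 0.15 fails the 0.2 floor."""
        dt = 1.0
        t = np.arange(200) * dt
        g = 0.075 * np.sin(2 * np.pi * 0.05 * t)  # peak-to-trough 0.15
        es = select_edges([self._edge(45.0)], g, dt, contrast_floor=0.2, rate_floor=0.0)
        assert not es.edges[0].included
        assert "contrast" in es.edges[0].reason

    def test_strong_edge_included(self):
        dt = 1.0
        t = np.arange(200) * dt
        g = 0.5 * np.sin(2 * np.pi * 0.05 * t)  # contrast 1.0
        es = select_edges([self._edge(45.0)], g, dt, contrast_floor=0.2, rate_floor=0.0)
        assert es.edges[0].included

    def test_budget_enforced(self):
        dt = 1.0
        t = np.arange(400) * dt
        g = np.sin(2 * np.pi * 0.05 * t)
        edges = [self._edge(5.0 + 20 * k) for k in range(12)]
        es = select_edges(edges, g, dt, contrast_floor=0.0, rate_floor=0.0,
                          edge_budget_n=10)
        assert len(es.included()) <= 10
        assert len(es) == 12

    def test_sorted_by_center_time(self):
        dt = 1.0
        g = np.sin(2 * np.pi * 0.05 * np.arange(300) * dt)
        edges = [self._edge(c) for c in (105.0, 45.0, 85.0)]
        es = select_edges(edges, g, dt, rate_floor=0.0)
        centers = [e.center_time for e in es.edges]
        assert centers == sorted(centers)


class TestDetectEdgesPipeline:
    def test_phantom_edge_count_and_budget(self, rs_carpet):
        carpet, _, _ = rs_carpet
        es = detect_edges(carpet, "rising")
        assert 1 <= len(es.included()) <= edge_budget(360.0, 0.1)

    def test_phantom_transits_near_truth(self, rs_carpet):
        carpet, _, truth = rs_carpet
        es = detect_edges(carpet, "rising")
        tt = es.transit_times()
        assert np.median(tt) == pytest.approx(truth.true_transit_time, abs=0.6)
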