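import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from envsync.classify import (
    ClassifierParams,
    ConfusionCounts,
    MaxPLVPositions,
    assign_zone,
    boundaries,
    classify_abnormal,
    classify_record,
    evaluate_record,
    max_plv_positions,
    metrics,
    sigma_count,
    sweep,
    zone_intervals,
)
from envsync.io import SeizureAnnotation
from envsync.sync import PLVSeries


def _series(values, starts, channel=""):
    return PLVSeries(
        values=np.asarray(values, float),
        window_start_s=np.asarray(starts, float),
        channel=channel,
    )


def _vp(positions):
    pos = np.asarray(positions, float)
    return MaxPLVPositions(pos, [f"ch{i}" for i in range(len(pos))])


class TestMaxPLVPositions:
    def test_single_channel_argmax(self):
        vp = max_plv_positions([_series([0.2, 0.9, 0.4], [0, 5, 10])])
        assert list(vp.positions_s) == [5.0]

    def test_tie_broken_by_earliest_window(self):
        vp = max_plv_positions([_series([0.9, 0.9], [0, 5])])
        assert list(vp.positions_s) == [0.0]

    def test_matches_argmax_oracle_many_channels(self):
        rng = np.random.default_rng(8)
        starts = np.arange(0, 3595, 5.0)
        series = [_series(rng.random(len(starts)), starts, f"c{k}") for k in range(23)]
        vp = max_plv_positions(series)
        expected = [starts[int(np.argmax(s.values))] for s in series]
        assert list(vp.positions_s) == expected

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            max_plv_positions([])
        with pytest.raises(ValueError):
            max_plv_positions([_series([], [])])


class TestBoundaries:
    @pytest.mark.parametrize(
        "positions,rho,mu,lower,upper",
        [
            ([1000], 20, 1000, 800, 1200),
            ([1000], 0, 1000, 1000, 1000),
            ([100, 200, 300, 400], 50, 250, 125, 375),
        ],
    )
    def test_median_and_rho_band(self, positions, rho, mu, lower, upper):
        b = boundaries(_vp(positions), rho)
        assert (b.mu, b.lower, b.upper) == (mu, lower, upper)


class TestClassifyAbnormal:
    def test_worked_example_abnormal(self):
        # 18 of 23 positions inside the band; any sigma below 19 declares abnormal
        inside = np.linspace(900, 1100, 18)
        outside = [100, 200, 3000, 3200, 3400]
        vp = _vp(np.concatenate([inside, outside]))
        b = boundaries(vp, 50)
        abnormal, count = classify_abnormal(vp, b, sigma=18)
        assert count == 18 and abnormal

    def test_worked_example_not_abnormal(self):
        # only 9 of 23 inside: sigma = 10 stays quiet
        inside = np.linspace(1000, 1080, 9)
        outside = np.concatenate([np.linspace(60, 450, 7), np.linspace(2600, 3500, 7)])
        vp = _vp(np.concatenate([inside, outside]))
        b = boundaries(vp, 50)
        abnormal, count = classify_abnormal(vp, b, sigma=10)
        assert count == 9 and not abnormal

    def test_sigma_zero_always_abnormal(self):
        vp = _vp([5000.0])
        abnormal, _ = classify_abnormal(vp, boundaries(vp, 0), sigma=0)
        assert abnormal

    def test_count_shrinks_with_rho(self):
        vp = _vp(np.linspace(100, 3500, 23))
        counts = [classify_abnormal(vp, boundaries(vp, rho), 1)[1] for rho in (80, 40, 20, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_abnormal_monotone_in_sigma(self):
        vp = _vp(np.linspace(100, 3500, 23))
        b = boundaries(vp, 30)
        flags = [classify_abnormal(vp, b, s)[0] for s in range(0, 24)]
        assert flags == sorted(flags, reverse=True)  # True...False, no flip back


class TestSigmaCount:
    @pytest.mark.parametrize(
        "sigma,mode,n,expected",
        [(7, "count", 23, 7), (30, "percent", 23, 7), (10, "percent", 23, 2),
         (50, "percent", 23, 12), (100, "percent", 23, 23)],
    )
    def test_resolution(self, sigma, mode, n, expected):
        assert sigma_count(sigma, mode, n) == expected


class TestZones:
    ann = SeizureAnnotation("r", 2000, 2100)

    @pytest.mark.parametrize(
        "pos,zone",
        [
            (2050, 1), (2000, 1), (2100, 1),
            (1950, 2), (1999.9, 2),
            (1900, 3), (1850, 4), (1790, 5), (1730, 6),
            (1000, 7), (700, 7),
            (699.9, None), (2100.1, None),
        ],
    )
    def test_assignment(self, pos, zone):
        assert assign_zone(pos, self.ann) == zone

    def test_zone7_interval(self):
        z = zone_intervals(self.ann)
        assert z[7] == (700, 1700)

    @given(st.floats(1400, 50000), st.floats(1, 600))
    def test_zones_2_to_7_tile_preictal_span(self, start, length):
        ann = SeizureAnnotation("r", start, start + length)
        z = zone_intervals(ann)
        # contiguity: each zone ends where the previous one starts
        assert z[2][1] == ann.start_s
        for k in range(3, 8):
            assert z[k][1] == z[k - 1][0]
        total = sum(hi - lo for (lo, hi) in (z[k] for k in range(2, 8)))
        assert total == pytest.approx(1300.0)
        # exhaustive probe: every point in the span maps to exactly one zone
        probes = np.linspace(start - 1299.99, start - 0.01, 400)
        zones = np.array([assign_zone(float(p), ann) for p in probes], dtype=float)
        assert not np.isnan(zones).any()
        assert np.all(np.diff(zones) <= 0)  # ordered 7..2 walking forward in time


class TestEvaluateRecord:
    ann = SeizureAnnotation("r", 2000, 2100)

    def test_true_positive_with_zone1_hit(self):
        c, hits = evaluate_record(True, [2050.0], [self.ann])
        assert (c.TP, c.FP, c.TN, c.FN) == (1, 0, 0, 0)
        assert hits == {1: 1}

    def test_true_negative(self):
        c, _ = evaluate_record(False, [], [])
        assert (c.TP, c.FP, c.TN, c.FN) == (0, 0, 1, 0)

    def test_false_positive_without_seizure(self):
        c, _ = evaluate_record(True, [500.0], [])
        assert c.FP == 1 and c.FP_no_seizure == 1

    def test_false_positive_out_of_zone(self):
        c, _ = evaluate_record(True, [100.0], [self.ann])
        assert c.FP == 1 and c.FP_out_of_zone == 1

    def test_false_negative(self):
        c, _ = evaluate_record(False, [2050.0], [self.ann])
        assert c.FN == 1

    def test_zone_filter_restricts_tp(self):
        c, _ = evaluate_record(True, [1950.0], [self.ann], zone_filter=1)
        assert c.FP == 1
        c, _ = evaluate_record(True, [1950.0], [self.ann], zone_filter=2)
        assert c.TP == 1

    @given(
        st.booleans(),
        st.lists(st.floats(0, 4000), max_size=5),
        st.booleans(),
    )
    def test_exactly_one_outcome_per_epoch(self, abnormal, positions, with_seizure):
        anns = [self.ann] if with_seizure else []
        c, _ = evaluate_record(abnormal, positions, anns)
        assert c.TP + c.FP + c.TN + c.FN == 1


class TestMetrics:
    def test_formulas(self):
        m = metrics(ConfusionCounts(TP=3, FN=1, TN=4, FP=1))
        assert m.sensitivity == 0.75
        assert m.specificity == 0.8
        assert m.accuracy == pytest.approx(7 / 9)

    def test_balanced_counts_half_accuracy(self):
        m = metrics(ConfusionCounts(TP=1, TN=1, FP=1, FN=1))
        assert m.accuracy == 0.5

    def test_undefined_ratios_are_nan_not_zero(self):
        m = metrics(ConfusionCounts(TN=5, FP=1))
        assert np.isnan(m.sensitivity)
        assert m.specificity == pytest.approx(5 / 6)


class TestSweep:
    def _records(self):
        rng = np.random.default_rng(12)
        starts = np.arange(0, 3595, 5.0)
        records = []
        for k in range(4):
            anns = [SeizureAnnotation(f"r{k}", 1800, 1890)] if k < 2 else []
            series = []
            for ch in range(8):
                vals = rng.random(len(starts)) * 0.5
                if anns:
                    vals[(starts >= 1800) & (starts <= 1880)] += 0.6
                series.append(_series(vals, starts, f"c{ch}"))
            records.append((f"r{k}", series, anns))
        return records

    def test_single_point_grid_matches_direct_call(self):
        records = self._records()
        rows = sweep(records, [50.0], [20.0], sigma_mode="percent")
        assert len(rows) == 1
        total = ConfusionCounts()
        params = ClassifierParams(rho=20, sigma=50, sigma_mode="percent")
        for rid, series, anns in records:
            _, c = classify_record(rid, series, anns, params)
            total += c
        assert (rows[0]["TP"], rows[0]["FP"], rows[0]["TN"], rows[0]["FN"]) == (
            total.TP, total.FP, total.TN, total.FN,
        )

    def test_grid_order_independence(self):
        records = self._records()
        up = sweep(records, [10, 50, 90], [20, 60], sigma_mode="percent")
        down = sweep(records, [90, 50, 10], [60, 20], sigma_mode="percent")
        assert up == down

    def test_rows_cover_unique_grid_points(self):
        rows = sweep(self._records(), [10, 20], [30, 40], sigma_mode="percent")
        pairs = {(r["rho"], r["sigma"]) for r in rows}
        assert len(pairs) == len(rows) == 4

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep(self._records(), [], [10])
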