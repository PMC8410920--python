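"""Station matching, scoring, summaries and the recovery properties."""

import numpy as np
import pandas as pd
import pytest

from thermidx.pipeline import GridSpec
from thermidx.synth import SynthConfig, generate_forcing, generate_stations
from thermidx.validation import (
    NONRADIATION_INDICES,
    build_pairs,
    export_scores,
    load_stations,
    match_station,
    pair_max_radiation,
    score,
    station_indices,
    summarize,
)


class TestMatchStation:
    def test_station_at_cell_center(self):
        grid = GridSpec.from_bbox(100.0, 101.0, 30.0, 31.0, 0.1)
        assert match_station(30.3, 100.7, grid) == (3, 7)

    def test_corner_tie_toward_lower_index(self):
        grid = GridSpec(lat=np.array([0.0, 1.0]), lon=np.array([0.0, 1.0]))
        assert match_station(0.5, 0.5, grid) == (0, 0)

    def test_matches_brute_force(self):
        grid = GridSpec.from_bbox(100.0, 102.0, 30.0, 32.0, 0.125)
        rng = np.random.default_rng(31)
        for _ in range(50):
            lat = rng.uniform(30.0, 32.0)
            lon = rng.uniform(100.0, 102.0)
            ilat, ilon = match_station(lat, lon, grid)
            d2 = (grid.lat[:, None] - lat) ** 2 + (grid.lon[None, :] - lon) ** 2
            assert (ilat, ilon) == np.unravel_index(np.argmin(d2), d2.shape)

    def test_outside_bbox_raises(self):
        grid = GridSpec.from_bbox(100.0, 101.0, 30.0, 31.0, 0.1)
        with pytest.raises(ValueError):
            match_station(45.0, 100.5, grid)


class TestScore:
    def test_perfect_prediction(self):
        assert score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 0.0)

    def test_constant_offset(self):
        rmse, bias = score([2.0, 3.0], [1.0, 2.0])
        assert (rmse, bias) == (1.0, 1.0)

    def test_cancelling_errors(self):
        rmse, bias = score([2.0, 0.0], [0.0, 2.0])
        assert rmse == pytest.approx(2.0)
        assert bias == pytest.approx(0.0)

    def test_rmse_dominates_bias_and_decomposes(self):
        rng = np.random.default_rng(8)
        pred = rng.normal(1.0, 2.0, 500)
        obs = rng.normal(0.0, 1.0, 500)
        rmse, bias = score(pred, obs)
        assert rmse >= abs(bias)
        var = np.var(pred - obs)
        assert rmse ** 2 == pytest.approx(bias ** 2 + var, rel=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            score([], [])


class TestExclusionRule:
    def test_incomplete_records_dropped(self, tmp_path, synth_cfg, synth_domain):
        import dataclasses
        cfg = dataclasses.replace(synth_cfg, missing_fraction=0.1, seed=77)
        csv = generate_stations(cfg, synth_domain["fine"], tmp_path / "s.csv")
        raw = pd.read_csv(csv)
        kept = load_stations(csv)
        n_incomplete = raw[["Ta", "Td", "Va10", "P"]].isna().any(axis=1).sum()
        assert n_incomplete > 0
        assert len(kept) == len(raw) - n_incomplete
        # ~10% binomial: within 4 sigma of the expectation
        p, n = 0.1, len(raw)
        assert abs(n_incomplete - p * n) < 4 * np.sqrt(n * p * (1 - p))


class TestStationIndices:
    def test_hand_built_record(self):
        from thermidx import indices as idx
        from thermidx.meteo import relative_humidity, vapor_pressure_from_dewpoint, wind_at_height
        rec = pd.DataFrame({"station_id": ["X"], "lat": [30.0], "lon": [100.0],
                            "time": [pd.Timestamp("2018-07-01 06:00")],
                            "Ta": [28.0], "Td": [22.0], "Va10": [3.0], "P": [1013.0]})
        out = station_indices(rec)
        e = vapor_pressure_from_dewpoint(295.15)
        rh = relative_humidity(301.15, 295.15)
        assert out["Humidex"][0] == pytest.approx(28.0 + 0.5555 * (e - 10.0))
        assert out["WBGT"][0] == pytest.approx(0.567 * 28.0 + 0.393 * e + 3.94)
        assert out["AT"][0] == pytest.approx(28.0 + 0.33 * e - 0.7 * 3.0 - 4.0)
        assert out["UTCI2"][0] == pytest.approx(idx.utci(28.0, 0.5, e, 28.0))
        assert out["NET"][0] == pytest.approx(
            idx.net_effective_temperature(28.0, rh, wind_at_height(3.0, 1.2)))


class TestPairMaxRadiation:
    @staticmethod
    def fixture_frames():
        synoptic_times = pd.date_range("2018-07-01", periods=80, freq="3h")
        syn = pd.DataFrame({"station_id": "A", "time": synoptic_times,
                            "Ta": 25.0, "Td": 20.0, "Va10": 2.0, "P": 1013.0})
        syn = syn.drop(index=[4]).reset_index(drop=True)  # 2018-07-01 12:00 missing
        daily = pd.DataFrame({
            "station_id": "A",
            "time_of_max": [f"2018-07-{d:02d} 11:40" for d in range(1, 11)],
            "SR_max": [800.0 + d for d in range(10)]})
        daily.loc[3, "SR_max"] = np.nan  # one incomplete daily record
        return daily, syn

    def test_rounding_rule(self):
        daily, syn = self.fixture_frames()
        out = pair_max_radiation(daily, syn)
        assert (out["synoptic_time"].dt.hour == 12).all()

    def test_hand_counted_survivors(self):
        # 10 daily records - 1 missing SR_max - 1 missing synoptic slot = 8
        daily, syn = self.fixture_frames()
        assert len(pair_max_radiation(daily, syn)) == 8


class TestSummaries:
    def test_single_station_single_month(self, synth_domain):
        pairs = build_pairs(synth_domain["fine"], synth_domain["stations"])
        one = pairs[pairs["station_id"] == pairs["station_id"].iloc[0]]
        tab = summarize(one, by="month")
        assert len(tab) == 1
        assert tab["n_pairs"].iloc[0] == 16  # 2 days x 8 synoptic hours

    def test_yearly_pools_pairs(self):
        rng = np.random.default_rng(5)
        t1 = pd.date_range("2018-01-01", periods=10, freq="3h")
        t2 = pd.date_range("2018-06-01", periods=40, freq="3h")
        times = t1.append(t2)
        obs = rng.normal(0, 1, 50)
        pred = obs + np.concatenate([np.full(10, 3.0), np.full(40, 0.5)])
        pairs = pd.DataFrame({"station_id": "A", "lat": 30.0, "lon": 100.0,
                              "time": times, "index": "Humidex",
                              "obs": obs, "pred": pred})
        year = summarize(pairs, by="year")
        pooled_rmse, pooled_bias = score(pred, obs)
        assert year["Humidex_rmse"].iloc[0] == pytest.approx(pooled_rmse)
        assert year["Humidex_bias"].iloc[0] == pytest.approx(pooled_bias)
        # pooling differs from averaging the monthly RMSEs
        month = summarize(pairs, by="month")
        assert month["Humidex_rmse"].mean() != pytest.approx(pooled_rmse)

    def test_export_layout(self, synth_domain, tmp_path):
        pairs = build_pairs(synth_domain["fine"], synth_domain["stations"])
        paths = export_scores(summarize(pairs, by="month"), tmp_path)
        assert [p.name for p in paths] == ["validation_2018-07.tsv"]
        table = pd.read_csv(paths[0], sep="\t")
        assert {"station_id", "lon", "lat", "n_pairs"} <= set(table.columns)
        assert {f"{n}_rmse" for n in NONRADIATION_INDICES} <= set(table.columns)


class TestRecovery:
    def test_perfect_recovery_zero_noise(self, synth_domain):
        """Noise-free collocated stations reproduce the grid indices exactly."""
        pairs = build_pairs(synth_domain["fine"], synth_domain["stations"])
        for name, sub in pairs.groupby("index"):
            rmse, bias = score(sub["pred"], sub["obs"])
            assert rmse == pytest.approx(0.0, abs=1e-9), name
            assert bias == pytest.approx(0.0, abs=1e-9), name

    def test_noise_propagates_to_humidex_rmse(self, tmp_path):
        """sigma=1 C noise on observed Ta gives Humidex RMSE -> 1 C (unit
        sensitivity) within the 3/sqrt(n) sampling band."""
        cfg = SynthConfig(bbox=(110.0, 112.0, 29.0, 31.0), start="2018-07-01",
                          n_days=4, seed=21, n_stations=25, noise_temperature=1.0)
        paths = generate_forcing(cfg, tmp_path)
        csv = generate_stations(cfg, paths["fine"], tmp_path / "s.csv")
        pairs = build_pairs(paths["fine"], csv)
        hum = pairs[pairs["index"] == "Humidex"]
        rmse, _ = score(hum["pred"], hum["obs"])
        n = len(hum)
        assert n >= 400
        assert abs(rmse - 1.0) <= 3.0 / np.sqrt(n)
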