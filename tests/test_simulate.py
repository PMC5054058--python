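import numpy as np
import pandas as pd
import pytest

from addhrvr import (
    EpisodeSet,
    PersonTruth,
    PlantSpec,
    SimConfig,
    aggregate,
    detect_person,
    evaluate_recovery,
    fit_inverse_model,
    pearson,
    simulate_calibration,
    simulate_dataset,
    simulate_day,
    simulate_reports,
    truth_from_calibration,
    truth_model,
)
from addhrvr.detection import Episode
from addhrvr.simulate import ConfigError


class TestSimulateCalibration:
    def test_determinism(self, sim_cfg):
        a = simulate_calibration(sim_cfg, 5)
        b = simulate_calibration(sim_cfg, 5)
        np.testing.assert_array_equal(a.epochs.rmssd, b.epochs.rmssd)
        np.testing.assert_array_equal(a.epochs.accel, b.epochs.accel)
        assert a.phases == b.phases

    def test_different_seeds_differ(self, sim_cfg):
        a = simulate_calibration(sim_cfg, 5)
        b = simulate_calibration(sim_cfg, 6)
        assert not np.array_equal(a.epochs.rmssd, b.epochs.rmssd)

    def test_noiseless_identifiability(self):
        cfg = SimConfig(epoch_noise_sd=0.0)
        model = fit_inverse_model(simulate_calibration(cfg, 3))
        assert model.b0 == pytest.approx(cfg.true_b0, abs=1e-8)
        assert model.b1 == pytest.approx(cfg.true_b1, abs=1e-8)

    def test_mean_rmssd_in_realistic_band(self, sim_cfg):
        means = [
            simulate_calibration(sim_cfg, s).epochs.rmssd.mean() for s in range(20)
        ]
        assert 30.0 < np.mean(means) < 60.0

    def test_phases_cover_epochs(self, sim_cfg):
        session = simulate_calibration(sim_cfg, 9)
        covered = np.zeros(len(session.epochs), dtype=bool)
        for p in session.phases:
            covered |= session.epochs.restrict(p.start, p.end)
        assert covered.all()
        assert session.has_rest


class TestSimulateDay:
    def test_determinism(self, sim_cfg):
        truth = PersonTruth(b0=21.56, b1=0.471, se=1.8)
        d1, t1 = simulate_day(sim_cfg, truth, 5)
        d2, t2 = simulate_day(sim_cfg, truth, 5)
        np.testing.assert_array_equal(d1.rmssd, d2.rmssd)
        np.testing.assert_array_equal(d1.accel, d2.accel)
        assert t1.plant_windows == t2.plant_windows

    def test_day_length(self, sim_cfg):
        day, _ = simulate_day(sim_cfg, PersonTruth(21.56, 0.471, 1.8), 5)
        assert len(day) == int(sim_cfg.day_hours * 3600 / sim_cfg.epoch_length)

    def test_overlapping_plants_rejected(self):
        cfg = SimConfig(
            plants=[PlantSpec(3.0, 30, 4.0), PlantSpec(3.1, 30, 4.0)]
        )
        with pytest.raises(ConfigError, match="overlap"):
            simulate_day(cfg, PersonTruth(21.56, 0.471, 1.8), 5)

    def test_plant_outside_day_rejected(self):
        cfg = SimConfig(day_hours=2.0, plants=[PlantSpec(3.0, 20, 4.0)])
        with pytest.raises(ConfigError, match="outside"):
            simulate_day(cfg, PersonTruth(21.56, 0.471, 1.8), 5)

    def test_null_condition_produces_no_episodes(self, sim_cfg):
        cfg = SimConfig(plants=[])
        for seed in range(10):
            session = simulate_calibration(cfg, seed)
            truth = truth_from_calibration(session, cfg)
            day, truth_out = simulate_day(cfg, truth, seed)
            episodes, _ = detect_person(truth_model(truth_out, cfg), day)
            assert len(episodes) == 0

    def test_planted_20_epoch_suppression_detected(self):
        cfg = SimConfig(plants=[PlantSpec(3.0, 20, 4.0)])
        hits = 0
        for seed in range(40):
            session = simulate_calibration(cfg, seed)
            truth = truth_from_calibration(session, cfg)
            day, truth_out = simulate_day(cfg, truth, seed)
            episodes, hourly = detect_person(truth_model(truth_out, cfg), day)
            rec = evaluate_recovery(truth_out, episodes, hourly)
            hits += rec.sensitivity == 1.0
        assert hits >= 38  # >= 95 %

    def test_short_plant_below_min_run_not_required(self):
        cfg = SimConfig(plants=[PlantSpec(3.0, 10, 6.0)])
        session = simulate_calibration(cfg, 2)
        truth = truth_from_calibration(session, cfg)
        day, truth_out = simulate_day(cfg, truth, 2)
        episodes, _ = detect_person(truth_model(truth_out, cfg), day)
        assert len(episodes) == 0

    def test_missing_rate_invalidates_epochs(self):
        cfg = SimConfig(missing_rate=0.2, plants=[])
        day, _ = simulate_day(cfg, PersonTruth(21.56, 0.471, 1.8), 5)
        frac = 1 - day.valid.mean()
        assert 0.1 < frac < 0.3
        assert np.isnan(day.rmssd[~day.valid]).all()


class TestSimulateReports:
    def test_base_rates_match_marginals(self):
        cfg = SimConfig(plants=[])
        frames = []
        for seed in range(40):
            _, truth = simulate_day(cfg, PersonTruth(21.56, 0.471, 1.8), seed)
            frames.append(simulate_reports(truth, cfg, seed))
        df = pd.concat(frames)
        n = len(df)
        worry = (df["worry_count"] >= 1).mean()
        stress = (df["stress_count"] >= 1).mean()
        assert abs(worry - cfg.worry_p_base) < 4 * np.sqrt(0.163 * 0.837 / n)
        assert abs(stress - cfg.stress_p_base) < 4 * np.sqrt(0.068 * 0.932 / n)

    def test_null_coupling_gives_zero_correlation(self):
        # vary the planted load across persons; with equal coupling
        # probabilities the person-level correlation has mean ~0
        rs = []
        for rep in range(15):
            totals_hrv, totals_worry = [], []
            for i in range(30):
                cfg = SimConfig(
                    worry_p_plant=0.163,
                    worry_p_base=0.163,
                    plants=[PlantSpec(2.0 + 3 * j, 25, 4.0) for j in range(i % 4)],
                )
                seed = rep * 1000 + i
                _, truth = simulate_day(cfg, PersonTruth(21.56, 0.471, 1.8), seed)
                reports = simulate_reports(truth, cfg, seed)
                totals_hrv.append(int(truth.hour_flags.sum()))
                totals_worry.append(int(reports["worry_count"].sum()))
            rs.append(pearson(totals_hrv, totals_worry)[0])
        assert abs(np.mean(rs)) < 0.15

    def test_strong_coupling_recovered(self):
        # vary the planted load across persons so person totals have variance
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            totals_hrv, totals_worry = [], []
            for i in range(40):
                n_plants = i % 4
                cfg = SimConfig(
                    worry_p_plant=0.8,
                    worry_p_base=0.1,
                    plants=[PlantSpec(2.0 + 3 * j, 25, 4.0) for j in range(n_plants)],
                )
                seed = rep * 1000 + i
                _, truth = simulate_day(cfg, PersonTruth(21.56, 0.471, 1.8), seed)
                reports = simulate_reports(truth, cfg, seed)
                totals_hrv.append(int(truth.hour_flags.sum()))
                totals_worry.append(int(reports["worry_count"].sum()))
            r, p = pearson(totals_hrv, totals_worry)
            hits += (r > 0) and (p < 0.05)
        assert hits >= int(0.95 * n_rep)

    def test_reports_have_expected_columns(self, sim_cfg):
        _, truth = simulate_day(sim_cfg, PersonTruth(21.56, 0.471, 1.8), 5)
        df = simulate_reports(truth, sim_cfg, 5)
        assert {"person_id", "hour_end_s", "worry_count", "stress_count"} <= set(df.columns)
        assert len(df) == len(truth.hour_starts)


class TestEvaluateRecovery:
    def _episodes(self, windows, epoch_length=30.0):
        eps = [
            Episode(start_index=a, length=ln, start_time=a * epoch_length)
            for a, ln in windows
        ]
        flags = pd.array([False] * 100, dtype="boolean")
        return EpisodeSet("sim", eps, flags, min_run=1, epoch_length=epoch_length)

    def _truth(self, windows):
        from addhrvr import SyntheticTruth

        hours = np.array([0.0])
        return SyntheticTruth(
            person_id="sim",
            truth=PersonTruth(21.56, 0.471, 1.8),
            plant_windows=windows,
            plant_depths=[4.0] * len(windows),
            hour_starts=hours,
            hour_flags=np.array([bool(windows)]),
        )

    def test_identity(self):
        truth = self._truth([(10, 20)])
        rec = evaluate_recovery(truth, self._episodes([(10, 20)]))
        assert rec.sensitivity == 1.0
        assert rec.precision == 1.0

    def test_nothing_detected(self):
        truth = self._truth([(10, 20)])
        rec = evaluate_recovery(truth, self._episodes([]))
        assert rec.sensitivity == 0.0
        assert rec.precision is None

    def test_half_found(self):
        truth = self._truth([(10, 20), (60, 20)])
        rec = evaluate_recovery(truth, self._episodes([(12, 15)]))
        assert rec.sensitivity == 0.5
        assert rec.precision == 1.0

    def test_grid_mismatch(self):
        truth = self._truth([(10, 20)])
        with pytest.raises(ValueError):
            evaluate_recovery(truth, self._episodes([(10, 20)], epoch_length=60.0))


class TestDatasetPipeline:
    def test_end_to_end_closure(self):
        cfg = SimConfig(n_persons=3, day_hours=6.0, plants=[PlantSpec(2.0, 20, 4.0)])
        persons = simulate_dataset(cfg, seed=7)
        assert len(persons) == 3
        hourly_frames, report_frames = [], []
        for p in persons:
            assert p.model.ok
            episodes, hourly = detect_person(p.model, p.day)
            hourly_frames.append(hourly)
            report_frames.append(p.reports)
        hourly = pd.concat(hourly_frames, ignore_index=True)
        reports = pd.concat(report_frames, ignore_index=True)
        summary = aggregate(hourly, reports)
        assert len(summary) == 3
        assert (summary["total_addhrvr_hours"] >= 0).all()

    def test_dataset_determinism(self):
        cfg = SimConfig(n_persons=2, day_hours=3.0, plants=[])
        a = simulate_dataset(cfg, seed=3)
        b = simulate_dataset(cfg, seed=3)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.day.rmssd, pb.day.rmssd)
            pd.testing.assert_frame_equal(pa.reports, pb.reports)
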