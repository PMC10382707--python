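"""Threshold detection, classification, dB HL, age windows, prevalence."""

import numpy as np
import pytest

from audiogain import audiometry, synth, waveforms
from audiogain.audiometry import (
    ABOVE_MAX,
    EarAudiogram,
    classify_hearing,
    compute_hl_db,
    detect_threshold,
    pooled_noise_sd,
    summarize_by_age_window,
    summarize_prevalence,
)

LEVELS = [float(v) for v in range(0, 100, 10)]


def _series_for_ear(threshold, params, seed=0, k_seed_stride=101):
    series = {}
    noise_sds = []
    ear = synth.EarTruth("left", False, threshold)
    for i, lvl in enumerate(LEVELS):
        sw = synth.synth_sweepset(
            ear, lvl, "ABR", params, np.random.default_rng(seed + i * k_seed_stride)
        )
        filt = waveforms.bandpass_abr(sw)
        noise_sds.append(pooled_noise_sd(filt))
        series[lvl] = waveforms.average_trials(filt)
    return series, float(np.mean(noise_sds))


class TestDetectThreshold:
    def test_zero_noise_exact(self, quiet_params):
        series, _ = _series_for_ear(40.0, quiet_params)
        a = detect_threshold(series)
        assert a.threshold == 40.0

    def test_zero_noise_offgrid_rounds_up(self, quiet_params):
        series, _ = _series_for_ear(43.0, quiet_params)
        a = detect_threshold(series)
        assert a.threshold == 50.0

    def test_pure_noise_above_max(self, quiet_params):
        # Zero-noise, no evoked component at any level (threshold beyond
        # instrument ceiling is emulated by a flat-zero series).
        series = {}
        for lvl in LEVELS:
            n = 272
            t = (np.arange(n) - 80) / quiet_params.fs_hz * 1e3
            series[lvl] = waveforms.Waveform(t, np.zeros(n))
        a = detect_threshold(series)
        assert a.threshold == ABOVE_MAX

    def test_noisy_subthreshold_series_above_max(self):
        # With the pooled noise estimate and calibrated k the detector must
        # not report a threshold from noise alone.
        params = synth.WaveformModelParams(noise_sd_uv=0.5, n_trials=24)
        ear = synth.EarTruth("left", True, 90.0)
        spurious = 0
        for seed in range(20):
            series = {}
            sds = []
            for i, lvl in enumerate(LEVELS[:-1]):  # stay below threshold
                sw = synth.synth_sweepset(
                    ear, lvl, "ABR", params, np.random.default_rng(seed * 37 + i)
                )
                filt = waveforms.bandpass_abr(sw)
                sds.append(pooled_noise_sd(filt))
                series[lvl] = waveforms.average_trials(filt)
            a = detect_threshold(series, k=7.0, noise_sd=float(np.mean(sds)))
            spurious += a.threshold != ABOVE_MAX
        assert spurious == 0

    def test_recovery_monte_carlo_small(self):
        params = synth.WaveformModelParams(noise_sd_uv=0.4, n_trials=32)
        rng = np.random.default_rng(19)
        within = 0
        n_ears = 40
        for _ in range(n_ears):
            thr = rng.uniform(20.0, 60.0)
            series = {}
            sds = []
            ear = synth.EarTruth("left", False, thr)
            for lvl in LEVELS:
                sw = synth.synth_sweepset(
                    ear, lvl, "ABR", params,
                    np.random.default_rng(rng.integers(1 << 31)),
                )
                filt = waveforms.bandpass_abr(sw)
                sds.append(pooled_noise_sd(filt))
                series[lvl] = waveforms.average_trials(filt)
            a = detect_threshold(series, k=7.0, noise_sd=float(np.mean(sds)))
            if a.threshold != ABOVE_MAX and abs(a.threshold - thr) <= 10.0:
                within += 1
        assert within >= int(0.9 * n_ears)

    def test_k_monotonicity(self, quiet_params):
        # Raising k never lowers the detected threshold.
        params = synth.WaveformModelParams(noise_sd_uv=0.3, n_trials=16)
        series, sd = _series_for_ear(35.0, params, seed=5)
        detected = []
        for k in (2.0, 4.0, 7.0, 12.0, 1000.0):
            a = detect_threshold(series, k=k, noise_sd=sd)
            detected.append(
                200.0 if a.threshold == ABOVE_MAX else a.threshold
            )
        assert detected == sorted(detected)

    def test_too_few_levels_rejected(self, quiet_params):
        series, _ = _series_for_ear(40.0, quiet_params)
        sub = {l: series[l] for l in LEVELS[:2]}
        with pytest.raises(ValueError):
            detect_threshold(sub)

    def test_uneven_steps_rejected(self, quiet_params):
        series, _ = _series_for_ear(40.0, quiet_params)
        sub = {l: series[l] for l in (0.0, 10.0, 30.0, 40.0)}
        with pytest.raises(ValueError):
            detect_threshold(sub)

    def test_missing_baseline_rejected(self, quiet_params):
        series = {}
        for lvl in LEVELS:
            n = 200
            t = np.arange(n) / quiet_params.fs_hz * 1e3  # no t < 0 samples
            series[lvl] = waveforms.Waveform(t, np.zeros(n))
        with pytest.raises(ValueError, match="baseline"):
            detect_threshold(series)


def _ear(animal, ear, thr, age=10.0, stim="click"):
    return EarAudiogram(
        animal_id=animal, ear=ear, stimulus=stim, age_weeks=age, threshold=thr
    )


def _wt_cohort(thresholds):
    """One WT animal per two thresholds, ears left/right."""
    records, genos = [], {}
    for i in range(0, len(thresholds), 2):
        aid = f"WT{i:03d}"
        genos[aid] = "WT"
        records.append(_ear(aid, "left", thresholds[i]))
        if i + 1 < len(thresholds):
            records.append(_ear(aid, "right", thresholds[i + 1]))
    return records, genos


class TestClassifyHearing:
    def test_printed_cutoff_rule(self):
        # Two WT ears constructed so mean + 2.5 * SD = 40.88 dB SPL exactly;
        # an ear at 40 is below the cutoff, an ear at 45 above it.
        half = 4.0 / np.sqrt(2.0)  # two-point sample SD = |a-b|/sqrt(2) = 4
        records, genos = _wt_cohort([30.88 - half, 30.88 + half])
        genos["M1"] = "MUT"
        records += [_ear("M1", "left", 40.0), _ear("M1", "right", 45.0)]
        statuses, cutoff = classify_hearing(records, genos)
        assert cutoff == pytest.approx(40.88)
        assert statuses["M1"].ear_impaired == {"left": False, "right": True}
        assert statuses["M1"].category == "monaural_HI"

    def test_strict_inequality_at_cutoff(self):
        # WT ears all equal -> SD 0, cutoff = that value; only strictly
        # higher ears are impaired.
        records, genos = _wt_cohort([40.0, 40.0, 40.0, 40.0])
        genos["M1"] = "MUT"
        genos["M2"] = "MUT"
        records += [
            _ear("M1", "left", 40.0), _ear("M1", "right", 45.0),
            _ear("M2", "left", 40.0), _ear("M2", "right", 40.0),
        ]
        statuses, cutoff = classify_hearing(records, genos)
        assert cutoff == 40.0
        assert statuses["M1"].ear_impaired == {"left": False, "right": True}
        assert statuses["M1"].category == "monaural_HI"
        assert statuses["M2"].category == "normal"

    def test_quadrant_categories(self):
        records, genos = _wt_cohort([30.0, 31.0, 29.0, 30.0])
        cutoff_ref = np.mean([30, 31, 29, 30]) + 2.5 * np.std(
            [30, 31, 29, 30], ddof=1
        )
        genos.update(M1="MUT", M2="MUT", M3="MUT")
        records += [
            _ear("M1", "left", 30.0), _ear("M1", "right", 70.0),   # monaural
            _ear("M2", "left", 70.0), _ear("M2", "right", 75.0),   # binaural
            _ear("M3", "left", 30.0), _ear("M3", "right", 30.0),   # normal
        ]
        statuses, cutoff = classify_hearing(records, genos)
        assert cutoff == pytest.approx(cutoff_ref)
        assert statuses["M1"].category == "monaural_HI"
        assert statuses["M2"].category == "binaural_HI"
        assert statuses["M3"].category == "normal"

    def test_sentinel_counts_as_impaired(self):
        records, genos = _wt_cohort([30.0, 32.0])
        genos["M1"] = "MUT"
        records += [_ear("M1", "left", ABOVE_MAX), _ear("M1", "right", 30.0)]
        statuses, _ = classify_hearing(records, genos)
        assert statuses["M1"].ear_impaired["left"] is True
        assert statuses["M1"].category == "monaural_HI"

    def test_one_eared_animal_partial_flag(self):
        records, genos = _wt_cohort([30.0, 32.0])
        genos["W9"] = "WT"
        records += [_ear("W9", "left", 30.0)]
        statuses, _ = classify_hearing(records, genos)
        assert statuses["W9"].partial is True
        assert statuses["W9"].category == "normal"

    def test_order_invariance(self):
        records, genos = _wt_cohort([28.0, 30.0, 33.0, 35.0])
        genos["M1"] = "MUT"
        records += [_ear("M1", "left", 80.0), _ear("M1", "right", 30.0)]
        s1, c1 = classify_hearing(records, genos)
        s2, c2 = classify_hearing(list(reversed(records)), genos)
        assert c1 == c2
        assert {k: v.category for k, v in s1.items()} == {
            k: v.category for k, v in s2.items()
        }

    def test_monotonicity_raising_threshold(self):
        # With the cutoff fixed by WT ears, raising a mutant ear's threshold
        # never flips it impaired -> unimpaired.
        records, genos = _wt_cohort([30.0, 32.0, 31.0, 29.0])
        genos["M1"] = "MUT"
        base = records + [_ear("M1", "left", 50.0), _ear("M1", "right", 30.0)]
        s_base, _ = classify_hearing(base, genos)
        assert s_base["M1"].ear_impaired["left"] is True
        for higher in (60.0, 75.0, 90.0, ABOVE_MAX):
            rec = records + [_ear("M1", "left", higher), _ear("M1", "right", 30.0)]
            s, _ = classify_hearing(rec, genos)
            assert s["M1"].ear_impaired["left"] is True

    def test_no_wt_ears_rejected(self):
        genos = {"M1": "MUT"}
        records = [_ear("M1", "left", 50.0), _ear("M1", "right", 60.0)]
        with pytest.raises(ValueError):
            classify_hearing(records, genos)


class TestComputeHlDb:
    def test_stated_rule_arithmetic(self):
        assert compute_hl_db([30.0, 40.0], [32.0]) == pytest.approx(8.0)

    def test_wt_at_reference_mean_is_zero(self):
        assert compute_hl_db([35.0, 30.0], [35.0, 35.0]) == pytest.approx(0.0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            compute_hl_db([30.0], [])

    def test_brute_force_cohort_oracle(self):
        # Independent re-implementation from raw per-ear tables.
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_wt, n_mut = rng.integers(3, 8), rng.integers(3, 8)
            wt = rng.uniform(25, 40, size=(n_wt, 2))
            mut = rng.uniform(25, 85, size=(n_mut, 2))
            ref = [max(row) for row in wt]
            ref_mean = sum(ref) / len(ref)
            for row in np.vstack([wt, mut]):
                oracle = max(row) - ref_mean
                assert compute_hl_db(list(row), ref) == pytest.approx(oracle)

    def test_classify_attaches_matching_hl(self):
        records, genos = _wt_cohort([30.0, 40.0, 28.0, 30.0])
        genos["M1"] = "MUT"
        records += [_ear("M1", "left", 70.0), _ear("M1", "right", 30.0)]
        statuses, _ = classify_hearing(records, genos)
        ref = np.mean([40.0, 30.0])  # per-animal maxima of the two WT mice
        assert statuses["M1"].hl_db == pytest.approx(70.0 - ref)


class TestAgeWindows:
    def test_mean_within_window(self):
        records = [
            _ear("A", "left", 30.0, age=4.0),
            _ear("A", "left", 40.0, age=5.0),
        ]
        out = summarize_by_age_window(records)
        assert len(out) == 1
        assert out[0]["mean_threshold_db_spl"] == 35.0
        assert out[0]["window_weeks"] == (3.0, 6.0)
        assert out[0]["longitudinal"] is False

    def test_adult_only_no_young_entry(self):
        records = [_ear("A", "left", 30.0, age=8.0)]
        out = summarize_by_age_window(records)
        assert len(out) == 1
        assert out[0]["window_weeks"] == (6.0, 14.0)

    def test_longitudinal_flag_set(self):
        records = [
            _ear("A", "left", 30.0, age=4.0),
            _ear("A", "left", 35.0, age=8.0),
        ]
        out = summarize_by_age_window(records)
        assert all(r["longitudinal"] for r in out)
        assert len(out) == 2

    def test_sentinel_excluded(self):
        records = [
            _ear("A", "left", 30.0, age=4.0),
            _ear("A", "left", ABOVE_MAX, age=5.0),
        ]
        out = summarize_by_age_window(records)
        assert out[0]["mean_threshold_db_spl"] == 30.0
        assert out[0]["n_sessions"] == 1

    def test_window_edges(self):
        # Age 6.0 belongs to the adult window only; 14.0 is included (closed).
        records = [
            _ear("A", "left", 30.0, age=6.0),
            _ear("A", "left", 40.0, age=14.0),
        ]
        out = summarize_by_age_window(records)
        assert len(out) == 1
        assert out[0]["window_weeks"] == (6.0, 14.0)
        assert out[0]["mean_threshold_db_spl"] == 35.0

    def test_persistent_impairment_recovered(self, quiet_params):
        # Same true threshold at both ages: window means agree exactly in
        # the zero-noise limit.
        params = quiet_params
        ear = synth.EarTruth("left", True, 60.0)
        records = []
        for age in (4.0, 10.0):
            series = {}
            for lvl in LEVELS:
                sw = synth.synth_sweepset(
                    ear, lvl, "ABR", params, np.random.default_rng(0),
                    age_weeks=age,
                )
                series[lvl] = waveforms.average_trials(waveforms.bandpass_abr(sw))
            records.append(
                detect_threshold(series, animal_id="A", ear="left", age_weeks=age)
            )
        out = summarize_by_age_window(records)
        assert len(out) == 2
        assert out[0]["mean_threshold_db_spl"] == out[1]["mean_threshold_db_spl"]


class TestPrevalence:
    @staticmethod
    def _statuses(n_impaired, n_total, genotype="MUT", ears_impaired=1):
        statuses = {}
        for i in range(n_total):
            impaired = i < n_impaired
            flags = {
                "left": impaired,
                "right": impaired and ears_impaired == 2,
            }
            category = (
                "binaural_HI" if all(flags.values())
                else "monaural_HI" if any(flags.values())
                else "normal"
            )
            statuses[f"{genotype}{i:03d}"] = audiometry.HearingStatus(
                animal_id=f"{genotype}{i:03d}",
                genotype=genotype,
                ear_impaired=flags,
                category=category,
                hl_db=0.0,
            )
        return statuses

    def test_animal_level_60_percent(self):
        statuses = self._statuses(15, 25)
        s = summarize_prevalence(statuses)["MUT"]
        assert s.animal_percent == pytest.approx(60.0)

    def test_ear_level_46_percent(self):
        # 23 impaired of 50 measured ears.
        statuses = self._statuses(23, 25)
        # gives 23 impaired ears over 50
        s = summarize_prevalence(statuses)["MUT"]
        assert s.ear_measured == 50
        assert s.ear_impaired == 23
        assert s.ear_percent == pytest.approx(46.0)

    def test_zero_percent_wt(self):
        statuses = self._statuses(0, 25, genotype="WT")
        extra = self._statuses(0, 1, genotype="WTX")
        # 25 two-eared + 1 partial (one-eared) WT animal = 51 ears
        one = list(extra.values())[0]
        one.ear_impaired = {"left": False}
        one.genotype = "WT"
        statuses["WTX000"] = one
        s = summarize_prevalence(statuses)["WT"]
        assert s.ear_measured == 51
        assert s.ear_percent == 0.0
        assert s.animal_percent == 0.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            summarize_prevalence({})

    def test_zero_measured_division_guard(self):
        s = audiometry.PrevalenceSummary("G", 0, 0, 0, 0)
        with pytest.raises(ZeroDivisionError):
            _ = s.ear_percent
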