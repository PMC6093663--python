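import numpy as np
import pytest

from larcfft.errors import DataError
from larcfft.larc_detect import (
    NO_SIGNIFICANT,
    SIGNIFICANT_AND_INDEPENDENT,
    SIGNIFICANT_NOT_INDEPENDENT,
    DetectionConfig,
    PeakEvaluation,
    analyze_recording,
    classify_study,
    find_top_peaks,
)
from larcfft.larc_detect import test_independence as eval_independence
from larcfft.larc_detect import test_significance as eval_significance
from larcfft.preprocess import condition
from larcfft.roi import extract_roi
from larcfft.spectrum import AmplitudeSpectrum, amplitude_spectrum, band_bins
from larcfft.synthgen import LarcSpec, SyntheticSpec, generate_recording

from conftest import make_recording

N = 2048
BINW = 600.0 / N


def spectrum_from_amplitudes(amps, channel="p_ves"):
    amps = np.asarray(amps, dtype=float)
    k = np.arange(amps.size)
    return AmplitudeSpectrum(
        frequencies=k * BINW,
        amplitudes=amps,
        n_samples=N,
        sample_rate=10.0,
        channel_name=channel,
    )


def make_peak(amp, left, right, bin=12):
    """PeakEvaluation with explicit neighbor amplitudes (two per side)."""
    return PeakEvaluation(
        rank=1,
        bin=bin,
        frequency=bin * BINW,
        pves_amplitude=amp,
        neighbors_left=tuple(left),
        neighbors_right=tuple(right),
    )


# ---------------------------------------------------------------------------
# independent brute-force re-evaluation of the published rules


def brute_force_classify(pves_amps, pabd_amps):
    """Literal re-application of every rule from raw spectrum arrays."""
    nb = len(pves_amps)
    band = [k for k in range(1, nb) if 1.75 <= k * BINW <= 6.0]
    # local maxima, plateaus collapsed to their lowest-frequency bin
    maxima = []
    for k in band:
        if k - 1 >= 1 and pves_amps[k - 1] >= pves_amps[k]:
            continue
        j = k + 1
        while j < nb and pves_amps[j] == pves_amps[k]:
            j += 1
        if j < nb and pves_amps[j] >= pves_amps[k]:
            continue
        maxima.append(k)
    maxima.sort(key=lambda k: (-pves_amps[k], k))
    outcomes = []
    for k in maxima[:3]:
        a = pves_amps[k]
        sig = a > 0.45
        left_ok = (k - 1 >= 1 and pves_amps[k - 1] <= 0.8 * a) or (
            k - 2 >= 1 and pves_amps[k - 2] <= 0.6 * a
        )
        right_ok = (k + 1 < nb and pves_amps[k + 1] <= 0.8 * a) or (
            k + 2 < nb and pves_amps[k + 2] <= 0.6 * a
        )
        sig = sig and left_ok and right_ok
        ind = False
        if sig:
            b0 = pabd_amps[k]
            bl = pabd_amps[k - 1] if k - 1 >= 1 else None
            br = pabd_amps[k + 1] if k + 1 < nb else None
            bmax = max(v for v in (b0, bl, br) if v is not None)
            nmax = max((v for v in (bl, br) if v is not None), default=0.0)
            rule_a = a > 1.5 * bmax
            rule_b = b0 < 1.33 * nmax
            rule_c = a > 2.0 * bmax
            ind = (rule_a and rule_b) or rule_c
        outcomes.append((k, sig, ind))
    if any(i for _, _, i in outcomes):
        cat = SIGNIFICANT_AND_INDEPENDENT
    elif any(s for _, s, _ in outcomes):
        cat = SIGNIFICANT_NOT_INDEPENDENT
    else:
        cat = NO_SIGNIFICANT
    return cat, outcomes


# ---------------------------------------------------------------------------


class TestFindTopPeaks:
    def test_single_dominant_bin(self):
        amps = np.zeros(30)
        amps[12] = 2.0
        spec = spectrum_from_amplitudes(amps)
        peaks = find_top_peaks(spec, band_bins(spec))
        assert [p.bin for p in peaks] == [12]

    def test_monotonically_decreasing_band_yields_no_interior_peak(self):
        # enumeration oracle: with amplitudes decreasing across the whole
        # spectrum, no bin exceeds its lower-frequency neighbor
        amps = np.linspace(3.0, 0.1, 30)
        spec = spectrum_from_amplitudes(amps)
        peaks = find_top_peaks(spec, band_bins(spec))
        assert peaks == []

    def test_band_edge_peak_detected_via_out_of_band_neighbors(self):
        amps = np.zeros(30)
        amps[6] = 2.0  # band edge; neighbors 5 and 7 are in-spectrum
        spec = spectrum_from_amplitudes(amps)
        assert [p.bin for p in find_top_peaks(spec, band_bins(spec))] == [6]

    def test_equal_maxima_tie_ranks_lower_frequency_first(self):
        amps = np.zeros(30)
        amps[8] = 2.0
        amps[15] = 2.0
        spec = spectrum_from_amplitudes(amps)
        peaks = find_top_peaks(spec, band_bins(spec))
        assert [p.bin for p in peaks] == [8, 15]
        assert peaks[0].rank == 1

    def test_plateau_counts_once_at_lower_frequency_bin(self):
        amps = np.zeros(30)
        amps[10] = amps[11] = 2.0
        spec = spectrum_from_amplitudes(amps)
        assert [p.bin for p in find_top_peaks(spec, band_bins(spec))] == [10]

    def test_returns_at_most_three_largest(self):
        amps = np.zeros(30)
        for k, a in [(7, 1.0), (10, 3.0), (13, 2.0), (16, 2.5), (19, 0.5)]:
            amps[k] = a
        spec = spectrum_from_amplitudes(amps)
        assert [p.bin for p in find_top_peaks(spec, band_bins(spec))] == [10, 16, 13]


class TestSignificance:
    def test_shallow_neighbors_fail_prominence(self):
        p = make_peak(1.0, [0.9, 0.85], [0.86, 0.9])
        assert not eval_significance(p).significant
        detail = p.criterion_detail["significance"]
        assert detail["amplitude"] and not detail["left_prominence"]

    def test_one_deep_neighbor_per_side_passes(self):
        p = make_peak(1.0, [0.95, 0.5], [0.7, 0.95])
        assert eval_significance(p).significant  # 0.5<=0.6 at d=2 left, 0.7<=0.8 at d=1 right

    def test_amplitude_floor_rejects_sharp_but_small_peak(self):
        p = make_peak(0.40, [0.0, 0.0], [0.0, 0.0])
        assert not eval_significance(p).significant

    def test_threshold_is_strict_inequality(self):
        p = make_peak(0.45, [0.0, 0.0], [0.0, 0.0])
        assert not eval_significance(p).significant

    def test_missing_side_neighbors_fail_that_side(self):
        p = make_peak(1.0, [None, None], [0.0, 0.0])
        assert not eval_significance(p).significant
        assert "left_reason" in p.criterion_detail["significance"]


class TestIndependence:
    def _sig_peak(self, amp):
        p = make_peak(amp, [0.0, 0.0], [0.0, 0.0])
        return eval_significance(p)

    def test_flat_abdominal_spectrum_passes_rules_a_and_b(self):
        pabd = np.zeros(30)
        pabd[11], pabd[12], pabd[13] = 0.9, 1.0, 0.9
        p = eval_independence(self._sig_peak(3.0), spectrum_from_amplitudes(pabd))
        assert p.independent

    def test_sharp_abdominal_peak_blocks_independence(self):
        pabd = np.zeros(30)
        pabd[11], pabd[12], pabd[13] = 0.5, 1.2, 0.5
        p = eval_independence(self._sig_peak(1.9), spectrum_from_amplitudes(pabd))
        assert not p.independent
        d = p.criterion_detail["independence"]
        assert d["rule_a_ratio"] and not d["rule_b_flatness"] and not d["rule_c_dominance"]

    def test_dominance_rule_overrides_abdominal_peak(self):
        pabd = np.zeros(30)
        pabd[11], pabd[12], pabd[13] = 0.5, 1.2, 0.5
        p = eval_independence(self._sig_peak(2.6), spectrum_from_amplitudes(pabd))
        assert p.independent
        assert p.criterion_detail["independence"]["rule_c_dominance"]

    def test_non_significant_peak_is_contract_error(self):
        p = make_peak(0.1, [0.0, 0.0], [0.0, 0.0])
        eval_significance(p)
        with pytest.raises(DataError):
            eval_independence(p, spectrum_from_amplitudes(np.zeros(30)))


class TestClassifyStudy:
    def test_flat_spectra_are_no_significant(self):
        spec = spectrum_from_amplitudes(np.full(30, 0.01))
        res = classify_study(spec, spec)
        assert res.category == NO_SIGNIFICANT
        assert res.slowest_si_frequency is None

    def test_vesical_rhythm_over_flat_abdomen_is_si(self, si_recording):
        res = analyze_recording(si_recording, offsets=[30.0]).results[30.0]
        assert res.category == SIGNIFICANT_AND_INDEPENDENT
        assert res.slowest_si_frequency == pytest.approx(3.0, abs=BINW)
        assert res.slowest_si_model.peak_to_peak == pytest.approx(10.0, rel=0.2)

    def test_translated_rhythm_is_significant_not_independent(
        self, translated_recording
    ):
        res = analyze_recording(translated_recording, offsets=[30.0]).results[30.0]
        assert res.category == SIGNIFICANT_NOT_INDEPENDENT

    def test_slowest_si_frequency_is_minimum_over_independent_peaks(self):
        pves = np.zeros(30)
        pves[9] = 2.0
        pves[17] = 3.0
        res = classify_study(
            spectrum_from_amplitudes(pves), spectrum_from_amplitudes(np.zeros(30))
        )
        assert res.category == SIGNIFICANT_AND_INDEPENDENT
        assert res.slowest_si_frequency == pytest.approx(9 * BINW)
        assert res.slowest_si_model.peak_to_peak == pytest.approx(8.0)


class TestAnalyzeRecording:
    def test_any_offset_flag_is_or_of_per_offset(self, si_recording):
        an = analyze_recording(si_recording)
        assert set(an.results) == {0.0, 30.0, 60.0}
        assert an.any_si == any(r.is_si for r in an.results.values())
        assert an.any_si

    def test_all_category_one_gives_false_flag(self, flat_recording):
        an = analyze_recording(flat_recording)
        assert not an.any_si
        assert all(r.category == NO_SIGNIFICANT for r in an.results.values())

    def test_ineligible_recording_propagates_error(self):
        rec = make_recording(np.zeros(1000))  # 100 s, too short
        with pytest.raises(DataError, match="ineligible"):
            analyze_recording(rec)

    def test_rhythm_stopping_before_void_favors_earlier_roi(self):
        # a near-threshold rhythm that stops 90 s before the void is caught
        # more often by the window ending 60 s before the void
        c0 = c60 = 0
        for seed in range(20):
            rec, _ = generate_recording(
                SyntheticSpec(
                    noise_sd=1.5,
                    larc=LarcSpec(frequency_cpm=3.0, peak_to_peak=3.0, stop_s=430.0),
                    seed=seed,
                )
            )
            an = analyze_recording(rec, offsets=[0.0, 60.0])
            c0 += an.results[0.0].is_si
            c60 += an.results[60.0].is_si
        assert c60 > c0

    def test_determinism_identical_input_identical_result(self, si_recording):
        r1 = analyze_recording(si_recording, offsets=[30.0]).results[30.0]
        r2 = analyze_recording(si_recording, offsets=[30.0]).results[30.0]
        assert r1.category == r2.category
        assert [(p.bin, p.significant, p.independent) for p in r1.peaks] == [
            (p.bin, p.significant, p.independent) for p in r2.peaks
        ]


class TestProperties:
    def test_scaling_rhythm_up_never_flips_si_off(self):
        rng = np.random.default_rng(42)
        n = 6000
        t = np.arange(n) / 10.0
        noise_v = rng.normal(0, 1.0, n)
        noise_a = rng.normal(0, 1.0, n)
        sine = np.sin(2 * np.pi * 3.0 / 60.0 * t)
        voided = np.where(t >= 520, np.minimum((t - 520) * 10, 300.0), 0.0)
        flags = []
        for p2p in [1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0]:
            rec = make_recording(
                10.0 + (p2p / 2) * sine + noise_v,
                p_abd=8.0 + noise_a,
                voided=voided,
            )
            flags.append(analyze_recording(rec, offsets=[30.0]).results[30.0].is_si)
        # monotone on the same noise realization: no True -> False transition
        assert all(b or not a for a, b in zip(flags, flags[1:]))
        assert flags[-1]

    @pytest.mark.parametrize("scenario", ["si", "translated", "none"])
    def test_oracle_equivalence_on_synthetic_fixtures(self, scenario):
        cfg = DetectionConfig()
        for seed in range(15):
            larc = None
            if scenario != "none":
                larc = LarcSpec(
                    frequency_cpm=2.0 + seed * 0.2,
                    peak_to_peak=6.0 + seed * 0.5,
                    channel="vesical" if scenario == "si" else "both",
                )
            rec, _ = generate_recording(
                SyntheticSpec(noise_sd=1.5, larc=larc, seed=100 + seed)
            )
            specs = {}
            for ch in ("p_ves", "p_abd"):
                seg = extract_roi(rec, ch, end_offset_s=30.0)
                specs[ch] = amplitude_spectrum(condition(seg))
            res = classify_study(specs["p_ves"], specs["p_abd"], cfg)
            cat, outcomes = brute_force_classify(
                specs["p_ves"].amplitudes, specs["p_abd"].amplitudes
            )
            assert res.category == cat
            assert [(p.bin, p.significant, p.independent) for p in res.peaks] == outcomes
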