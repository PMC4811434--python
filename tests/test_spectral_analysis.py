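"""Preprocessing, wavelet spectra, modulation indices, statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from oscistim.recording import RawRecording
from oscistim.spectral_analysis import (
    BandDefinition,
    DegenerateStatisticsError,
    NoPeakError,
    compare_states,
    dual_resolution_grid,
    endogenous_band,
    epoch_spectra,
    epoch_spectra_of_recording,
    find_endogenous_peak,
    mi_vs_distance,
    modulation_index,
    morlet_power,
    peak_shift_test,
    preprocess,
    results_table,
    stimulation_band,
)
from oscistim.synthetic_data import make_layout

FS = 800.0


def _rec(data, onsets=(4000,)):
    return RawRecording(data=data, sample_rate=FS, trial_onsets=np.array(onsets))


class TestPreprocess:
    def test_common_average_is_zero(self):
        rng = np.random.default_rng(0)
        rec = _rec(rng.standard_normal((4, 8000)))
        out = preprocess(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10

    def test_line_noise_attenuated_20db(self):
        t = np.arange(16000) / FS
        x = np.sin(2 * np.pi * 60.0 * t)
        rec = _rec(np.vstack([x, -x]))
        out = preprocess(rec)
        atten = np.sqrt((out.data[0] ** 2).mean() / (x**2).mean())
        assert 20 * np.log10(atten) < -20

    def test_common_mode_component_removed_entirely(self):
        t = np.arange(8000) / FS
        common = 3.0 * np.sin(2 * np.pi * 10.0 * t)
        rng = np.random.default_rng(1)
        base = rng.standard_normal((3, 8000))
        rec = _rec(base + common)
        out = preprocess(rec)
        ref = preprocess(_rec(base))
        np.testing.assert_allclose(out.data, ref.data, atol=1e-8)

    def test_single_channel_warns_and_skips_reference(self):
        rec = _rec(np.random.default_rng(2).standard_normal((1, 4000)), onsets=(2000,))
        with pytest.warns(UserWarning, match="single channel"):
            preprocess(rec)


class TestMorlet:
    def test_grid_has_256_frequencies(self):
        grid = dual_resolution_grid()
        assert len(grid) == 256
        assert grid[0] == 0.5 and grid[-1] == 80.0

    def test_pure_tone_peaks_at_its_frequency(self):
        """The peak lands on the tone's grid frequency to within one grid
        step (L2-normalized wavelets carry a ~sigma_f^2/f downward bias,
        one 0.1 Hz step at 10 Hz)."""
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        power, margins = morlet_power(x, FS)
        grid = dual_resolution_grid()
        mean_p = power[:, 2000:6000].mean(axis=1)
        assert grid[np.argmax(mean_p)] == pytest.approx(10.0, abs=0.11)

    def test_power_scales_quadratically_with_amplitude(self):
        t = np.arange(8000) / FS
        grid = np.array([10.0])
        p1, _ = morlet_power(np.sin(2 * np.pi * 10 * t), FS, grid)
        p2, _ = morlet_power(2 * np.sin(2 * np.pi * 10 * t), FS, grid)
        ratio = p2[0, 2000:6000].mean() / p1[0, 2000:6000].mean()
        assert ratio == pytest.approx(4.0, rel=1e-6)

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            morlet_power(np.zeros(1000), FS, np.array([500.0]))


class TestEpochSpectra:
    def test_stationary_signal_gives_matching_epochs(self):
        rng = np.random.default_rng(3)
        t = np.arange(12000) / FS
        x = np.sin(2 * np.pi * 9.0 * t) + 0.1 * rng.standard_normal(12000)
        spec = epoch_spectra_of_recording(_rec(x[None, :]), channel=0)
        band = BandDefinition(9.0, 3.0)
        powers = [spec.band_power(band, e) for e in ("pre", "during", "post")]
        assert max(powers) / min(powers) < 1.10

    def test_mid_trial_tone_concentrates_in_during_epoch(self):
        t = np.arange(12000) / FS
        x = 0.05 * np.random.default_rng(4).standard_normal(12000)
        mid = slice(4000, 8000)
        x[mid] += np.sin(2 * np.pi * 10.0 * t[mid])
        spec = epoch_spectra_of_recording(_rec(x[None, :]), channel=0)
        band = stimulation_band()
        assert spec.band_power(band, "during") > 5 * spec.band_power(band, "pre")

    def test_truncated_trial_raises_with_trial_id(self):
        power = np.zeros((3, 1000))
        margins = np.zeros(3, dtype=int)
        with pytest.raises(ValueError, match="trial 7"):
            epoch_spectra(power, margins, np.array([5.0, 6.0, 7.0]), FS, 100, trial=7)

    def test_epoch_sample_counts(self):
        x = np.random.default_rng(5).standard_normal((1, 12000))
        spec = epoch_spectra_of_recording(_rec(x), channel=0)
        # bookkeeping: the three 5 s epochs tile the 15 s trial
        assert spec.power_pre.shape == spec.power_during.shape == spec.power_post.shape


class TestEndogenousPeak:
    def test_injected_peak_at_7_1(self):
        grid = dual_resolution_grid()
        p = np.ones_like(grid)
        p[np.argmin(np.abs(grid - 7.1))] = 10.0
        spec = _make_spectra(grid, p)
        assert find_endogenous_peak(spec) == pytest.approx(7.1)

    def test_flat_spectrum_raises(self):
        grid = dual_resolution_grid()
        with pytest.raises(NoPeakError):
            find_endogenous_peak(_make_spectra(grid, np.ones_like(grid)))

    def test_tie_resolves_to_lower_frequency(self):
        grid = dual_resolution_grid()
        p = np.ones_like(grid)
        p[np.argmin(np.abs(grid - 7.0))] = 10.0
        p[np.argmin(np.abs(grid - 9.0))] = 10.0
        assert find_endogenous_peak(_make_spectra(grid, p)) == pytest.approx(7.0)


def _make_spectra(grid, p):
    from oscistim.spectral_analysis import EpochSpectra

    return EpochSpectra(
        freqs=grid, power_pre=p, power_during=p.copy(), power_post=p.copy()
    )


class TestModulationIndex:
    @pytest.mark.parametrize(
        "s1,s2,expected", [(2.0, 2.0, 0.0), (0.0, 5.0, 1.0), (3.0, 1.0, -0.5)]
    )
    def test_examples(self, s1, s2, expected):
        assert modulation_index(s1, s2) == pytest.approx(expected)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            modulation_index(0.0, 0.0)

    @given(
        s1=st.floats(0.0, 1e6),
        s2=st.floats(0.0, 1e6),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_antisymmetric(self, s1, s2):
        if s1 + s2 == 0:
            return
        mi = modulation_index(s1, s2)
        assert -1.0 <= mi <= 1.0
        assert modulation_index(s2, s1) == pytest.approx(-mi, abs=1e-12)


class TestStatistics:
    def test_one_sample_t_closed_form(self):
        report = compare_states({"a": np.array([1.0, 2.0, 3.0]), "b": np.array([0.0, 1.0, -1.0])})
        assert report["per_state"]["a"]["t"] == pytest.approx(3.464, abs=1e-3)
        assert report["per_state"]["a"]["p"] == pytest.approx(0.0742, abs=1e-3)

    def test_equal_means_give_zero_two_sample_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 1.0, 4.0])
        report = compare_states({"a": a, "b": b})
        assert report["pairwise"]["a vs b"]["t"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_group_rejected(self):
        with pytest.raises(DegenerateStatisticsError):
            compare_states({"a": np.array([1.0, 1.0, 1.0])})

    def test_detection_power_for_small_positive_shift(self):
        """MIs ~ Normal(0.05, 0.02), n=50: the one-sample test should be
        significant in at least 99% of replicates."""
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(200):
            mis = rng.normal(0.05, 0.02, size=50)
            rep = compare_states({"s": mis})
            hits += rep["per_state"]["s"]["significant"]
        assert hits >= 198

    def test_peak_shift_identity(self):
        peaks = np.array([7.0, 7.2, 7.4, 6.9])
        rep = peak_shift_test(peaks, peaks)
        assert rep["median_shift"] == 0.0

    def test_peak_shift_detects_pure_shift(self):
        rng = np.random.default_rng(13)
        pre = 7.0 + 0.3 * rng.standard_normal(20)
        rep = peak_shift_test(pre, pre + 2.0)
        assert rep["p"] < 0.01
        assert rep["median_shift"] == pytest.approx(2.0, abs=0.3)

    def test_median_arithmetic(self):
        rep = peak_shift_test(
            np.array([8.9, 9.0, 9.1]), np.array([8.9, 9.0, 9.1])
        )
        assert rep["median_pre"] == pytest.approx(9.0)


class TestDistance:
    def test_groups_and_decaying_mi(self):
        layout = make_layout(4, 4, 10.0)
        dist = layout.distances_to_stim()
        rng = np.random.default_rng(6)
        import pandas as pd

        rows = []
        for e, d in enumerate(dist):
            for _ in range(5):
                rows.append(
                    {"electrode": e, "distance_mm": d,
                     "mi": float(np.exp(-d / 10.0) + 0.01 * rng.standard_normal())}
                )
        table = pd.DataFrame(rows)
        rep = mi_vs_distance(table, layout, cutoff_mm=20.0)
        assert rep["near"]["mean"] > rep["far"]["mean"]
        assert rep["comparison"]["p"] < 0.05

    def test_boundary_electrode_is_far(self):
        layout = make_layout(1, 2, 10.0)  # electrodes at 0 and 10 mm; midpoint 5
        import pandas as pd

        table = pd.DataFrame(
            {"electrode": [0, 1], "distance_mm": [5.0, 5.0], "mi": [0.1, 0.2]}
        )
        rep = mi_vs_distance(table, layout, cutoff_mm=5.0)
        assert rep["near"]["n"] == 0 and rep["far"]["n"] == 2

    def test_results_table_carries_distance(self, layout44):
        from oscistim.spectral_analysis import ModulationResult

        res = [ModulationResult(mi=0.1, epoch_pair="pre→during", band=endogenous_band(7.0),
                                electrode=3, trial=0, state="task")]
        table = results_table(res, layout44)
        assert table.loc[0, "distance_mm"] == pytest.approx(
            layout44.distances_to_stim()[3]
        )
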