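"""Preprocessing, wavelet spectra, modulation indices and statistics.

The analysis chain for one stimulation trial: notch out line noise (second
order IIR), re-reference to the common average, convolve with Morlet
wavelets on a dual-resolution frequency grid (0.5-20 Hz in 0.1 Hz steps,
21-80 Hz in 1 Hz steps; 256 frequencies), average wavelet power within the
5 s pre / during / post epochs, and quantify band-power changes with the
modulation index

    MI = (S_b2 - S_b1) / (S_b2 + S_b1)  in [-1, 1],

where S_b1 is mean band power before stimulation and S_b2 during or after.
The endogenous band is 3 Hz wide around the detected pre-stimulation
spectral peak; the stimulation band is 2 Hz wide around 10 Hz. One- and
two-sample t tests summarize MIs per state and between states; a Wilcoxon
rank-sum test compares per-trial peak frequencies; and MIs are compared
between electrodes nearer / farther than 20 mm from the stimulation pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .recording import ElectrodeLayout, RawRecording

DEFAULT_CYCLES = 7.0
#: cap on the per-frequency edge-exclusion margin, seconds
MAX_EDGE_MARGIN_S = 2.0


class NoPeakError(ValueError):
    """No qualifying endogenous spectral peak in the search range."""


class DegenerateStatisticsError(ValueError):
    """A statistical test received a zero-variance or too-small group."""


@dataclass
class BandDefinition:
    """Frequency band: full ``width`` Hz centred on ``center``."""

    center: float
    width: float
    role: str = "endogenous"  # or "stimulation"

    @property
    def lo(self) -> float:
        return self.center - self.width / 2.0

    @property
    def hi(self) -> float:
        return self.center + self.width / 2.0


def stimulation_band(freq: float = 10.0) -> BandDefinition:
    return BandDefinition(center=freq, width=2.0, role="stimulation")


def endogenous_band(peak: float) -> BandDefinition:
    return BandDefinition(center=peak, width=3.0, role="endogenous")


@dataclass
class EpochSpectra:
    """Mean wavelet power per frequency in the pre/during/post epochs."""

    freqs: np.ndarray
    power_pre: np.ndarray
    power_during: np.ndarray
    power_post: np.ndarray
    electrode: int = 0
    trial: int = 0

    def power(self, epoch: str) -> np.ndarray:
        return {"pre": self.power_pre, "during": self.power_during, "post": self.power_post}[epoch]

    def band_power(self, band: BandDefinition, epoch: str) -> float:
        sel = (self.freqs >= band.lo - 1e-9) & (self.freqs <= band.hi + 1e-9)
        if not sel.any():
            raise ValueError("band contains no grid frequencies")
        return float(self.power(epoch)[sel].mean())


@dataclass
class ModulationResult:
    mi: float
    epoch_pair: str  # "pre→during" or "pre→post"
    band: BandDefinition
    electrode: int = 0
    trial: int = 0
    state: str = ""


def dual_resolution_grid() -> np.ndarray:
    """The 256-frequency analysis grid: 0.5-20 Hz @ 0.1, 21-80 Hz @ 1."""
    low = np.round(np.arange(0.5, 20.0 + 1e-9, 0.1), 1)
    high = np.arange(21.0, 80.0 + 1e-9, 1.0)
    return np.concatenate([low, high])


def preprocess(rec: RawRecording, line_freq: float = 60.0, quality: float = 30.0) -> RawRecording:
    """Notch out line noise, then re-reference to the common average.

    The notch is a second-order IIR filter applied forward-backward (zero
    phase). With a single channel the common-average step is skipped with
    a warning.
    """
    b, a = sps.iirnotch(line_freq, quality, fs=rec.sample_rate)
    data = sps.filtfilt(b, a, rec.data, axis=1)
    if rec.n_channels >= 2:
        data = data - data.mean(axis=0, keepdims=True)
    else:
        warnings.warn("single channel: skipping common-average reference")
    return rec.copy_with(data)


def morlet_power(
    x: np.ndarray,
    sample_rate: float,
    freqs: Optional[np.ndarray] = None,
    cycles: float = DEFAULT_CYCLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Time-frequency power of one signal by complex Morlet convolution.

    Returns ``(power, margin_samples)`` where power is (n_freqs, n_times)
    and margin_samples[f] is the per-frequency count of edge samples that
    should be excluded from epoch averages (half the wavelet support,
    capped at 2 s so very low frequencies still contribute to 5 s epochs).

    At the lowest frequencies the cycle count shrinks so the wavelet
    always fits within the signal (a 7-cycle wavelet at 0.5 Hz would
    outlast a 15 s trial).
    """
    from mne.time_frequency import tfr_array_morlet

    if freqs is None:
        freqs = dual_resolution_grid()
    freqs = np.asarray(freqs, dtype=float)
    if freqs.max() >= sample_rate / 2:
        raise ValueError("frequencies must lie below Nyquist")
    x = np.asarray(x, dtype=float)
    # mne's wavelet spans 10 sigma_t = 1.59 * n_cycles / freq seconds
    duration = len(x) / sample_rate
    n_cycles = np.minimum(cycles, 0.6 * freqs * duration)
    # L2-normalized wavelets (the standard convention): note their tone
    # response scales with sigma_t, so a pure tone's measured peak sits
    # ~sigma_f^2/f below the true frequency (one 0.1 Hz grid step at
    # 10 Hz with 7 cycles).
    power = tfr_array_morlet(
        x[None, None, :], sfreq=sample_rate, freqs=freqs, n_cycles=n_cycles,
        output="power", zero_mean=True, verbose="error",
    )[0, 0]
    margins = np.minimum(
        np.ceil(n_cycles / (2.0 * freqs) * sample_rate),
        MAX_EDGE_MARGIN_S * sample_rate,
    ).astype(int)
    return power, margins


def epoch_spectra(
    power: np.ndarray,
    margins: np.ndarray,
    freqs: np.ndarray,
    sample_rate: float,
    onset_sample: int,
    durations: Sequence[float] = (5.0, 5.0, 5.0),
    electrode: int = 0,
    trial: int = 0,
) -> EpochSpectra:
    """Average time-frequency power within the pre/during/post epochs.

    Per frequency, samples within the wavelet margin of an epoch boundary
    are excluded so stimulation-epoch power does not bleed into the
    flanking epochs.
    """
    n_pre = int(round(durations[0] * sample_rate))
    n_dur = int(round(durations[1] * sample_rate))
    n_post = int(round(durations[2] * sample_rate))
    start = onset_sample - n_pre
    bounds = [
        (start, onset_sample),
        (onset_sample, onset_sample + n_dur),
        (onset_sample + n_dur, onset_sample + n_dur + n_post),
    ]
    if start < 0 or bounds[-1][1] > power.shape[1]:
        raise ValueError(
            f"trial {trial}: epochs [{start}, {bounds[-1][1]}) do not fit the recording"
        )
    means = []
    for lo, hi in bounds:
        ep = np.empty(len(freqs))
        for i, m in enumerate(margins):
            a, b = lo + m, hi - m
            if b <= a:  # margin swallowed the epoch; fall back to the full epoch
                a, b = lo, hi
            ep[i] = power[i, a:b].mean()
        means.append(ep)
    return EpochSpectra(
        freqs=np.asarray(freqs, dtype=float),
        power_pre=means[0],
        power_during=means[1],
        power_post=means[2],
        electrode=electrode,
        trial=trial,
    )


def epoch_spectra_of_recording(
    rec: RawRecording,
    channel: int = 0,
    epoch_durations: Sequence[float] = (5.0, 5.0, 5.0),
    freqs: Optional[np.ndarray] = None,
    cycles: float = DEFAULT_CYCLES,
    trial: int = 0,
) -> EpochSpectra:
    """Morlet power + epoch averaging for one channel of one trial."""
    if rec.trial_onsets.size == 0:
        raise ValueError("recording carries no stimulation-onset annotation")
    if freqs is None:
        freqs = dual_resolution_grid()
        freqs = freqs[freqs < rec.sample_rate / 2]
    power, margins = morlet_power(rec.data[channel], rec.sample_rate, freqs, cycles)
    return epoch_spectra(
        power, margins, freqs, rec.sample_rate, int(rec.trial_onsets[0]),
        epoch_durations, electrode=channel, trial=trial,
    )


def average_spectra(spectra: Sequence[EpochSpectra]) -> EpochSpectra:
    """Mean epoch spectra across electrodes (e.g. for peak detection)."""
    if not spectra:
        raise ValueError("no spectra to average")
    return EpochSpectra(
        freqs=spectra[0].freqs,
        power_pre=np.mean([s.power_pre for s in spectra], axis=0),
        power_during=np.mean([s.power_during for s in spectra], axis=0),
        power_post=np.mean([s.power_post for s in spectra], axis=0),
        electrode=-1,
        trial=spectra[0].trial,
    )


def find_endogenous_peak(
    spectrum: EpochSpectra,
    search_range: tuple[float, float] = (3.0, 15.0),
    prominence_factor: float = 1.2,
) -> float:
    """Frequency of the pre-stimulation spectral maximum in the range.

    The maximum must exceed ``prominence_factor`` times the median power of
    the search range, otherwise :class:`NoPeakError` is raised (the trial
    should be excluded). Ties resolve to the lower frequency.
    """
    sel = (spectrum.freqs >= search_range[0]) & (spectrum.freqs <= search_range[1])
    if not sel.any():
        raise NoPeakError("search range contains no grid frequencies")
    p = spectrum.power_pre[sel]
    f = spectrum.freqs[sel]
    imax = int(np.argmax(p))  # argmax returns the first (lowest-frequency) maximum
    if p[imax] <= prominence_factor * np.median(p):
        raise NoPeakError(
            f"no spectral peak above {prominence_factor} x median in "
            f"{search_range[0]}-{search_range[1]} Hz"
        )
    return float(f[imax])


def modulation_index(S_b1: float, S_b2: float) -> float:
    """(S_b2 - S_b1) / (S_b2 + S_b1); powers must be nonnegative, not both 0."""
    if S_b1 < 0 or S_b2 < 0:
        raise ValueError("band powers must be nonnegative")
    denom = S_b1 + S_b2
    if denom == 0:
        raise ValueError("modulation index undefined: both band powers are zero")
    return (S_b2 - S_b1) / denom


def modulation_results(
    spectra: EpochSpectra,
    bands: Sequence[BandDefinition],
    state: str = "",
) -> list[ModulationResult]:
    """MIs of all bands for both epoch pairs of one trial/electrode."""
    out = []
    for band in bands:
        s_pre = spectra.band_power(band, "pre")
        for epoch, label in (("during", "pre→during"), ("post", "pre→post")):
            out.append(
                ModulationResult(
                    mi=modulation_index(s_pre, spectra.band_power(band, epoch)),
                    epoch_pair=label,
                    band=band,
                    electrode=spectra.electrode,
                    trial=spectra.trial,
                    state=state,
                )
            )
    return out


def results_table(results: Sequence[ModulationResult], layout: Optional[ElectrodeLayout] = None) -> pd.DataFrame:
    """Flatten modulation results to a tidy DataFrame (one row per MI)."""
    dist = None
    if layout is not None and layout.stim_pair is not None:
        dist = layout.distances_to_stim()
    rows = []
    for r in results:
        rows.append(
            {
                "state": r.state,
                "epoch_pair": r.epoch_pair,
                "band": r.band.role,
                "band_center": r.band.center,
                "electrode": r.electrode,
                "trial": r.trial,
                "distance_mm": float(dist[r.electrode]) if dist is not None else np.nan,
                "mi": r.mi,
            }
        )
    return pd.DataFrame(rows)


def compare_states(mis_by_state: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """Per-state one-sample t tests vs 0 and pairwise two-sample t tests."""
    report: dict = {"per_state": {}, "pairwise": {}, "alpha": alpha}
    for state, mis in mis_by_state.items():
        mis = np.asarray(mis, dtype=float)
        if len(mis) < 2:
            raise DegenerateStatisticsError(f"state {state!r} has fewer than 2 observations")
        if np.allclose(mis.std(ddof=1), 0):
            raise DegenerateStatisticsError(f"state {state!r} has zero variance")
        t, p = stats.ttest_1samp(mis, 0.0)
        report["per_state"][state] = {
            "n": int(len(mis)),
            "mean": float(mis.mean()),
            "sem": float(stats.sem(mis)),
            "t": float(t),
            "p": float(p),
            "significant": bool(p < alpha),
        }
    states = list(mis_by_state)
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            a, b = states[i], states[j]
            t, p = stats.ttest_ind(mis_by_state[a], mis_by_state[b])
            report["pairwise"][f"{a} vs {b}"] = {
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
    return report


def paired_state_test(mis_a: np.ndarray, mis_b: np.ndarray) -> dict:
    """Paired t test between matched MI samples (alternative reading)."""
    t, p = stats.ttest_rel(mis_a, mis_b)
    return {"t": float(t), "p": float(p), "test": "paired t"}


def peak_shift_test(pre_peaks: np.ndarray, post_peaks: np.ndarray) -> dict:
    """Median per-trial peak frequencies and a two-sided rank-sum test."""
    pre = np.asarray(pre_peaks, dtype=float)
    post = np.asarray(post_peaks, dtype=float)
    if len(pre) < 3 or len(post) < 3:
        raise ValueError("need at least 3 per-trial peaks per group")
    stat, p = stats.ranksums(post, pre)
    return {
        "median_pre": float(np.median(pre)),
        "median_post": float(np.median(post)),
        "median_shift": float(np.median(post) - np.median(pre)),
        "statistic": float(stat),
        "p": float(p),
    }


def mi_vs_distance(
    table: pd.DataFrame, layout: ElectrodeLayout, cutoff_mm: float = 20.0
) -> dict:
    """Compare MIs of electrodes near (< cutoff) vs far (>= cutoff).

    Distance is Euclidean from each electrode to the stimulation-pair
    midpoint; an electrode exactly at the cutoff is assigned "far".
    """
    if layout.stim_pair is None:
        raise ValueError("layout has no stimulation pair")
    df = table.copy()
    if df["distance_mm"].isna().any():
        dist = layout.distances_to_stim()
        df["distance_mm"] = dist[df["electrode"].to_numpy()]
    near = df.loc[df["distance_mm"] < cutoff_mm, "mi"].to_numpy()
    far = df.loc[df["distance_mm"] >= cutoff_mm, "mi"].to_numpy()
    report = {
        "cutoff_mm": cutoff_mm,
        "near": {"n": int(len(near)), "mean": float(np.mean(near)) if len(near) else np.nan,
                 "sem": float(stats.sem(near)) if len(near) > 1 else np.nan},
        "far": {"n": int(len(far)), "mean": float(np.mean(far)) if len(far) else np.nan,
                "sem": float(stats.sem(far)) if len(far) > 1 else np.nan},
    }
    if len(near) >= 2 and len(far) >= 2:
        t, p = stats.ttest_ind(near, far)
        report["comparison"] = {"t": float(t), "p": float(p)}
    else:
        warnings.warn("empty or singleton distance group: comparison skipped")
        report["comparison"] = None
    return report
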