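"""Synthetic multichannel ECoG trials with known ground truth.

Generates 15 s stimulation trials (5 s pre / 5 s stim / 5 s post at 800 Hz)
on a rectangular electrode grid. Each trial combines a state-dependent
alpha-band sinusoid (strongest eyes-closed, intermediate eyes-open,
suppressed during task engagement), 1/f background noise, 60 Hz line noise
and, optionally, stereotyped ~10 ms biphasic stimulation artifacts repeating
at 10 Hz whose amplitude decays exponentially with distance from the
stimulation pair. Clean / artifact-only / contaminated versions are returned
together so artifact-removal performance can be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .recording import ElectrodeLayout, RawRecording

STATES = ("eyes_closed", "eyes_open", "task")


@dataclass
class ArtifactSpec:
    """Stimulation-artifact description.

    ``peak_amplitude`` defaults to 20x the eyes-closed alpha amplitude of
    the default trial config; raw artifact amplitudes relative to signal
    are hardware-dependent, so this is a deliberately large, configurable
    default rather than a measured value.
    """

    pulse_rate: float = 10.0  # Hz
    train_duration: float = 5.0  # s
    waveform_duration: float = 0.010  # s (~10 ms deflection)
    peak_amplitude: float = 400.0  # arbitrary units
    channel_gain_decay_length: float = 10.0  # mm

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0 or self.train_duration <= 0:
            raise ValueError("pulse_rate and train_duration must be positive")
        if self.waveform_duration >= 1.0 / self.pulse_rate:
            raise ValueError("waveform_duration must be much less than the pulse period")
        if self.peak_amplitude < 0 or self.channel_gain_decay_length <= 0:
            raise ValueError("amplitude must be nonnegative, decay length positive")

    @property
    def n_pulses(self) -> int:
        return int(np.floor(self.train_duration * self.pulse_rate))


@dataclass
class SyntheticTrialConfig:
    """Parameters of one synthetic stimulation trial.

    Default state amplitudes (20 / 8 / 2 arbitrary units) encode the
    eyes-closed > eyes-open > task ordering of alpha power; the endogenous
    frequency defaults to 7.1 Hz so that it is distinct from the 10 Hz
    stimulation frequency, as in recordings where the two are separable.
    """

    sample_rate: float = 800.0
    trial_duration: float = 15.0
    pre_duration: float = 5.0
    alpha_freq: float = 7.1
    alpha_amplitude_by_state: dict = field(
        default_factory=lambda: {"eyes_closed": 20.0, "eyes_open": 8.0, "task": 2.0}
    )
    one_over_f_exponent: float = 1.0
    noise_rms: float = 3.0
    line_noise_amp: float = 2.0
    line_freq: float = 60.0
    phase_jitter_sd: float = 0.1  # rad, per-channel alpha phase scatter
    alpha_gain_jitter: float = 0.5  # per-channel alpha amplitude scatter (uniform +-)
    during_alpha_gain: float = 1.0  # alpha amplitude multiplier in the stim epoch
    post_alpha_gain: float = 1.0  # alpha amplitude multiplier after stimulation
    entrained_10hz_amp: float = 0.0  # stimulation-frequency component in the stim epoch
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        amps = self.alpha_amplitude_by_state
        if any(a < 0 for a in amps.values()):
            raise ValueError("state amplitudes must be nonnegative")
        if not (amps["eyes_closed"] >= amps["eyes_open"] >= amps["task"]):
            raise ValueError("state amplitudes must satisfy eyes_closed >= eyes_open >= task")
        if not (0 < self.alpha_freq < self.sample_rate / 2):
            raise ValueError("alpha_freq must lie below Nyquist")
        if self.trial_duration < self.pre_duration + self.artifact.train_duration:
            raise ValueError("trial too short for pre epoch plus stimulation train")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration * self.sample_rate))

    @property
    def stim_onset_sample(self) -> int:
        return int(round(self.pre_duration * self.sample_rate))


@dataclass
class SyntheticTrial:
    """Paired clean / contaminated recordings with artifact ground truth.

    ``true_artifact_times`` are peak-aligned sample indices (at the
    recording's native rate) of each injected artifact.
    """

    clean: RawRecording
    contaminated: RawRecording
    artifact_only: RawRecording
    true_artifact_times: np.ndarray
    config: SyntheticTrialConfig
    state: str = "eyes_closed"


def make_layout(n_rows: int, n_cols: int, spacing: float = 10.0) -> ElectrodeLayout:
    """Rectangular electrode lattice with `spacing` mm between neighbours.

    The stimulation pair defaults to the first two row-adjacent electrodes;
    a degenerate 1x1 grid carries no pair (``stim_pair is None``).
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    positions = np.column_stack([cc.ravel() * spacing, rr.ravel() * spacing])
    labels = [f"G{r + 1:02d}{c + 1:02d}" for r, c in zip(rr.ravel(), cc.ravel())]
    if n_cols >= 2:
        stim_pair: Optional[tuple[int, int]] = (0, 1)
    elif n_rows >= 2:
        stim_pair = (0, 1)  # column grid: first two electrodes are vertical neighbours
    else:
        stim_pair = None
    return ElectrodeLayout(positions=positions, labels=labels, stim_pair=stim_pair, spacing=spacing)


def artifact_waveform(spec: ArtifactSpec, sample_rate: float) -> np.ndarray:
    """One stereotyped biphasic artifact deflection.

    A sharp positive lobe (a cubed half-sine, concentrating the energy in
    a single dominant peak, as real pulse artifacts do) followed by a
    broader, shallower negative recovery lobe; the mean is subtracted so
    the deflection is exactly zero-mean. The maximum absolute value equals
    ``spec.peak_amplitude`` and the waveform is deterministic given the
    spec.
    """
    n = int(round(spec.waveform_duration * sample_rate))
    if n < 4:
        raise ValueError("waveform must span at least 4 samples at this rate")
    phase = np.arange(n) / n
    first = phase < 0.5
    w = np.where(
        first,
        np.sin(2 * np.pi * phase) ** 3,
        -0.6 * np.sin(2 * np.pi * (phase - 0.5)),
    )
    w = w - w.mean()
    peak = np.abs(w).max()
    if peak > 0:
        w = w * (spec.peak_amplitude / peak)
    return w


def inject_artifacts(
    clean: RawRecording, layout: ElectrodeLayout, spec: ArtifactSpec,
    config: Optional[SyntheticTrialConfig] = None, state: str = "eyes_closed",
) -> SyntheticTrial:
    """Add a periodic artifact train to a clean recording.

    Pulses start at the recording's first trial onset and repeat every
    ``1/pulse_rate`` s for ``train_duration`` s. Channel c receives the
    template scaled by exp(-d_c / decay_length) where d_c is its distance
    to the stimulation-pair midpoint.
    """
    if clean.trial_onsets.size == 0:
        raise ValueError("clean recording carries no stimulation-onset annotation")
    onset = int(clean.trial_onsets[0])
    fs = clean.sample_rate
    wave = artifact_waveform(spec, fs)
    n_pulses = spec.n_pulses
    last_start = onset + int(round((n_pulses - 1) / spec.pulse_rate * fs))
    if last_start + len(wave) > clean.n_samples:
        raise ValueError("stimulation train extends past the end of the recording")

    gains = np.exp(-layout.distances_to_stim() / spec.channel_gain_decay_length)
    starts = onset + np.round(np.arange(n_pulses) / spec.pulse_rate * fs).astype(int)
    artifact = np.zeros_like(clean.data)
    for s in starts:
        artifact[:, s : s + len(wave)] += gains[:, None] * wave[None, :]

    peak_offset = int(np.argmax(np.abs(wave)))
    trial_cfg = config if config is not None else SyntheticTrialConfig(
        sample_rate=fs, artifact=spec
    )
    return SyntheticTrial(
        clean=clean,
        contaminated=clean.copy_with(clean.data + artifact),
        artifact_only=clean.copy_with(artifact),
        true_artifact_times=starts + peak_offset,
        config=trial_cfg,
        state=state,
    )


def _one_over_f_noise(rng: np.random.Generator, n: int, exponent: float,
                      sample_rate: float, rms: float) -> np.ndarray:
    """FFT-shaped Gaussian noise with power spectrum proportional to 1/f^exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def generate_clean(
    config: SyntheticTrialConfig, layout: ElectrodeLayout, state: str
) -> RawRecording:
    """Clean (artifact-free) synthetic ECoG for one behavioral state."""
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    n_ch = layout.n_channels
    amp = config.alpha_amplitude_by_state[state]

    phases = rng.normal(0.0, config.phase_jitter_sd, size=n_ch)
    # amplitude topography across the grid: without per-channel amplitude
    # scatter the rhythm is purely common-mode and a common-average
    # reference would cancel it, which no real grid recording shows
    gains = 1.0 + config.alpha_gain_jitter * (2.0 * rng.random(n_ch) - 1.0)
    onset = config.stim_onset_sample
    offset = onset + int(round(config.artifact.train_duration * config.sample_rate))
    envelope = np.ones(n)
    envelope[onset:offset] = config.during_alpha_gain
    envelope[offset:] = config.post_alpha_gain
    alpha = (
        amp * gains[:, None] * envelope[None, :]
        * np.sin(2 * np.pi * config.alpha_freq * t[None, :] + phases[:, None])
    )
    if config.entrained_10hz_amp:
        drive = np.zeros(n)
        drive[onset:offset] = config.entrained_10hz_amp
        alpha = alpha + drive[None, :] * np.sin(
            2 * np.pi * config.artifact.pulse_rate * t[None, :] + phases[:, None]
        )

    noise = np.empty((n_ch, n))
    for c in range(n_ch):
        noise[c] = _one_over_f_noise(
            rng, n, config.one_over_f_exponent, config.sample_rate, config.noise_rms
        )

    line_phase = rng.uniform(0, 2 * np.pi)
    line_gains = config.line_noise_amp * (1.0 + 0.1 * rng.standard_normal(n_ch))
    line = line_gains[:, None] * np.sin(2 * np.pi * config.line_freq * t[None, :] + line_phase)

    return RawRecording(
        data=alpha + noise + line,
        sample_rate=config.sample_rate,
        channel_labels=list(layout.labels),
        layout=layout,
        trial_onsets=np.array([config.stim_onset_sample]),
    )


def generate_trial(
    config: SyntheticTrialConfig, layout: ElectrodeLayout, state: str
) -> SyntheticTrial:
    """Full synthetic trial: clean signal plus injected artifact train."""
    clean = generate_clean(config, layout, state)
    return inject_artifacts(clean, layout, config.artifact, config=config, state=state)
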