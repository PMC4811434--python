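# oscistim

Forward models and analysis tools for **state-dependent modulation of
cortical alpha oscillations by 10 Hz direct cortical stimulation**.

Alpha-band rhythms (~8–13 Hz) are strongest with eyes closed, weaker with
eyes open, and suppressed during task engagement. When a 10 Hz pulse train
is delivered to the cortical surface, its effect depends on that state: a
robust endogenous rhythm masks the drive, an intermediate one is enhanced
at its own frequency, and a suppressed one entrains at the stimulation
frequency. `oscistim` provides, as a single tested package:

- **`static_model`** — a threshold-summation model: a sine-wave
  endogenous oscillation of amplitude *A* plus a pulse-evoked response
  (kernel *f(t) = t·e^{−0.01t}*, t in ms, driven by charge-balanced
  biphasic pulses), included only where the summed waveform exceeds a
  threshold. Output spectra switch from endogenous-dominated to
  stimulation-dominated as *A* falls, and two-parameter strength sweeps
  map the regimes.
- **`network_model`** — N excitatory/inhibitory oscillator pairs with
  sparse random coupling, a delayed thalamo-cortical loop (gain −0.5,
  65 ms) that generates the alpha rhythm, a delayed cortico-cortical loop
  (gain 0.85, 290 ms), state-dependent input, shared-noise
  Euler–Maruyama integration (numba-compiled), and a synthetic ECoG
  defined as the population-average potential.
- **`synthetic_data`** — 800 Hz, 15 s multichannel ECoG trials
  (5 s pre / 5 s stim / 5 s post) on a 10 mm electrode grid with
  state-scaled alpha, 1/f noise, 60 Hz line noise, and ground-truth
  stimulation artifacts (~10 ms biphasic deflections at 10 Hz whose
  amplitude decays with distance from the stimulation pair).
- **`artifact_removal`** — template-matching artifact suppression:
  upsample to 3,200 S/s, detect pulses on the most affected channel by
  robust thresholding, subtract per-event 5-artifact moving-average
  templates (least-squares scaled, edge-continuous) on every channel,
  resample back.
- **`spectral_analysis`** — 60 Hz notch, common-average reference,
  Morlet-wavelet power on a dual-resolution grid (0.5–20 Hz @ 0.1 Hz,
  21–80 Hz @ 1 Hz), epoch averaging, modulation indices
  MI = (S_b2 − S_b1)/(S_b2 + S_b1) in endogenous (peak ± 1.5 Hz) and
  stimulation (10 ± 1 Hz) bands, t-test / rank-sum statistics, and
  near-vs-far (20 mm) electrode comparisons.
- **`pipeline` + `oscistim` CLI** — reproducible study runs with JSON/YAML
  configs and bit-reproducible manifests.

See `docs/methods.md` for model equations, parameter tables, numerical
conventions, and known limitations.

## Worked example

```python
from oscistim.static_model import StaticModelParams, simulate_static, periodogram_peak_freq
from oscistim.synthetic_data import SyntheticTrialConfig, generate_trial, make_layout
from oscistim.artifact_removal import clean_recording
from oscistim.spectral_analysis import (
    preprocess, epoch_spectra_of_recording, average_spectra, find_endogenous_peak,
    endogenous_band, stimulation_band, modulation_index,
)

# 1. Static model: state-dependent entrainment
for state, amp in [("eyes-closed", 5.0), ("task-engaged", 0.2)]:
    p = StaticModelParams(osc_amplitude=amp, stim_strength=1.0)
    peak = periodogram_peak_freq(simulate_static(p).output, p.sample_rate)
    print(f"{state:13s} dominant output frequency: {peak:.1f} Hz")

# 2. Synthetic trial -> artifact removal -> modulation indices
layout = make_layout(4, 4, spacing=10.0)
trial = generate_trial(SyntheticTrialConfig(seed=1, during_alpha_gain=1.5),
                       layout, "eyes_closed")
cleaned, events, qc = clean_recording(trial.contaminated)
print(f"detected {len(events.times)} artifact pulses on reference channel {qc['reference_channel']}")

rec = preprocess(cleaned)
spectra = [epoch_spectra_of_recording(rec, channel=c) for c in range(rec.n_channels)]
spec = average_spectra(spectra)
peak = find_endogenous_peak(spec)
mi_endo = modulation_index(spec.band_power(endogenous_band(peak), "pre"),
                           spec.band_power(endogenous_band(peak), "during"))
mi_stim = modulation_index(spec.band_power(stimulation_band(), "pre"),
                           spec.band_power(stimulation_band(), "during"))
print(f"endogenous peak: {peak:.1f} Hz")
print(f"MI (endogenous band, pre->during): {mi_endo:+.3f}")
print(f"MI (stimulation band, pre->during): {mi_stim:+.3f}")
```

Output:

```
eyes-closed   dominant output frequency: 7.0 Hz
task-engaged  dominant output frequency: 10.0 Hz
detected 50 artifact pulses on reference channel 0
endogenous peak: 7.0 Hz
MI (endogenous band, pre->during): +0.384
MI (stimulation band, pre->during): +0.299
```

Reading the numbers: with a strong 7 Hz oscillation the static model's
output stays at 7 Hz; with a weak one it entrains to the 10 Hz train. All
50 injected artifact pulses are found, and the trial's planted 1.5×
during-stimulation alpha boost is recovered as an endogenous-band MI of
+0.384, matching the analytic (k² − 1)/(k² + 1) = 0.385 for k = 1.5. The
smaller stimulation-band MI reflects spectral leakage of the boosted
7.1 Hz rhythm into the 9–11 Hz band — the trial contains no true 10 Hz
component.

The CLI drives the same machinery:

```bash
oscistim simulate-static --osc-amplitude 0.2 --sweep --out static_out
oscistim simulate-network --state task --seed 1 --out net_out
oscistim generate --state eyes_closed --seed 1 --out trial_1
oscistim clean trial_1 --out trial_1_clean
oscistim analyze --seed 1 --out analysis_out
```

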