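# opmtools

Interference suppression for wearable OPM-MEG recordings.

Optically pumped magnetometers (OPMs) sit directly on the scalp and move
with the head, which makes magnetoencephalography wearable — and makes
interference the central problem. Neural fields are tens to hundreds of
femtotesla; the remnant field inside a shielded room is tens of nanotesla,
so a moving sensor array picks up low-frequency artifacts many orders of
magnitude above the signal, on top of mains harmonics, camera LEDs,
blinks and heartbeats. `opmtools` implements the sensor- and source-level
denoising stages used with such arrays, plus a synthetic session
simulator that provides exact per-component ground truth for validating
every stage.

**Who it is for:** researchers processing wearable-MEG magnetometer data
(or building methods for it) who want each suppression step as a tested,
composable operation rather than a monolithic script.

## What is implemented

* **Motion regression** — windowed multiple linear regression of each
  channel onto the six rigid-body pose parameters
  (tx, ty, tz, pitch, yaw, roll) from motion capture, in overlapping 10 s
  windows blended with a raised-cosine cross-fade.
* **Homogeneous field correction (HFC)** — with `N` the (n×3) matrix of
  sensitive-axis unit normals, interference expressible as a spatially
  constant field `b` appears as `Nb`; the projector
  `P = I − N(NᵀN)⁻¹Nᵀ` removes it exactly while largely preserving
  dipolar brain fields.
* **Synthetic gradiometry** — off-head reference channels, band-split
  (2–20 / 20–80 Hz, zero-phase Butterworth), regressed out of the scalp
  channels in overlapping 100 s windows.
* **Temporal tools** — bidirectional Butterworth filters, windowed
  (robust) polynomial detrending, and spectral interpolation: DFT-domain
  replacement of a narrow band's amplitude by the mean of its flanking
  frequencies, phase preserved.
* **SSP and ICA** — noise-subspace projection from an empty-room
  recording, and FastICA denoising with rule-based or template-based
  component flagging.
* **Dual-source LCMV beamforming** — `W = (LᵀC_r⁻¹L)⁻¹LᵀC_r⁻¹` with
  diagonal loading `C_r = C + λ·(tr C/n)·I` (λ = 0.1 % by default) and a
  joint unit-gain constraint on bilateral correlated sources.
* **Metrics** — Welch amplitude spectral density (fT/√Hz, 10 s Hann
  windows), the shielding factor `Gain = 20·log₁₀(ASD₁/ASD₂)` in dB, and
  the per-second maximum field change.
* **Simulator** — 86-channel dual-axis (or triaxial) scalp arrays with
  reference sensors, Sarvas sphere-model dipole sources (M100-like evoked
  responses, beta-band ERD/PMBR), homogeneous drift, rigid-body motion
  through a remnant field gradient, drifting narrow-band interferers,
  15 fT/√Hz sensor noise, blink/cardiac artifacts — with the emitted
  recording exactly equal to the sum of the stored truth components.

## Worked example

```python
import dataclasses
import numpy as np
from opmtools import (AEFConfig, simulate_evoked_session, regress_motion,
                      apply_hfc, spectral_interpolate, butter_zerophase,
                      welch_asd, gain_db, epoch_by_trigger, evoked_tstats)

cfg = dataclasses.replace(AEFConfig(), n_trials=120, still_until=10.0)
rec, truth = simulate_evoked_session(cfg, seed=5)

proc, _ = regress_motion(rec, truth.motion)          # 6-DOF pose regression
proc = apply_hfc(proc)                               # uniform-field projector
proc = spectral_interpolate(proc, [50, 100, 106, 120])
proc = butter_zerophase(proc, "highpass", 2.0, 5)
proc = butter_zerophase(proc, "lowpass", 40.0, 6)

g = gain_db(welch_asd(rec), welch_asd(proc))
low = welch_asd(rec).freqs < 2.0
print(f"gain below 2 Hz: {np.nanmean(g[:, low]):.1f} dB")

ep = epoch_by_trigger(proc, truth.events, 0.2, 0.5)
t, _ = evoked_tstats(ep)
peak = np.unravel_index(np.nanargmax(np.abs(t)), t.shape)
print(f"peak |t| = {abs(t[peak]):.1f} at {ep.times[peak[1]]*1000:.0f} ms")
```

Output:

```
gain below 2 Hz: 112.3 dB
peak |t| = 24.6 at 100 ms
```

The first number is the broadband low-frequency shielding factor of the
combined pipeline (movement artifacts dominate below 2 Hz; the regression
and high-pass remove them). The second shows the auditory evoked response
recovered at its simulated 100 ms latency — on the raw data the same
t-statistics are near zero.

There is also a CLI for shell use:

```bash
opmtools simulate --preset aef --seed 1 --out session/
opmtools psd session/aef_meta.json --window 10 --out psd.tsv
opmtools hfc session/aef_meta.json --out cleaned
opmtools run pipeline.yaml --out rundir/   # full config-driven pipeline
```

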