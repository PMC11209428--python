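# mrcpkit

Analysis toolkit for **movement-related cortical potentials (MRCPs)** — the
slow negative EEG deflection that builds up over the ~2 s before a
self-paced voluntary movement. MRCPs are used to study motor preparation
and as the control signal of movement-intention brain-computer interfaces
(BCIs), where detecting a single pre-movement epoch against resting EEG
estimates online performance.

`mrcpkit` implements the full offline pipeline for a repeated-measures
MRCP study (three sessions of 100 self-paced ankle dorsiflexions with a
synchronized bipolar EMG channel and a 2-min idle recording per session):

* **EMG onset detection** — 20-40 Hz order-4 zero-phase Butterworth,
  full-wave rectification, threshold crossing with a refractory period;
  movement onsets define time zero for all EEG epochs.
* **MRCP morphology** — 0.1-10 Hz filtering, 3-s epochs (−2 to +1 s),
  ±125 µV artifact rejection, pointwise averaging, and the component
  amplitudes RP = mean over [−2, −0.5) s, NS = mean over [−0.5, −0.1) s,
  MP = mean over [−0.1, +0.1] s at Fz, FCz, Cz.
* **Single-trial detection** — 0.1-30 Hz filtering, large Laplacian
  surrogate channel Cz − (F3+Fz+F4+C3+C4+P3+Pz+P4)/8, 29 features per 2-s
  epoch (5 temporal window means, 23 Welch PSD bins at 8-30 Hz, 1
  template cross-correlation), leave-one-out cross-validation with random
  forest (512 trees), LDA, and kNN (k = 5), with per-fold template and
  standardization recomputation.
* **Statistics** — one-way and two-way repeated-measures ANOVA with
  Mauchly's sphericity test, Greenhouse-Geisser correction, partial η²,
  and Bonferroni-corrected paired post hoc t-tests.
* **Synthetic sessions** — a seeded generator producing EEG/EMG sessions
  with known component amplitudes, 1/f noise, alpha/beta rhythms with
  movement-related beta attenuation, blink artifacts, and EMG bursts, so
  every stage is verifiable against ground truth. See `docs/methods.md`.

## Worked example

```python
import numpy as np
from mrcpkit import (SessionConfig, generate_session, auto_threshold,
                     detect_onsets, session_morphology, session_detection,
                     ClassifierSpec)
from mrcpkit.emg import OnsetDetectionParams

cfg = SessionConfig(seed=1)          # 100 movements, study-default SNR
sess = generate_session(cfg)

thr = auto_threshold(sess.emg.data[0], cfg.fs)
onsets = detect_onsets(sess.emg.data[0], cfg.fs,
                       OnsetDetectionParams(threshold=thr))
print(f"threshold {thr:.2f} uV, {len(onsets)} onsets")

comps = session_morphology(sess.eeg, onsets)
for ch in ("Fz", "FCz", "Cz"):
    rp, ns, mp = (comps.values[(ch, c)] for c in ("RP", "NS", "MP"))
    print(f"{ch}: RP {rp:+.1f}  NS {ns:+.1f}  MP {mp:+.1f} uV")

res = session_detection(sess.eeg, sess.idle, onsets,
                        [ClassifierSpec(kind="lda", seed=1)], idle_seed=1)[0]
print(f"LDA LOOCV accuracy: {res.accuracy:.1f}% over {res.n_folds} folds")
```

Output:

```
threshold 1.44 uV, 100 onsets
Fz: RP -1.4  NS -6.3  MP -7.9 uV
FCz: RP -0.4  NS -7.9  MP -10.2 uV
Cz: RP -0.4  NS -8.9  MP -10.9 uV
LDA LOOCV accuracy: 83.5% over 200 folds
```

The recovered amplitudes sit within the noise floor of their configured
values (Fz −1.4/−6.5/−7.9, FCz −0.5/−8.2/−10.3, Cz −0.5/−9.0/−10.8 µV);
the accuracy lands in the ~80% regime the default noise level is
calibrated to.

A full multi-subject study (synthesis → onsets → morphology → detection →
ANOVAs, with all report tables) runs via the library
(`mrcpkit.pipeline.run_study`) or the CLI:

```bash
mrcpkit synth --seed 1 --out session1/
mrcpkit emg-onsets --in session1/emg.edf --out session1/onsets.csv
mrcpkit morphology --eeg session1/eeg.edf --onsets session1/onsets.csv --out components.csv
mrcpkit detect --eeg session1/eeg.edf --idle session1/idle.edf \
               --onsets session1/onsets.csv --classifier lda --out accuracy.csv
mrcpkit run --seed 7 --out study/        # full study, all tables
```

Recordings are stored as 16-bit EDF or as a delimited text format
(bit-exact round-trip); events and result tables are CSV.

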