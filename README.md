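# vagpipe

Filtering and classification of knee-joint vibroarthrographic (VAG)
signals — the acoustic emissions of a knee during flexion-extension — for
screening of cartilage degeneration (healthy control, HC, versus
osteoarthritis, OA).

Raw VAG recordings are nonstationary and heavily contaminated: sensor
noise, skin friction, baseline drift.  `vagpipe` implements a hybrid
pipeline that

1. decomposes each recording into intrinsic mode functions with **ensemble
   empirical mode decomposition** (EEMD):
   x(t) = Σ_j c_j(t) + r(t), with modes averaged over M white-noise-perturbed
   decompositions;
2. scores every mode with **detrended fluctuation analysis** (DFA): the
   scaling exponent α is the log-log slope of the fluctuation function
   F(n) ~ n^α over window lengths n = 50…500;
3. keeps only the modes with **long-range correlation** (0.5 < α < 1) and
   reconstructs the signal from them — a per-recording, data-driven filter
   that discards white/anticorrelated noise (α ≤ 0.5) and drift (α ≥ 1);
4. converts the reconstruction to a **continuous-wavelet scalogram**
   (analytic Morlet, log frequency grid) and trains a small **CNN**
   (conv 10×5×5 stride 2 → ReLU → max-pool → dense → softmax; SGD with
   momentum 0.26, learning rate 10⁻³, L2 0.74, ≤200 epochs, 5 repetitions,
   70/20/10 subject-disjoint split) to classify HC vs OA.

Because clinical recordings are not publicly available, the package
includes generators for exact fractional Gaussian noise (the DFA oracle)
and for labelled VAG-like cohorts, so the full pipeline runs and is tested
end-to-end on synthetic data.  See `docs/methods.md` for the model details
and assumptions.

## Worked example

```python
import numpy as np
from vagpipe import (
    VagSpec, gen_vag, EEMDConfig, filter_recording, dfa_alpha, gen_fgn,
)

# DFA on exact fractional Gaussian noise with Hurst 0.8
res = dfa_alpha(gen_fgn(0.8, 10_000, seed=1))
print(f"alpha = {res.alpha:.3f}  regime = {res.regime.value}")

# EEMD-DFA filtering of a synthetic OA recording (10 cycles, 20 s, 1 kHz)
rec = gen_vag("OA", VagSpec(seed=7))
report = filter_recording(rec, EEMDConfig(ensembles=8, seed=1))
print("per-IMF alpha:", np.round(report.per_imf_alpha, 2))
print("kept modes:   ", np.flatnonzero(report.selected) + 1)
```

prints

```
alpha = 0.763  regime = lrc
per-IMF alpha: [0.37 0.13 0.06 0.66 1.09 1.74 1.96 1.99 2.   2.    nan  nan  nan]
kept modes:    [4]
```

The fGn exponent estimate (0.763) recovers the generating Hurst parameter
0.8 and is classified as long-range correlated.  For the recording, the
fast modes (IMF 1-3, α < 0.5) scale like noise or tremor and the slow
modes (IMF 5+, α ≥ 1) like drift; only IMF 4 — the band where the
crepitus-like transients live — is long-range correlated and enters the
reconstruction.  (`nan` rows are zero-padded trailing modes of the fixed
ensemble budget.)

From the shell, the same stages are available as subcommands:

```sh
vagpipe simulate --n-per-class 50 --seed 7 --out cohort/
vagpipe filter --input cohort/S0000.wav --ensembles 8 --out filtered/
vagpipe dfa --input cohort/S0000.wav --out dfa.json
vagpipe run-all --out results/        # full raw-vs-filtered comparison
```

`run-all` simulates a cohort, runs both classification arms (raw
scalograms vs EEMD-DFA-filtered scalograms) with paired seeds, and writes
`report.json`/`report.csv` with learning/validation/testing accuracies per
arm.

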