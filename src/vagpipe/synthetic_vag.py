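"""Synthetic signal generators: DFA oracles and VAG-like cohorts.

Two families of generators live here.

Exact stochastic oracles
    :func:`gen_fgn` draws fractional Gaussian noise with a prescribed Hurst
    exponent via Davies-Harte circulant embedding (an *exact* method: the
    output has the target autocovariance in distribution), and
    :func:`gen_random_walk` integrates white noise.  Together they probe all
    four DFA scaling regimes with known ground truth.

Vibroarthrographic emulation
    :func:`gen_vag` builds a knee-acoustic-like recording: a 1/f^beta
    coloured background, a cycle-locked load-modulation envelope over each
    ~2 s flexion-extension cycle, Poisson-arriving damped-oscillation bursts
    (joint crepitus), and optional drift/impulse artifacts.  The
    osteoarthritic class phase-locks its bursts to a mid-cycle flexion
    angle (the lesion-contact signature) with strength ``separation``;
    event rate and amplitude are shared between groups, and everything
    else - coupling gain, noise colour, friction artifacts, cycle-locked
    muscle tremor - is class-independent.  The generator targets the
    statistical structure the pipeline exploits (nonstationarity,
    transients, coloured noise, cycle periodicity), not biomechanical
    fidelity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_model import Chain, Group, InvalidInputError, Recording, RecordingMeta, Sensor, write_recording


@dataclass
class VagSpec:
    """Generative parameters for one VAG-like recording.

    Defaults follow the acquisition protocol being emulated: ~2 s per
    flexion-extension cycle, 10 cycles per recording, 1 kHz sampling.
    Both groups share ``burst_rate_hz`` and ``burst_amp``; the OA class
    phase-locks a fraction ``separation`` of its bursts to mid-cycle.
    """

    fs: float = 1000.0
    n_cycles: int = 10
    cycle_s: float = 2.0
    background_beta: float = 0.8
    burst_rate_hz: float = 2.0
    burst_amp: float = 4.0
    burst_damp_s: float = 0.2
    artifact_prob: float = 0.1
    separation: float = 0.5
    seed: int = 0

    #: centre-frequency band of the damped-oscillation bursts, Hz.  Joint
    #: sounds reach a patellar contact microphone through soft tissue that
    #: attenuates high frequencies, so the bursts are slow "thump"-like
    #: events concentrated well below 20 Hz.
    burst_band_hz: tuple[float, float] = (4.0, 8.0)
    #: lognormal sigma of the per-recording sensor-coupling gain (skin
    #: contact varies between subjects, independent of the diagnosis)
    gain_sigma: float = 0.3
    #: high-frequency friction/rubbing artifacts (sensor on skin, clothing):
    #: short broadband transients at 60-240 Hz whose rate and amplitude vary
    #: per recording but are independent of the diagnosis.  ``(lo, hi)``
    #: bounds of the per-recording uniform draws.
    hf_artifact_rate_hz: tuple[float, float] = (1.0, 8.0)
    hf_artifact_amp: tuple[float, float] = (2.0, 6.0)
    #: physiological muscle tremor: a sustained, slowly amplitude-modulated
    #: oscillation at 20-28 Hz whose strength varies per subject but not
    #: with the diagnosis.  As a sustained narrowband process it scales
    #: like anticorrelated noise under DFA and is stripped by the LRC rule,
    #: while in the raw scalogram it lights up rows adjacent to the
    #: crepitus band.
    tremor_amp: tuple[float, float] = (4.0, 8.0)
    tremor_band_hz: tuple[float, float] = (20.0, 28.0)
    #: per-recording jitter of the background spectral slope (subject-to-
    #: subject variation in muscle/ambient noise colour, class-independent)
    background_beta_jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.n_cycles < 1 or self.cycle_s <= 0:
            raise InvalidInputError("n_cycles >= 1 and cycle_s > 0 required")
        if self.burst_rate_hz < 0:
            raise InvalidInputError("burst_rate_hz must be >= 0")
        if not 0 <= self.separation <= 1:
            raise InvalidInputError("separation must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.n_cycles * self.cycle_s * self.fs))


def _next_pow2(n: int) -> int:
    return 1 << (int(n - 1).bit_length())


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of unit-variance fGn: gamma(k) = 0.5(|k+1|^2H - 2|k|^2H + |k-1|^2H)."""
    k = np.abs(lags).astype(float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2.0 * k**h2 + np.abs(k - 1) ** h2)


def gen_fgn(hurst: float, length: int, seed: int = 0) -> np.ndarray:
    """Exact fractional Gaussian noise via circulant embedding.

    The target autocovariance is embedded in a circulant matrix of size 2m
    (m the next power of two >= length) whose eigenvalues are obtained by
    FFT; complex Gaussian variates weighted by the eigenvalue square roots
    synthesise a sequence whose finite-dimensional distributions match fGn
    exactly.  If the embedding is not positive semi-definite (pathological
    H near 1 at short length) the negative eigenvalues are clipped and a
    warning is emitted.
    """
    if not 0 < hurst < 1:
        raise InvalidInputError("hurst must lie in (0, 1)")
    if length < 2:
        raise InvalidInputError("length must be >= 2")
    m = _next_pow2(max(length, 64))
    gamma = fgn_autocovariance(hurst, np.arange(m + 1))
    # first row of the circulant embedding: gamma(0..m), gamma(m-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-10 * lam.max():
        warnings.warn(
            f"circulant embedding not PSD for H={hurst}, length {length}; "
            "clipping negative eigenvalues (approximate synthesis)",
            RuntimeWarning,
        )
    lam = np.clip(lam, 0.0, None)
    rng = np.random.default_rng(seed)
    n2 = 2 * m
    z = rng.standard_normal(n2) + 1j * rng.standard_normal(n2)
    synth = np.fft.fft(np.sqrt(lam / (2.0 * n2)) * z)
    return synth.real[:length] * np.sqrt(2.0)


def gen_random_walk(length: int, seed: int = 0) -> np.ndarray:
    """Cumulative sum of seeded standard Gaussian noise (DFA alpha ~ 1.5)."""
    if length < 2:
        raise InvalidInputError("length must be >= 2")
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.standard_normal(length))


def colored_noise(beta: float, length: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^beta, unit variance."""
    white = rng.standard_normal(length)
    if beta == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(length)
    f[0] = f[1]  # avoid the DC singularity; DC is zeroed below
    spec *= f ** (-beta / 2.0)
    spec[0] = 0.0
    out = np.fft.irfft(spec, n=length)
    sd = out.std()
    return out / sd if sd > 0 else out


def two_tone(
    f1: float = 1.0, f2: float = 10.0, duration_s: float = 10.0, fs: float = 1000.0
) -> np.ndarray:
    """Fixed two-tone EMD probe: sin(2*pi*f1*t) + sin(2*pi*f2*t)."""
    t = np.arange(int(duration_s * fs)) / fs
    return np.sin(2 * np.pi * f1 * t) + np.sin(2 * np.pi * f2 * t)


def _burst_train(
    spec: VagSpec,
    rate_hz: float,
    amp: float,
    rng: np.random.Generator,
    phase_lock: float = 0.0,
) -> np.ndarray:
    """Poisson-arriving tone bursts under the cycle-locked load envelope.

    Each burst is a Gaussian-enveloped oscillation (a smooth grinding
    vibration transmitted through soft tissue, which suppresses any sharp
    attack), so its energy stays spectrally compact around its centre
    frequency instead of leaking into faster modes.
    """
    n = spec.n_samples
    out = np.zeros(n)
    duration = n / spec.fs
    n_bursts = rng.poisson(rate_hz * duration)
    tau = spec.burst_damp_s
    half = int(3 * tau * spec.fs)
    tloc = (np.arange(2 * half + 1) - half) / spec.fs
    gauss = np.exp(-0.5 * (tloc / tau) ** 2)
    for _ in range(n_bursts):
        if rng.uniform() < phase_lock:
            # lesion-contact event: locked to a mid-cycle flexion angle
            k = rng.integers(0, spec.n_cycles)
            start = (k + 0.5 + 0.08 * rng.standard_normal()) * spec.cycle_s
            start = min(max(start, 0.0), duration - 1e-6)
        else:
            start = rng.uniform(0, duration)
        i0 = int(start * spec.fs) - half
        f_c = rng.uniform(spec.burst_band_hz[0], spec.burst_band_hz[1])
        phase = rng.uniform(0, 2 * np.pi)
        a = amp * rng.lognormal(0.0, 0.3)
        # load modulation: bursts strongest mid-cycle
        envelope = 0.2 + 0.8 * np.sin(np.pi * (start % spec.cycle_s) / spec.cycle_s) ** 2
        burst = a * envelope * gauss * np.sin(2 * np.pi * f_c * tloc + phase)
        lo = max(0, i0)
        hi = min(n, i0 + burst.size)
        if hi <= lo:
            continue
        out[lo:hi] += burst[lo - i0 : hi - i0]
    return out


def _tremor(spec: VagSpec, rng: np.random.Generator) -> np.ndarray:
    """Sustained AM-modulated muscle-tremor oscillation, class-independent."""
    n = spec.n_samples
    amp = rng.uniform(*spec.tremor_amp)
    f_t = rng.uniform(*spec.tremor_band_hz)
    t = np.arange(n) / spec.fs
    # slow random amplitude modulation (~0.3 Hz) keeps it quasi-stationary
    am = 1.0 + 0.5 * np.sin(2 * np.pi * rng.uniform(0.2, 0.5) * t + rng.uniform(0, 2 * np.pi))
    # muscle activity also follows the joint load over each cycle
    load = 0.2 + 0.8 * np.sin(np.pi * (t % spec.cycle_s) / spec.cycle_s) ** 2
    return amp * am * load * np.sin(2 * np.pi * f_t * t + rng.uniform(0, 2 * np.pi))


def _hf_artifacts(spec: VagSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-recording friction/rubbing transients, independent of the class."""
    n = spec.n_samples
    out = np.zeros(n)
    rate = rng.uniform(*spec.hf_artifact_rate_hz)
    amp = rng.uniform(*spec.hf_artifact_amp)
    n_events = rng.poisson(rate * n / spec.fs)
    tau = 0.015
    support = int(6 * tau * spec.fs) + 1
    tloc = np.arange(support) / spec.fs
    for _ in range(n_events):
        i0 = rng.integers(0, n)
        f_c = rng.uniform(60.0, 240.0)
        load = 0.2 + 0.8 * np.sin(np.pi * ((i0 / spec.fs) % spec.cycle_s) / spec.cycle_s) ** 2
        burst = amp * load * rng.lognormal(0.0, 0.3) * np.exp(-tloc / tau) * np.sin(
            2 * np.pi * f_c * tloc + rng.uniform(0, 2 * np.pi)
        )
        end = min(n, i0 + support)
        out[i0:end] += burst[: end - i0]
    return out


def gen_vag(group: Group | str, spec: VagSpec | None = None) -> Recording:
    """One synthetic VAG-like recording for the given diagnostic group."""
    spec = spec or VagSpec()
    group = Group(group)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    # class-independent background spectral tilt (subject-specific noise colour)
    beta = spec.background_beta + rng.uniform(-1.0, 1.0) * spec.background_beta_jitter
    background = colored_noise(max(0.0, beta), n, rng)
    # OA crepitus: events phase-locked to the flexion angle of the lesion
    # contact; HC micro-events are uniform in the cycle.  The groups share
    # the event rate and per-event amplitude - the class signature is the
    # timing structure, not the energy.
    lock = spec.separation if group is Group.OA else 0.0
    bursts = _burst_train(spec, spec.burst_rate_hz, spec.burst_amp, rng, phase_lock=lock)
    # sensor-coupling gain scales the whole acoustic path, class-independent
    gain = rng.lognormal(0.0, spec.gain_sigma)
    x = gain * (background + bursts + _tremor(spec, rng) + _hf_artifacts(spec, rng))

    if rng.uniform() < spec.artifact_prob:
        if rng.uniform() < 0.5:
            # slow baseline drift, class-independent
            f_drift = rng.uniform(0.1, 0.4)
            t = np.arange(n) / spec.fs
            x = x + 3.0 * np.sin(2 * np.pi * f_drift * t + rng.uniform(0, 2 * np.pi))
        else:
            # motion impulses
            for _ in range(rng.integers(1, 4)):
                x[rng.integers(0, n)] += rng.choice([-1, 1]) * 8.0

    meta = RecordingMeta(subject_id=f"synthetic-{spec.seed}", group=group)
    return Recording(samples=x, fs=spec.fs, meta=meta)


def gen_cohort(
    n_per_class: int,
    spec: VagSpec | None = None,
    out_dir: str | Path | None = None,
) -> tuple[list[Recording], pd.DataFrame]:
    """Balanced labelled cohort with unique subjects.

    Sensors M1-M3 and chains CKC/OKC are cycled across subjects.  When
    ``out_dir`` is given, each recording is written as WAV and a
    ``manifest.csv`` (path, subject_id, group, sensor, chain) alongside.
    """
    if n_per_class < 1:
        raise InvalidInputError("n_per_class must be >= 1")
    spec = spec or VagSpec()
    master = np.random.SeedSequence(spec.seed)
    seeds = master.generate_state(2 * n_per_class) % (2**31)
    sensors = list(Sensor)
    chains = list(Chain)

    recordings: list[Recording] = []
    rows = []
    idx = 0
    for group in (Group.HC, Group.OA):
        for k in range(n_per_class):
            import dataclasses as _dc

            rec_spec = _dc.replace(spec, seed=int(seeds[idx]))
            rec = gen_vag(group, rec_spec)
            subject = f"S{idx:04d}"
            meta = RecordingMeta(
                subject_id=subject,
                group=group,
                sensor=sensors[idx % len(sensors)],
                chain=chains[(idx // len(sensors)) % len(chains)],
            )
            rec = Recording(samples=rec.samples, fs=rec.fs, meta=meta)
            recordings.append(rec)
            rows.append(
                {
                    "path": f"{subject}.wav",
                    "subject_id": subject,
                    "group": meta.group.value,
                    "sensor": meta.sensor.value,
                    "chain": meta.chain.value,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rec, row in zip(recordings, rows):
            write_recording(rec, out_dir / row["path"])
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return recordings, manifest
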