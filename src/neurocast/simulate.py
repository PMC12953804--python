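"""Synthetic neuromonitoring cohort generation.

Two families of generators live here:

* :func:`generate_arma_series` draws pure ARIMA(p, d, q) realizations with
  known coefficients, used to validate the estimation and forecasting stack
  against theory.
* :func:`generate_patient_waveforms` builds uniform-rate arterial blood
  pressure (ABP), intracranial pressure (ICP) and brain tissue oxygen
  (PbtO2) traces with the spectral structure the downstream analysis
  assumes: a cardiac pulse (with harmonics), a respiratory oscillation,
  slow vasogenic waves in the 0.005-0.05 Hz band, a signed MAP->ICP
  autoregulation coupling, additive Gaussian noise and optional injected
  missingness.

The autoregulation coupling gain ``g`` is the key control: the ICP channel
receives the MAP slow-wave component scaled by ``g``, so the derived
pressure reactivity index (PRx) recovers ``sign(g)`` — positive (impaired
reactivity) or negative (intact reactivity) — through the full derivation
chain.  Real bedside data are far messier; see docs/methods.md for what
this emulation does and does not cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import signal as spsignal

__all__ = [
    "SlowWave",
    "SimulationConfig",
    "WaveformRecord",
    "generate_arma_series",
    "generate_patient_waveforms",
    "inject_missingness",
    "random_gaps",
    "impaired_config",
    "intact_config",
]

SLOW_WAVE_BAND = (0.005, 0.05)

CHANNELS = ("abp", "icp", "pbto2")


@dataclass(frozen=True)
class SlowWave:
    """One sinusoidal slow-wave component.

    frequency : Hz, must lie in the vasogenic band (0.005, 0.05].
    amplitude : mmHg.
    phase : radians; ``None`` means "draw from the seeded RNG".
    """

    frequency: float
    amplitude: float
    phase: Optional[float] = None


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic patient recording.

    Defaults describe a plausibly "impaired autoregulation" adult TBI
    patient: MAP around 90 mmHg, ICP around 12 mmHg, cardiac fundamental
    1.2 Hz (72 bpm, centered on the 0.1 Hz bin grid of a 10-s frame so a
    frame holds a whole number of cycles), respiration at 0.25 Hz, three
    slow waves and a positive MAP->ICP gain.
    """

    sampling_rate: float = 100.0
    duration_minutes: float = 120.0
    map_baseline: float = 90.0
    icp_baseline: float = 12.0
    cardiac_freq: float = 1.2
    resp_freq: float = 0.25
    resp_amplitude: float = 2.0
    slow_wave_components: tuple[SlowWave, ...] = (
        SlowWave(1.0 / 60.0, 3.0),
        SlowWave(0.025, 1.5),
        SlowWave(0.04, 1.0),
    )
    icp_slow_wave: SlowWave = SlowWave(0.02, 1.0)
    autoregulation_gain: float = 1.0
    pulse_pressure: float = 20.0
    icp_pulse_base: float = 2.0
    amp_icp_coupling: float = 0.2
    pbto2_baseline: float = 25.0
    pbto2_cpp_gain: float = 0.3
    pbto2_lag: float = 20.0
    noise_sd: float = 1.0
    drift_sd: float = 0.3
    missing_spec: tuple[tuple[int, int], ...] = ()
    slow_wave_mode: str = "sinusoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration_minutes <= 0:
            raise ValueError("duration must be positive")
        nyquist = self.sampling_rate / 2.0
        for wave in (*self.slow_wave_components, self.icp_slow_wave):
            if not (0.0 < wave.frequency < nyquist):
                raise ValueError(
                    f"slow-wave frequency {wave.frequency} Hz outside (0, {nyquist})"
                )
            if not (SLOW_WAVE_BAND[0] <= wave.frequency <= SLOW_WAVE_BAND[1]):
                raise ValueError(
                    f"slow-wave frequency {wave.frequency} Hz outside the "
                    f"vasogenic band {SLOW_WAVE_BAND}"
                )
        # a 10-s frame must contain a whole number of cardiac cycles so the
        # pulse lands on a DFT bin (no spectral leakage in AMP estimation)
        if abs(self.cardiac_freq / 0.1 - round(self.cardiac_freq / 0.1)) > 1e-9:
            raise ValueError("cardiac_freq must be an integer multiple of 0.1 Hz")
        if self.slow_wave_mode not in ("sinusoid", "filtered_noise"):
            raise ValueError("slow_wave_mode must be 'sinusoid' or 'filtered_noise'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_minutes * 60.0 * self.sampling_rate))


@dataclass
class WaveformRecord:
    """Uniform-rate per-patient monitor traces with per-channel missing masks.

    Masked samples keep their underlying values (the mask is authoritative);
    this avoids sentinel-value ambiguity and lets tests compare against the
    unmasked truth.
    """

    patient_id: str
    sampling_rate: float
    abp: np.ndarray
    icp: np.ndarray
    pbto2: Optional[np.ndarray] = None
    missing_mask: dict[str, np.ndarray] = field(default_factory=dict)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.abp = np.asarray(self.abp, dtype=float)
        self.icp = np.asarray(self.icp, dtype=float)
        if self.pbto2 is not None:
            self.pbto2 = np.asarray(self.pbto2, dtype=float)
        n = len(self.abp)
        if len(self.icp) != n or (self.pbto2 is not None and len(self.pbto2) != n):
            raise ValueError("all channels must have equal length")
        for name in self.channel_names():
            mask = self.missing_mask.get(name)
            if mask is None:
                mask = np.zeros(n, dtype=bool)
            else:
                mask = np.asarray(mask, dtype=bool)
                if len(mask) != n:
                    raise ValueError(f"mask for {name} has wrong length")
            self.missing_mask[name] = mask

    def channel_names(self) -> tuple[str, ...]:
        return ("abp", "icp") if self.pbto2 is None else CHANNELS

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    @property
    def n_samples(self) -> int:
        return len(self.abp)


def _check_stable(coeffs: Sequence[float], what: str) -> None:
    """Require all roots of 1 - c1 z - ... - cp z^p outside the unit circle."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        return
    roots = npoly.polyroots(np.r_[1.0, -coeffs])
    if roots.size and np.min(np.abs(roots)) <= 1.0 + 1e-10:
        raise ValueError(
            f"{what} polynomial has a root on or inside the unit circle "
            f"(min |root| = {np.min(np.abs(roots)):.6f}); "
            "express unit roots through the differencing order d instead"
        )


def generate_arma_series(
    ar_coeffs: Sequence[float],
    ma_coeffs: Sequence[float],
    d: int = 0,
    n: int = 1000,
    innovation_sd: float = 1.0,
    seed: int = 0,
    burn_in: int = 500,
) -> np.ndarray:
    """Simulate an ARIMA(p, d, q) realization with zero constant.

    The d-times-differenced output follows
    ``w_t = sum_i phi_i w_{t-i} + e_t + sum_j theta_j e_{t-j}`` with
    Gaussian innovations of standard deviation ``innovation_sd``.  A burn-in
    of ``burn_in`` (>= 500 by default) samples is discarded so the retained
    stretch is effectively stationary before integration.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if d not in (0, 1, 2):
        raise ValueError("d must be 0, 1 or 2")
    ar = np.asarray(ar_coeffs, dtype=float)
    ma = np.asarray(ma_coeffs, dtype=float)
    _check_stable(ar, "AR")
    _check_stable(-ma, "MA")  # invertibility: roots of 1 + theta z outside circle
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, innovation_sd, size=n + burn_in)
    w = spsignal.lfilter(np.r_[1.0, ma], np.r_[1.0, -ar], e)[burn_in:]
    for _ in range(d):
        w = np.cumsum(w)
    return w


def _slow_wave_sum(
    components: Sequence[SlowWave], t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    out = np.zeros_like(t)
    for wave in components:
        phase = wave.phase
        if phase is None:
            phase = rng.uniform(0.0, 2.0 * np.pi)
        out += wave.amplitude * np.sin(2.0 * np.pi * wave.frequency * t + phase)
    return out


def _filtered_noise_slow_wave(
    components: Sequence[SlowWave],
    n: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian noise alternative to the sinusoid sum.

    Matched in RMS to the sinusoid-sum configuration so downstream
    correlation magnitudes are comparable.
    """
    white = rng.normal(0.0, 1.0, size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    band = (freqs >= SLOW_WAVE_BAND[0]) & (freqs <= SLOW_WAVE_BAND[1])
    spec[~band] = 0.0
    x = np.fft.irfft(spec, n=n)
    target_rms = np.sqrt(sum((w.amplitude**2) / 2.0 for w in components))
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= target_rms / rms
    return x


def _cardiac_pulse(freq: float, t: np.ndarray, amplitude: np.ndarray | float) -> np.ndarray:
    """Cardiac pulse: fundamental plus two decaying harmonics.

    The harmonic ratios (0.3, 0.1 of the fundamental) give a mildly peaked,
    non-sinusoidal pulse; AMP extraction reads only the fundamental bin.
    """
    base = (
        np.sin(2.0 * np.pi * freq * t)
        + 0.3 * np.sin(2.0 * np.pi * 2.0 * freq * t)
        + 0.1 * np.sin(2.0 * np.pi * 3.0 * freq * t)
    )
    return amplitude * base


def generate_patient_waveforms(
    config: SimulationConfig, patient_id: str = "synthetic-000"
) -> WaveformRecord:
    """Generate one patient's ABP/ICP/PbtO2 record from a config.

    Construction (all on the same uniform time base):

    * ABP  = map_baseline + MAP slow waves + respiration + cardiac pulse + noise
    * ICP  = icp_baseline + g * (MAP slow-wave component) + own slow wave
             + cardiac pulse of amplitude icp_pulse_base * (1 + a * z) + noise,
      where z is the ICP slow-wave level normalized to [-1, 1]
    * PbtO2 = pbto2_baseline + pbto2_cpp_gain * lagged CPP slow wave + noise

    Identical config (including seed) yields bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n = config.n_samples
    t = np.arange(n) / fs

    if config.slow_wave_mode == "sinusoid":
        map_slow = _slow_wave_sum(config.slow_wave_components, t, rng)
        icp_own_slow = _slow_wave_sum([config.icp_slow_wave], t, rng)
    else:
        map_slow = _filtered_noise_slow_wave(config.slow_wave_components, n, fs, rng)
        icp_own_slow = _filtered_noise_slow_wave([config.icp_slow_wave], n, fs, rng)

    def minute_walk() -> np.ndarray:
        """Baseline wander: a per-minute Gaussian random walk interpolated to
        the sample grid.  Emulates the slow, non-oscillatory drift of real
        bedside signals that survives coarse averaging."""
        if config.drift_sd == 0:
            return np.zeros(n)
        n_knots = int(np.ceil(config.duration_minutes)) + 1
        knots = np.concatenate(
            [[0.0], np.cumsum(rng.normal(0.0, config.drift_sd, n_knots))]
        )
        return np.interp(t / 60.0, np.arange(n_knots + 1, dtype=float), knots)

    abp_drift = minute_walk()
    icp_drift = minute_walk()
    pbto2_drift = minute_walk()

    resp = config.resp_amplitude * np.sin(
        2.0 * np.pi * config.resp_freq * t + rng.uniform(0.0, 2.0 * np.pi)
    )

    abp = (
        config.map_baseline
        + abp_drift
        + map_slow
        + resp
        + _cardiac_pulse(config.cardiac_freq, t, config.pulse_pressure)
    )

    icp_slow = config.autoregulation_gain * map_slow + icp_own_slow
    peak = np.max(np.abs(icp_slow))
    z = icp_slow / peak if peak > 0 else np.zeros_like(icp_slow)
    icp_pulse_amp = np.maximum(
        config.icp_pulse_base * (1.0 + config.amp_icp_coupling * z), 0.0
    )
    icp = (
        config.icp_baseline
        + icp_drift
        + icp_slow
        + _cardiac_pulse(config.cardiac_freq, t, icp_pulse_amp)
    )

    cpp_slow = map_slow - icp_slow
    shift = int(round(config.pbto2_lag * fs))
    if shift > 0:
        lagged = np.concatenate([np.full(min(shift, n), cpp_slow[0]), cpp_slow[:-shift]])[:n]
    else:
        lagged = cpp_slow
    pbto2 = config.pbto2_baseline + pbto2_drift + config.pbto2_cpp_gain * lagged

    if config.noise_sd > 0:
        abp = abp + rng.normal(0.0, config.noise_sd, size=n)
        icp = icp + rng.normal(0.0, config.noise_sd, size=n)
        pbto2 = pbto2 + rng.normal(0.0, config.noise_sd, size=n)

    record = WaveformRecord(
        patient_id=patient_id, sampling_rate=fs, abp=abp, icp=icp, pbto2=pbto2
    )
    if config.missing_spec:
        gaps = []
        for gap_length, count in config.missing_spec:
            gaps.extend(random_gaps(n, gap_length, count, rng, existing=gaps))
        record = inject_missingness(record, gaps)
    return record


def random_gaps(
    n_samples: int,
    gap_length: int,
    count: int,
    seed_or_rng: int | np.random.Generator,
    existing: Sequence[tuple[int, int]] = (),
) -> list[tuple[int, int]]:
    """Draw ``count`` non-overlapping (start, length) gaps of a given length.

    Deterministic given the seed; raises if placements cannot be found.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if gap_length <= 0 or gap_length > n_samples:
        raise ValueError("gap_length out of range")
    placed: list[tuple[int, int]] = list(existing)
    out: list[tuple[int, int]] = []
    for _ in range(count):
        for _attempt in range(10_000):
            start = int(rng.integers(0, n_samples - gap_length + 1))
            if all(
                start + gap_length <= s or start >= s + l for s, l in placed
            ):
                placed.append((start, gap_length))
                out.append((start, gap_length))
                break
        else:
            raise ValueError("could not place non-overlapping gaps")
    return out


def inject_missingness(
    record: WaveformRecord, gaps: Sequence[tuple[int, int]], seed: int | None = None
) -> WaveformRecord:
    """Flag (start, length) sample ranges missing on every channel.

    Values under the mask are preserved.  Overlapping or out-of-range gaps
    are rejected.  ``seed`` is accepted for signature symmetry with the
    other generators but unused when gaps are explicit.
    """
    n = record.n_samples
    sorted_gaps = sorted((int(s), int(l)) for s, l in gaps)
    prev_end = -1
    for start, length in sorted_gaps:
        if length <= 0 or start < 0 or start + length > n:
            raise ValueError(f"gap ({start}, {length}) out of record bounds")
        if start < prev_end:
            raise ValueError("overlapping gaps")
        prev_end = start + length
    new_masks = {k: v.copy() for k, v in record.missing_mask.items()}
    for start, length in sorted_gaps:
        for name in record.channel_names():
            new_masks[name][start : start + length] = True
    return replace(record, missing_mask=new_masks)


def impaired_config(**overrides) -> SimulationConfig:
    """Config with impaired cerebral autoregulation (pressure-passive ICP)."""
    return SimulationConfig(autoregulation_gain=1.0, **overrides)


def intact_config(**overrides) -> SimulationConfig:
    """Config with intact autoregulation (counter-regulating ICP)."""
    return SimulationConfig(autoregulation_gain=-1.0, **overrides)
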