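"""Synthesis and analysis-based verification of suprathreshold auditory stimuli.

Six target stimulus classes are covered, each paired with an unmodulated
standard:

* diotic / dichotic frequency modulation of a low-frequency pure tone
  (2-Hz sinusoidal phase modulation of a 460-550 Hz carrier),
* a temporal gap between two 4-ms 500-Hz tone bursts,
* temporally (4 Hz), spectrally (2 cycles/octave), and spectrotemporally
  modulated broadband noise.

All generators return a calibrated two-channel :class:`AudioStimulus`.
Digital level calibration is handled by :class:`CalibrationMap`, which maps
dB SPL onto full-scale digital RMS (the software analogue of a headphone
calibration): level is defined on the steady-state (un-ramped) portion of
the waveform, so onset/offset gating does not count against the level.

Verification (:func:`verify_stimulus`) re-estimates the generating
parameters from the samples alone — Hilbert demodulation for FM, silent-run
measurement on the rectified waveform for gaps, log-spectrum/log-envelope
sinusoid regression for the modulated noises — and shares no code with the
synthesis path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "DEFAULT_SAMPLE_RATE",
    "AudioStimulus",
    "CalibrationMap",
    "FMToneSpec",
    "GapStimulusSpec",
    "ModulatedNoiseSpec",
    "StimulusVerification",
    "synth_fm_tone",
    "synth_gap_pair",
    "synth_modulated_noise",
    "verify_stimulus",
]

DEFAULT_SAMPLE_RATE = 44100

#: onset/offset ramp applied to every observation interval (s)
INTERVAL_RAMP_S = 0.010
#: shorter ramp used inside the 4-ms tone bursts of the gap stimulus (s)
BURST_RAMP_S = 0.001


class ParameterError(ValueError):
    """A stimulus specification violates its physical constraints."""


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class AudioStimulus:
    """A calibrated two-channel sampled waveform (full scale ±1)."""

    samples: np.ndarray  # shape (2, n)
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim == 1:
            samples = np.vstack([samples, samples])
        if samples.ndim != 2 or samples.shape[0] != 2:
            raise ParameterError("samples must have shape (2, n)")
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-12:
            raise ParameterError("samples exceed full scale [-1, 1]")
        object.__setattr__(self, "samples", samples)

    @property
    def n_channels(self) -> int:
        return 2

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    def channel(self, i: int) -> np.ndarray:
        return self.samples[i]


@dataclass(frozen=True)
class CalibrationMap:
    """Digital calibration: a reference dB SPL pinned to a reference RMS.

    The map is exponential, so +20 dB SPL multiplies digital RMS by 10.
    Default: 75 dB SPL <-> RMS 0.05 full scale (convention, configurable).
    """

    reference_db_spl: float = 75.0
    reference_rms: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.reference_rms <= 1.0:
            raise ParameterError("reference_rms must be in (0, 1]")

    def rms_for_level(self, level_db_spl: float) -> float:
        return self.reference_rms * 10.0 ** ((level_db_spl - self.reference_db_spl) / 20.0)

    def level_for_rms(self, rms: float) -> float:
        if rms <= 0:
            raise ParameterError("rms must be positive")
        return self.reference_db_spl + 20.0 * math.log10(rms / self.reference_rms)


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class FMToneSpec:
    """Sinusoidally phase-modulated pure tone.

    ``depth_hz`` is the peak instantaneous-frequency deviation; the
    phase-modulation index is ``depth_hz / mod_rate_hz``.  ``mode`` selects
    identical modulation in the two ears (diotic) or antiphase modulation
    (dichotic, a dynamic interaural time difference).
    """

    carrier_hz: float = 505.0
    mod_rate_hz: float = 2.0
    depth_hz: float = 0.0
    duration_s: float = 0.4
    level_db_spl: float = 75.0
    mode: Literal["diotic", "dichotic"] = "diotic"

    def __post_init__(self) -> None:
        if self.depth_hz < 0:
            raise ParameterError("depth_hz must be >= 0")
        if not 460.0 <= self.carrier_hz <= 550.0:
            raise ParameterError("carrier_hz outside the roving range [460, 550]")
        if self.mode not in ("diotic", "dichotic"):
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.mod_rate_hz <= 0:
            raise ParameterError("mod_rate_hz must be positive")


@dataclass(frozen=True)
class GapStimulusSpec:
    """Two brief tone bursts separated by ``gap_ms`` of silence.

    The gap is the silent span between the end of the first burst's offset
    ramp and the start of the second burst's onset ramp; ``gap_ms = 0``
    reproduces the standard (one contiguous 8-ms event).
    """

    burst_freq_hz: float = 500.0
    burst_dur_ms: float = 4.0
    gap_ms: float = 0.0
    level_db_spl: float = 75.0

    def __post_init__(self) -> None:
        if self.gap_ms < 0:
            raise ParameterError("gap_ms must be >= 0")
        if self.burst_dur_ms <= 0:
            raise ParameterError("burst_dur_ms must be positive")


@dataclass(frozen=True)
class ModulatedNoiseSpec:
    """Broadband noise carrying temporal and/or spectral (ripple) modulation.

    ``depth_db`` is the peak-to-midline excursion, in dB, of the sinusoidal
    modulation: of the log-frequency spectrum (SM), of the broadband envelope
    (TM), or of a ripple drifting at ``temporal_rate_hz`` (STM).
    ``phase_rad`` is the starting phase; ``None`` draws it from the seed.
    """

    kind: Literal["TM", "SM", "STM"] = "STM"
    temporal_rate_hz: float = 4.0
    spectral_density_cyc_oct: float = 2.0
    depth_db: float = 0.0
    phase_rad: float | None = None
    duration_s: float = 0.4
    level_db_spl: float = 75.0
    band_lo_hz: float = 200.0
    band_hi_hz: float = 8000.0
    drift_direction: Literal[1, -1, 0] = 0  # STM drift; 0 = randomize per seed

    def __post_init__(self) -> None:
        if self.kind not in ("TM", "SM", "STM"):
            raise ParameterError(f"unsupported kind {self.kind!r}")
        if self.depth_db < 0:
            raise ParameterError("depth_db must be >= 0")
        if not self.band_lo_hz < self.band_hi_hz:
            raise ParameterError("band_lo_hz must be < band_hi_hz")
        # the kind pins which modulation rates are active
        if self.kind == "TM" and self.spectral_density_cyc_oct != 0:
            object.__setattr__(self, "spectral_density_cyc_oct", 0.0)
        if self.kind == "SM" and self.temporal_rate_hz != 0:
            object.__setattr__(self, "temporal_rate_hz", 0.0)


# ---------------------------------------------------------------------------
# synthesis helpers


def _ramp_gains(n: int) -> np.ndarray:
    # raised-cosine, sampled at half-sample offsets so no endpoint is exactly 0
    k = np.arange(n) + 0.5
    return np.sin(0.5 * np.pi * k / n) ** 2


def _apply_ramps(x: np.ndarray, n_ramp: int) -> np.ndarray:
    g = _ramp_gains(n_ramp)
    x = x.copy()
    x[..., :n_ramp] *= g
    x[..., -n_ramp:] *= g[::-1]
    return x


def _steady_rms(x: np.ndarray, n_ramp: int) -> float:
    core = x[..., n_ramp:-n_ramp] if n_ramp else x
    return float(np.sqrt(np.mean(core[0] ** 2)))


def synth_fm_tone(
    spec: FMToneSpec,
    calib: CalibrationMap | None = None,
    seed: int | np.random.Generator | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioStimulus:
    """Synthesize a (possibly phase-modulated) pure tone interval.

    Diotic mode: both channels bit-identical. Dichotic mode: the
    phase-modulation terms of the two channels are in antiphase, creating a
    2-Hz interaural delay sweep while each ear alone carries identical FM.
    """
    calib = calib or CalibrationMap()
    if sample_rate < 4 * spec.carrier_hz:
        raise ParameterError("sample_rate must be at least 4x the carrier")
    n = round(spec.duration_s * sample_rate)
    n_ramp = round(INTERVAL_RAMP_S * sample_rate)
    if n < 2 * n_ramp:
        raise ParameterError("duration shorter than two onset/offset ramps")
    t = np.arange(n) / sample_rate
    beta = spec.depth_hz / spec.mod_rate_hz  # phase-modulation index
    pm = beta * np.sin(2 * np.pi * spec.mod_rate_hz * t)
    amp = math.sqrt(2.0) * calib.rms_for_level(spec.level_db_spl)
    carrier_phase = 2 * np.pi * spec.carrier_hz * t
    left = amp * np.sin(carrier_phase + pm)
    if spec.mode == "diotic":
        right = left
    else:
        right = amp * np.sin(carrier_phase - pm)
    samples = _apply_ramps(np.vstack([left, right]), n_ramp)
    return AudioStimulus(samples, sample_rate)


def synth_gap_pair(
    spec: GapStimulusSpec,
    calib: CalibrationMap | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioStimulus:
    """Two ramped tone bursts with ``gap_ms`` of digital silence between."""
    calib = calib or CalibrationMap()
    n_burst = round(spec.burst_dur_ms / 1000.0 * sample_rate)
    n_gap = round(spec.gap_ms / 1000.0 * sample_rate)
    n_ramp = min(round(BURST_RAMP_S * sample_rate), n_burst // 2)
    t = np.arange(n_burst) / sample_rate
    amp = math.sqrt(2.0) * calib.rms_for_level(spec.level_db_spl)
    burst = _apply_ramps(amp * np.sin(2 * np.pi * spec.burst_freq_hz * t), n_ramp)
    mono = np.concatenate([burst, np.zeros(n_gap), burst])
    return AudioStimulus(np.vstack([mono, mono]), sample_rate)


def synth_modulated_noise(
    spec: ModulatedNoiseSpec,
    calib: CalibrationMap | None = None,
    seed: int | np.random.Generator | None = None,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
) -> AudioStimulus:
    """Synthesize rippled / envelope-modulated noise, presented diotically.

    The noise is a dense bank of equal-amplitude random-phase tone carriers
    uniformly spaced on a log2-frequency axis across the band. Each carrier
    ``i`` at log2 offset ``u_i`` octaves receives the time-varying dB gain::

        g_i(t) = depth_db * sin(2*pi*(density*u_i + dir*rate*t) + phase)

    which reduces to a static spectral ripple for SM (rate 0), a common
    broadband envelope for TM (density 0), and a drifting ripple for STM.
    ``depth_db = 0`` leaves flat pseudo-noise of the same band and level.
    The realization is normalized so its steady-state RMS meets the
    calibrated level exactly.
    """
    calib = calib or CalibrationMap()
    rng = np.random.default_rng(seed)
    n = round(spec.duration_s * sample_rate)
    n_ramp = round(INTERVAL_RAMP_S * sample_rate)
    if n < 2 * n_ramp:
        raise ParameterError("duration shorter than two onset/offset ramps")

    n_octaves = math.log2(spec.band_hi_hz / spec.band_lo_hz)
    comps_per_octave = 60
    n_comp = max(16, round(comps_per_octave * n_octaves))
    u = (np.arange(n_comp) + 0.5) * (n_octaves / n_comp)  # octaves above band_lo
    freqs = spec.band_lo_hz * 2.0**u
    phases = rng.uniform(0, 2 * np.pi, size=n_comp)
    ripple_phase = spec.phase_rad if spec.phase_rad is not None else rng.uniform(0, 2 * np.pi)
    if spec.kind == "STM" and spec.drift_direction == 0:
        direction = 1 if rng.random() < 0.5 else -1
    else:
        direction = spec.drift_direction or 1

    t = np.arange(n) / sample_rate
    rate = spec.temporal_rate_hz if spec.kind in ("TM", "STM") else 0.0
    density = spec.spectral_density_cyc_oct if spec.kind in ("SM", "STM") else 0.0
    # (n_comp, n) dB-gain argument; memory ~ n_comp * n floats
    arg = 2 * np.pi * (density * u[:, None] + direction * rate * t[None, :]) + ripple_phase
    gains = 10.0 ** (spec.depth_db * np.sin(arg) / 20.0)
    carriers = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    mono = np.sum(gains * carriers, axis=0)

    # level is defined on the steady-state portion (gating ramps excluded)
    target_rms = calib.rms_for_level(spec.level_db_spl)
    core_rms = np.sqrt(np.mean(mono[n_ramp:-n_ramp] ** 2))
    mono *= target_rms / core_rms
    peak = np.max(np.abs(mono))
    if peak > 1.0:  # guard full scale; practically unreachable at default levels
        mono /= peak
    mono = _apply_ramps(mono, n_ramp)
    return AudioStimulus(np.vstack([mono, mono]), sample_rate)


# ---------------------------------------------------------------------------
# verification (analysis path, independent of synthesis)


@dataclass
class StimulusVerification:
    """Parameter estimates recovered from a waveform by signal analysis."""

    kind: str
    level_db_spl: float
    carrier_hz: float | None = None
    depth_hz: float | None = None
    gap_ms: float | None = None
    temporal_rate_hz: float | None = None
    spectral_density_cyc_oct: float | None = None
    depth_db: float | None = None
    channels_identical: bool | None = None
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {k: v for k, v in self.__dict__.items() if k != "extras" and v is not None}
        out.update(self.extras)
        return out


def _sinusoid_fit(y: np.ndarray, x: np.ndarray, cycles_grid: np.ndarray):
    """Least-squares fit of a + b*sin + c*cos over a grid of frequencies.

    Returns (best_freq, amplitude, r_squared). ``x`` in the units matching
    ``cycles_grid`` (cycles per unit of x).
    """
    y = y - np.mean(y)
    best = (float(cycles_grid[0]), 0.0, -np.inf)
    for f in cycles_grid:
        s = np.sin(2 * np.pi * f * x)
        c = np.cos(2 * np.pi * f * x)
        design = np.column_stack([s, c, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y) + 1e-30
        r2 = 1.0 - ss_res / ss_tot
        if r2 > best[2]:
            best = (float(f), float(np.hypot(coef[0], coef[1])), r2)
    return best


def _instantaneous_frequency(x: np.ndarray, sample_rate: int) -> np.ndarray:
    analytic = hilbert(x)
    phase = np.unwrap(np.angle(analytic))
    return np.diff(phase) * sample_rate / (2 * np.pi)


def _verify_fm(stim: AudioStimulus, spec: FMToneSpec) -> StimulusVerification:
    fs = stim.sample_rate
    n_trim = round(2 * INTERVAL_RAMP_S * fs)  # drop ramps + settling margin
    x = stim.channel(0)
    inst_f = _instantaneous_frequency(x, fs)[n_trim:-n_trim]
    t = np.arange(inst_f.size) / fs
    carrier_est = float(np.mean(inst_f))
    # known modulation rate: project the deviation on sin/cos at that rate
    s = np.sin(2 * np.pi * spec.mod_rate_hz * t)
    c = np.cos(2 * np.pi * spec.mod_rate_hz * t)
    design = np.column_stack([s, c, np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, inst_f, rcond=None)
    depth_est = float(np.hypot(coef[0], coef[1]))
    rms = _steady_rms(stim.samples, round(INTERVAL_RAMP_S * fs))
    identical = bool(np.array_equal(stim.channel(0), stim.channel(1)))
    return StimulusVerification(
        kind="FM",
        level_db_spl=CalibrationMap().level_for_rms(rms),
        carrier_hz=carrier_est,
        depth_hz=depth_est,
        channels_identical=identical,
    )


def _verify_gap(stim: AudioStimulus, spec: GapStimulusSpec) -> StimulusVerification:
    fs = stim.sample_rate
    x = np.abs(stim.channel(0))
    active = np.flatnonzero(x > 1e-9 * max(x.max(), 1e-30))
    if active.size == 0:
        raise ParameterError("empty stimulus")
    seg = x[active[0] : active[-1] + 1]
    # longest internal run of silent samples = the gap
    silent = seg <= 1e-9 * x.max()
    best = run = 0
    for s in silent:
        run = run + 1 if s else 0
        best = max(best, run)
    # burst plateau level: peak amplitude of the gated tone over sqrt(2)
    rms = float(x.max() / math.sqrt(2.0))
    return StimulusVerification(
        kind="gap",
        level_db_spl=CalibrationMap().level_for_rms(max(rms, 1e-12)),
        gap_ms=best / fs * 1000.0,
        channels_identical=bool(np.array_equal(stim.channel(0), stim.channel(1))),
    )


def _band_averaged_spectrum_db(x: np.ndarray, fs: int, lo: float, hi: float,
                               bands_per_octave: int = 16):
    """Mean periodogram power in log-spaced bands, in dB, vs octave offset."""
    w = np.hanning(x.size)
    spec = np.abs(np.fft.rfft(x * w)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    # stay clear of the band edges where the carrier bank rolls off
    lo_m, hi_m = lo * 2**0.25, hi * 2**-0.25
    n_bands = int(math.log2(hi_m / lo_m) * bands_per_octave)
    edges = lo_m * 2.0 ** (np.arange(n_bands + 1) / bands_per_octave)
    u_mid = np.log2(edges[:-1] * np.sqrt(edges[1] / edges[0]) / lo)
    power = np.empty(n_bands)
    for i in range(n_bands):
        sel = (freqs >= edges[i]) & (freqs < edges[i + 1])
        power[i] = spec[sel].mean() if sel.any() else np.nan
    keep = np.isfinite(power) & (power > 0)
    return u_mid[keep], 10.0 * np.log10(power[keep])


def _verify_sm(x: np.ndarray, fs: int, spec: ModulatedNoiseSpec):
    u, p_db = _band_averaged_spectrum_db(x, fs, spec.band_lo_hz, spec.band_hi_hz)
    grid = np.arange(0.25, 4.51, 0.01)
    density, depth, r2 = _sinusoid_fit(p_db, u, grid)
    return density, depth, r2


def _verify_tm(x: np.ndarray, fs: int):
    env = np.abs(hilbert(x))
    n_trim = round(1.5 * INTERVAL_RAMP_S * fs)
    env = env[n_trim:-n_trim]
    n_ma = round(0.025 * fs)  # 25-ms moving average
    kernel = np.ones(n_ma) / n_ma
    env = np.convolve(env, kernel, mode="valid")
    e_db = 20.0 * np.log10(np.maximum(env, 1e-12))
    t = np.arange(e_db.size) / fs
    grid = np.arange(1.0, 10.01, 0.02)
    rate, depth, r2 = _sinusoid_fit(e_db, t, grid)
    depth /= np.sinc(rate * n_ma / fs)  # undo moving-average attenuation
    return rate, depth, r2


def _verify_stm(x: np.ndarray, fs: int, spec: ModulatedNoiseSpec):
    """Short-time ripple tracking: per-frame spectral fit, phase drift -> rate."""
    n_win = 2048
    hop = 512
    frames = []
    times = []
    for start in range(0, x.size - n_win + 1, hop):
        frames.append(x[start : start + n_win])
        times.append((start + n_win / 2) / fs)
    times = np.array(times)
    grid = np.arange(0.5, 4.01, 0.05)
    # pick density by mean fit quality across frames
    best_density, best_score = grid[0], -np.inf
    proj_cache = {}
    for d in grid:
        amps = []
        zs = []
        for fr in frames:
            u, p_db = _band_averaged_spectrum_db(fr, fs, spec.band_lo_hz, spec.band_hi_hz,
                                                 bands_per_octave=12)
            z = np.mean((p_db - p_db.mean()) * np.exp(-2j * np.pi * d * u))
            zs.append(z)
            amps.append(abs(z))
        score = float(np.mean(amps))
        proj_cache[d] = np.array(zs)
        if score > best_score:
            best_density, best_score = float(d), score
    z = proj_cache[best_density]
    phase = np.unwrap(np.angle(z))
    slope, _ = np.polyfit(times, phase, 1)
    rate = slope / (2 * np.pi)  # signed: drift direction
    depth = 2.0 * float(np.mean(np.abs(z)))
    # window smear correction for a ripple drifting across the frame
    depth /= max(np.sinc(abs(rate) * n_win / fs), 1e-6)
    return rate, best_density, depth


def _verify_noise(stim: AudioStimulus, spec: ModulatedNoiseSpec) -> StimulusVerification:
    fs = stim.sample_rate
    n_ramp = round(INTERVAL_RAMP_S * fs)
    x = stim.channel(0)[n_ramp:-n_ramp]
    rms = float(np.sqrt(np.mean(x**2)))
    out = StimulusVerification(
        kind=spec.kind,
        level_db_spl=CalibrationMap().level_for_rms(rms),
        channels_identical=bool(np.array_equal(stim.channel(0), stim.channel(1))),
    )
    if spec.kind == "SM":
        density, depth, r2 = _verify_sm(x, fs, spec)
        out.spectral_density_cyc_oct = density
        out.depth_db = depth
        out.extras["ripple_fit_r2"] = r2
    elif spec.kind == "TM":
        rate, depth, r2 = _verify_tm(x, fs)
        out.temporal_rate_hz = rate
        out.depth_db = depth
        out.extras["envelope_fit_r2"] = r2
    else:
        rate, density, depth = _verify_stm(stim.channel(0), fs, spec)
        out.temporal_rate_hz = abs(rate)
        out.extras["drift_direction"] = int(np.sign(rate)) if rate else 0
        out.spectral_density_cyc_oct = density
        out.depth_db = depth
    return out


def verify_stimulus(
    stim: AudioStimulus,
    spec: FMToneSpec | GapStimulusSpec | ModulatedNoiseSpec,
) -> StimulusVerification:
    """Estimate the generating parameters of ``stim`` from its samples.

    The estimators are analysis-only (demodulation, silent-run measurement,
    spectrum/envelope regression) and never consult the synthesis code.
    """
    if stim.n_samples == 0:
        raise ParameterError("empty stimulus")
    if isinstance(spec, FMToneSpec):
        return _verify_fm(stim, spec)
    if isinstance(spec, GapStimulusSpec):
        return _verify_gap(stim, spec)
    if isinstance(spec, ModulatedNoiseSpec):
        return _verify_noise(stim, spec)
    raise TypeError(f"unsupported spec type {type(spec).__name__}")


def standard_for(spec):
    """The unmodulated standard matching a target spec (zero depth / gap)."""
    if isinstance(spec, FMToneSpec):
        return replace(spec, depth_hz=0.0)
    if isinstance(spec, GapStimulusSpec):
        return replace(spec, gap_ms=0.0)
    if isinstance(spec, ModulatedNoiseSpec):
        return replace(spec, depth_db=0.0)
    raise TypeError(f"unsupported spec type {type(spec).__name__}")
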