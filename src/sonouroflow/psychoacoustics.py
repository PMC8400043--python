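"""Psychoacoustic features of voiding sounds: loudness (sone) and roughness (asper).

The two features feed the sequence models:

* **Loudness** ``N = integral_0^24 N'(z) dz`` where the specific loudness per
  critical band is ``N' = 0.08 (E_TQ/E_0)^0.23 [(0.5 + 0.5 E/E_TQ)^0.23 - 1]``
  (Zwicker's stationary-loudness law, clamped at zero below the threshold in
  quiet).  The excitation pattern E(z) is obtained from calibrated spectrum
  levels via third-octave band intensities mapped onto the Bark scale with
  level spreading, in the spirit of ISO 532-1 but without claiming
  certification.
* **Roughness** ``R = cal * 0.3 * f_mod[kHz] * integral_0^24 dL(z) dz`` where
  dL(z) is the masking depth (peak-to-trough swing, capped) of the critical
  band level envelope band-passed around the modulation frequency.  The
  modulation frequency is fixed at 70 Hz and the final scalar ``cal`` is
  calibrated once so that the reference signal -- a 1 kHz tone at 60 dB SPL,
  100% amplitude-modulated at 70 Hz -- yields 1 asper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_core import P_REF, SoundRecording, Spectrogram, STFTConfig, stft

# --------------------------------------------------------------------------
# Bark scale and threshold in quiet
# --------------------------------------------------------------------------

#: Reference intensity I0 = 1e-12 W/m^2 (0 dB).
I_0 = 1e-12

#: Fixed critical-band-rate grid, 0..24 Bark in 0.1-Bark steps.
BARK_STEP = 0.1
BARK_GRID = np.round(np.arange(0.0, 24.0 + 1e-9, BARK_STEP), 10)

# Excitation-spreading slopes in dB/Bark (level domain).  The skirt toward
# lower critical-band rates is steep; the skirt toward higher rates is
# shallower (simplified level-independent values).
_SLOPE_LOWER = 27.0
_SLOPE_UPPER = 12.0


def hz_to_bark(f) -> np.ndarray:
    """Critical-band rate z (Bark) for frequency f (Hz), Zwicker-Terhardt form.

    z = 13 arctan(0.00076 f) + 3.5 arctan((f/7500)^2); 1 kHz maps to ~8.5 Bark.
    """
    f = np.asarray(f, dtype=float)
    return 13.0 * np.arctan(0.00076 * f) + 3.5 * np.arctan((f / 7500.0) ** 2)


# Monotone table for the numerical inverse of hz_to_bark.
_F_TAB = np.geomspace(1.0, 32_000.0, 4000)
_Z_TAB = hz_to_bark(_F_TAB)


def bark_to_hz(z) -> np.ndarray:
    """Numerical inverse of :func:`hz_to_bark` on [0, 24] Bark."""
    return np.interp(np.asarray(z, dtype=float), _Z_TAB, _F_TAB)


def threshold_quiet_db(f) -> np.ndarray:
    """Threshold in quiet, dB SPL, Terhardt's analytic approximation."""
    fk = np.asarray(f, dtype=float) / 1000.0
    fk = np.maximum(fk, 0.02)
    return (
        3.64 * fk ** -0.8
        - 6.5 * np.exp(-0.6 * (fk - 3.3) ** 2)
        + 1e-3 * fk ** 4
    )


# --------------------------------------------------------------------------
# Excitation pattern and loudness
# --------------------------------------------------------------------------


@dataclass
class ExcitationPattern:
    """Auditory excitation per critical-band rate on the fixed Bark grid.

    ``excitation`` is intensity-like (W/m^2-equivalent); ``e_tq`` is the
    threshold-in-quiet excitation per band and ``e_0`` the reference
    excitation corresponding to I0 = 1e-12 W/m^2.
    """

    bark_grid: np.ndarray
    excitation: np.ndarray
    e_tq: np.ndarray
    e_0: float = I_0

    def __post_init__(self) -> None:
        if np.any(self.excitation < 0):
            raise ValueError("excitation must be nonnegative")
        if np.any(self.e_tq <= 0):
            raise ValueError("threshold-in-quiet excitation must be positive")


@dataclass
class SpecificLoudnessPattern:
    """Specific loudness N' (sone_G/Bark) per band on the Bark grid."""

    bark_grid: np.ndarray
    values: np.ndarray  # N', >= 0


# Third-octave band center frequencies (base-10 preferred values), 25 Hz .. 16 kHz.
_TO_CENTERS = 1000.0 * 10.0 ** (np.arange(-16, 13) / 10.0)
_TO_EDGE = 10.0 ** (1.0 / 20.0)

#: Threshold-in-quiet excitation on the Bark grid (intensity units).
E_TQ_GRID = I_0 * 10.0 ** (threshold_quiet_db(bark_to_hz(BARK_GRID)) / 10.0)


def bark_excitation(level_db: np.ndarray, bin_freqs: np.ndarray) -> ExcitationPattern:
    """Excitation pattern of one spectrogram frame.

    Per-bin RMS levels (dB re 20 uPa) are converted to intensities, summed
    into third-octave bands, placed at each band center's critical-band rate
    and spread over the Bark grid with fixed skirt slopes; component
    intensities add.  Digital silence maps to all-zero excitation.
    """
    level_db = np.asarray(level_db, dtype=float)
    bin_freqs = np.asarray(bin_freqs, dtype=float)
    if level_db.shape != bin_freqs.shape:
        raise ValueError("level_db and bin_freqs must have equal shapes")

    intens = 10.0 ** (level_db / 10.0) * I_0
    # Levels at/below an effective silence floor carry no excitation.
    intens[level_db < -60.0] = 0.0

    exc = np.zeros_like(BARK_GRID)
    for fc in _TO_CENTERS:
        lo, hi = fc / _TO_EDGE, fc * _TO_EDGE
        sel = (bin_freqs >= lo) & (bin_freqs < hi)
        if not np.any(sel):
            continue
        band_i = intens[sel].sum()
        if band_i <= 0:
            continue
        zc = hz_to_bark(fc)
        dz = BARK_GRID - zc
        slope = np.where(dz < 0, _SLOPE_LOWER, _SLOPE_UPPER)
        exc += band_i * 10.0 ** (-slope * np.abs(dz) / 10.0)
    return ExcitationPattern(bark_grid=BARK_GRID, excitation=exc, e_tq=E_TQ_GRID.copy())


def specific_loudness(exc: ExcitationPattern) -> SpecificLoudnessPattern:
    """Specific loudness N' per band from an excitation pattern.

    N' = 0.08 (E_TQ/E0)^0.23 [(0.5 + 0.5 E/E_TQ)^0.23 - 1], clamped at 0:
    excitation at or below the threshold in quiet produces no loudness.
    """
    if np.any(exc.excitation < 0):
        raise ValueError("excitation must be nonnegative")
    ratio = exc.e_tq / exc.e_0
    raw = 0.08 * ratio ** 0.23 * (
        (0.5 + 0.5 * exc.excitation / exc.e_tq) ** 0.23 - 1.0
    )
    return SpecificLoudnessPattern(bark_grid=exc.bark_grid, values=np.maximum(raw, 0.0))


def total_loudness(sl: SpecificLoudnessPattern) -> float:
    """Total loudness N (sone): trapezoid integral of N' over 0-24 Bark."""
    return float(np.trapezoid(sl.values, sl.bark_grid))


def frame_loudness(spec: Spectrogram) -> np.ndarray:
    """Stationary total loudness of every spectrogram frame (sone)."""
    out = np.empty(spec.n_frames)
    for j in range(spec.n_frames):
        exc = bark_excitation(spec.level_db[:, j], spec.bin_freqs)
        out[j] = total_loudness(specific_loudness(exc))
    return out


def _exp_smooth(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """First-order exponential smoothing with time constant tau seconds."""
    if tau <= 0 or dt <= 0 or x.size < 2:
        return x.copy()
    alpha = 1.0 - np.exp(-dt / tau)
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.size):
        y[i] = y[i - 1] + alpha * (x[i] - y[i - 1])
    return y


# --------------------------------------------------------------------------
# Roughness
# --------------------------------------------------------------------------


@dataclass
class RoughnessConfig:
    """Roughness model settings.

    ``modulation_frequency`` is fixed at 70 Hz; ``masking_depth_cap`` (50 dB)
    limits the per-band level swing so background noise does not inflate the
    estimate; ``calibration_factor`` is the 0.3 prefactor of the roughness
    integral; ``asper_scale`` is the one-time calibration scalar fixed so the
    reference AM tone yields 1 asper (see ROUGHNESS_ASPER_SCALE).
    """

    modulation_frequency: float = 70.0
    masking_depth_cap: float = 50.0
    calibration_factor: float = 0.3
    asper_scale: float = None  # filled with ROUGHNESS_ASPER_SCALE below
    block_length: float = 0.2
    block_overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.modulation_frequency <= 0:
            raise ValueError("modulation_frequency must be > 0")
        if self.masking_depth_cap <= 0:
            raise ValueError("masking_depth_cap must be > 0")
        if self.asper_scale is None:
            self.asper_scale = ROUGHNESS_ASPER_SCALE


#: One-time roughness calibration scalar: raw roughness of the 1-kHz, 60-dB,
#: 100% AM-at-70-Hz reference tone computed with asper_scale = 1, inverted so
#: that the reference yields exactly 1 asper.  Frozen; do not refit per run.
ROUGHNESS_ASPER_SCALE = 0.11001481569364767  # from calibrate_asper_scale()

#: Rate (Hz) at which band level envelopes are carried after decimation.
_ENV_RATE = 3000.0

#: Level floor (dB) for band envelopes, avoiding log(0) at 100% modulation.
_LEVEL_FLOOR_DB = 0.0


def critical_band_level_envelopes(rec: SoundRecording, n_bands: int = 24):
    """Per-critical-band level envelopes of a recording.

    The signal is split into 24 one-Bark-wide bands (Butterworth band-pass at
    the Bark band edges), each band's Hilbert envelope is decimated to 3 kHz
    and expressed in dB re 20 uPa (floored at 0 dB).

    Returns ``(levels, env_rate)`` with ``levels`` of shape (n_bands, n_env);
    bands entirely above Nyquist are silent (floor level).
    """
    x = rec.samples
    nyq = rec.sample_rate / 2.0
    dec = max(int(rec.sample_rate // _ENV_RATE), 1)
    env_rate = rec.sample_rate / dec
    n_env = int(np.ceil(x.size / dec))
    levels = np.full((n_bands, n_env), _LEVEL_FLOOR_DB)
    amp_cal = 10.0 ** (rec.calibration_offset / 20.0)
    for b in range(n_bands):
        f_lo = max(float(bark_to_hz(b)), 20.0)
        f_hi = min(float(bark_to_hz(b + 1)), 0.97 * nyq)
        if f_lo >= f_hi:
            continue
        sos = sps.butter(2, [f_lo, f_hi], btype="bandpass", fs=rec.sample_rate, output="sos")
        xb = sps.sosfilt(sos, x)
        env = np.abs(sps.hilbert(xb))[::dec] * amp_cal
        levels[b] = np.maximum(
            20.0 * np.log10(np.maximum(env, P_REF) / P_REF), _LEVEL_FLOOR_DB
        )
    return levels, env_rate


def masking_depth(band_levels: np.ndarray, cap: float) -> np.ndarray:
    """Masking depth dL(z) per band: peak-to-trough level swing, capped.

    ``band_levels`` holds one analysis block of level envelopes, shape
    (n_bands, n_samples).  Returns dL in dB, clipped to [0, cap].
    """
    band_levels = np.atleast_2d(np.asarray(band_levels, dtype=float))
    if band_levels.shape[1] == 0:
        raise ValueError("empty analysis block")
    swing = band_levels.max(axis=1) - band_levels.min(axis=1)
    return np.clip(swing, 0.0, cap)


def _modulation_bandpass(levels: np.ndarray, env_rate: float, f_mod: float) -> np.ndarray:
    """Band-pass each band's dB envelope around the modulation frequency.

    Zero-phase 2nd-order Butterworth over [f_mod/2, 2*f_mod]; isolates level
    fluctuation at roughness-relevant rates (an unmodulated tone passes ~0).
    """
    lo, hi = f_mod / 2.0, min(2.0 * f_mod, 0.45 * env_rate)
    sos = sps.butter(2, [lo, hi], btype="bandpass", fs=env_rate, output="sos")
    return sps.sosfiltfilt(sos, levels, axis=1)


def roughness_from_envelopes(
    levels: np.ndarray, env_rate: float, cfg: RoughnessConfig
) -> float:
    """Roughness (asper) of one analysis block of band level envelopes.

    R = asper_scale * 0.3 * f_mod[kHz] * integral dL(z) dz, the integral
    taken bandwise over the 24 one-Bark bands.
    """
    n = np.atleast_2d(levels).shape[1]
    if n / env_rate < 1.0 / cfg.modulation_frequency:
        raise ValueError("analysis block shorter than one modulation period")
    dl = masking_depth(levels, cfg.masking_depth_cap)
    integral = float(dl.sum())  # dz = 1 Bark per band
    return (
        cfg.asper_scale
        * cfg.calibration_factor
        * (cfg.modulation_frequency / 1000.0)
        * integral
    )


def roughness_series(rec: SoundRecording, cfg: RoughnessConfig | None = None):
    """Block-wise roughness of a recording.

    200-ms blocks with 50% overlap (>= 14 modulation periods at 70 Hz);
    returns (block_center_times, roughness_asper).
    """
    cfg = cfg or RoughnessConfig()
    levels, env_rate = critical_band_level_envelopes(rec)
    fluct = _modulation_bandpass(levels, env_rate, cfg.modulation_frequency)
    blk = int(round(cfg.block_length * env_rate))
    hop = max(int(round(blk * (1.0 - cfg.block_overlap))), 1)
    n = fluct.shape[1]
    if n < blk:
        raise ValueError("recording shorter than one roughness analysis block")
    starts = np.arange(0, n - blk + 1, hop)
    times = (starts + blk / 2.0) / env_rate
    vals = np.array(
        [roughness_from_envelopes(fluct[:, s : s + blk], env_rate, cfg) for s in starts]
    )
    return times, vals


def roughness(rec: SoundRecording, cfg: RoughnessConfig | None = None) -> float:
    """Single roughness value of a (quasi-)stationary recording: the median
    over analysis blocks, robust to filter transients at the edges."""
    _, vals = roughness_series(rec, cfg)
    return float(np.median(vals))


def calibrate_asper_scale() -> float:
    """Recompute the one-time asper calibration scalar from the reference
    signal (1 kHz, 60 dB SPL, 100% AM at 70 Hz).  Used once at development
    time to freeze ROUGHNESS_ASPER_SCALE; exposed for auditability."""
    from .synthetic_data import gen_am_tone

    tone = gen_am_tone()
    cfg = RoughnessConfig(asper_scale=1.0)
    raw = roughness(tone, cfg)
    return 1.0 / raw


# --------------------------------------------------------------------------
# Combined feature series
# --------------------------------------------------------------------------


@dataclass
class FeatureSeries:
    """Loudness (sone) and roughness (asper) on a common time grid."""

    times: np.ndarray
    loudness: np.ndarray
    roughness: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.loudness = np.asarray(self.loudness, dtype=float)
        self.roughness = np.asarray(self.roughness, dtype=float)
        if not (self.times.size == self.loudness.size == self.roughness.size):
            raise ValueError("times, loudness, roughness must have equal lengths")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.loudness < 0) or np.any(self.roughness < 0):
            raise ValueError("loudness and roughness must be nonnegative")

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.loudness, self.roughness]),
            delimiter=",",
            header="time_s,loudness_sone,roughness_asper",
            comments="",
        )

    @classmethod
    def from_csv(cls, path) -> "FeatureSeries":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2])


def feature_series(
    rec: SoundRecording,
    stft_cfg: STFTConfig | None = None,
    r_cfg: RoughnessConfig | None = None,
    loudness_smoothing: float = 0.05,
) -> FeatureSeries:
    """Loudness and roughness time series of a recording on one grid.

    Loudness is computed frame-by-frame from the STFT and smoothed with a
    50-ms exponential filter; roughness is computed block-wise and linearly
    interpolated onto the loudness frame times (restricted to the
    intersection of supports).
    """
    stft_cfg = stft_cfg or STFTConfig()
    r_cfg = r_cfg or RoughnessConfig()
    spec = stft(rec, stft_cfg)
    loud = frame_loudness(spec)
    dt = float(np.median(np.diff(spec.frame_times))) if spec.n_frames > 1 else 0.0
    loud = _exp_smooth(loud, dt, loudness_smoothing)
    r_times, r_vals = roughness_series(rec, r_cfg)
    t0, t1 = max(spec.frame_times[0], r_times[0]), min(spec.frame_times[-1], r_times[-1])
    keep = (spec.frame_times >= t0) & (spec.frame_times <= t1)
    if not np.any(keep):
        # Degenerate short recording: fall back to the loudness grid with
        # the nearest roughness value.
        keep = np.ones_like(keep)
    times = spec.frame_times[keep]
    rough = np.interp(times, r_times, r_vals)
    return FeatureSeries(times, np.maximum(loud[keep], 0.0), np.maximum(rough, 0.0))
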