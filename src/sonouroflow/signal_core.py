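"""Sound I/O, windowing and short-time Fourier analysis of voiding recordings.

Conventions (fixed, documented):

* spectra are one-sided (``fft_size // 2 + 1`` bins), 0-based bin indexing;
* each frame is time-stamped at its window *center*;
* sound-pressure levels are expressed in dB re 20 uPa.  Recordings that are
  not absolutely calibrated carry a user-supplied ``calibration_offset`` in
  dB (default 0, i.e. a sample value of 1 Pa RMS maps to 94 dB SPL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.io import wavfile

#: Reference sound pressure, 20 uPa (threshold of hearing at 1 kHz).
P_REF = 2e-5

#: Floor applied before taking logs of pressure amplitudes.
_EPS = 1e-12

#: Default sample rate for synthetic audio; covers the Bark range to
#: 24 Bark (~15.5 kHz) with margin.
DEFAULT_SAMPLE_RATE = 48_000


@dataclass
class SoundRecording:
    """A mono, finite sound-pressure recording.

    Parameters
    ----------
    samples:
        Sound pressure in pascals (or digital full-scale units when
        uncalibrated; see ``calibration_offset``).
    sample_rate:
        Sampling rate in Hz, strictly positive.
    calibration_offset:
        dB added to every computed level to map the digital scale onto
        absolute dB SPL.  0 dB means samples are interpreted as pascals.
    """

    samples: np.ndarray
    sample_rate: float
    calibration_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("recording must be mono (1-D samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.samples.size / self.sample_rate

    @classmethod
    def from_wav(cls, path, calibration_offset: float = 0.0) -> "SoundRecording":
        """Read a mono WAV file (PCM 16/24/32-bit or float).

        Integer PCM is rescaled to [-1, 1] full scale.
        """
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise ValueError("multi-channel WAV not supported; mono required")
        if np.issubdtype(data.dtype, np.integer):
            scale = float(np.iinfo(data.dtype).max) + 1.0
            data = data.astype(float) / scale
        else:
            data = data.astype(float)
        return cls(data, float(rate), calibration_offset)

    def to_wav(self, path) -> None:
        """Write the recording as 32-bit float WAV."""
        wavfile.write(path, int(round(self.sample_rate)), self.samples.astype(np.float32))


@dataclass
class STFTConfig:
    """Short-time Fourier transform settings.

    Defaults follow the analysis settings used throughout the pipeline:
    4096-point FFT, window length equal to the FFT size, 25% overlap,
    Hanning window.
    """

    fft_size: int = 4096
    window_length: int | None = None
    overlap_fraction: float = 0.25
    window: str = "hann"  # "hann" or "rect"

    def __post_init__(self) -> None:
        if self.window_length is None:
            self.window_length = self.fft_size
        if self.window_length > self.fft_size:
            raise ValueError("window_length must be <= fft_size")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window not in ("hann", "rect"):
            raise ValueError("window must be 'hann' or 'rect'")

    @property
    def hop(self) -> int:
        """Frame advance in samples: m * (1 - overlap)."""
        h = int(round(self.window_length * (1.0 - self.overlap_fraction)))
        return max(h, 1)

    def window_values(self) -> np.ndarray:
        if self.window == "hann":
            return hanning_window(self.window_length)
        return np.ones(self.window_length)


@dataclass
class Spectrogram:
    """One-sided complex spectrogram with calibrated per-bin levels.

    ``values`` has shape (n_bins, n_frames) with n_bins = fft_size/2 + 1.
    ``level_db`` holds the per-bin, per-frame RMS sound-pressure level in
    dB re 20 uPa (including any calibration offset).
    """

    values: np.ndarray
    frame_times: np.ndarray
    bin_freqs: np.ndarray
    level_db: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.bin_freqs.size:
            raise ValueError("bin count mismatch")
        if self.values.shape[1] != self.frame_times.size:
            raise ValueError("frame count mismatch")
        if self.frame_times.size > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frame_times.size

    def save_npz(self, path) -> None:
        """Write to a self-describing .npz container."""
        np.savez(
            path,
            values=self.values,
            frame_times=self.frame_times,
            bin_freqs=self.bin_freqs,
            level_db=self.level_db,
        )

    @classmethod
    def load_npz(cls, path) -> "Spectrogram":
        with np.load(path) as z:
            return cls(
                values=z["values"],
                frame_times=z["frame_times"],
                bin_freqs=z["bin_freqs"],
                level_db=z["level_db"],
            )


def hanning_window(m: int) -> np.ndarray:
    """Periodic Hanning window w(n) = 0.5*(1 - cos(2*pi*n/m)), n = 0..m-1.

    Used for spectral-leakage reduction before the short-time Fourier
    transform.  Nonnegative, peak value 1 (m even), symmetric about m/2.
    """
    if m < 2:
        raise ValueError("window length must be >= 2")
    n = np.arange(m)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * n / m))


def stft(rec: SoundRecording, cfg: STFTConfig) -> Spectrogram:
    """One-sided short-time Fourier transform of a voiding recording.

    Frames advance by ``cfg.hop`` samples; frame k covers samples
    [k*hop, k*hop + m) and is stamped at the window center.  Per-bin levels
    are single-component RMS levels: the windowed DFT magnitude is rescaled
    by 2/sum(w) (1/sum(w) for DC and Nyquist) so that a full-scale sine
    yields its physical RMS pressure, then expressed in dB re 20 uPa plus
    the recording's calibration offset.
    """
    m = cfg.window_length
    x = rec.samples
    if x.size < m:
        raise ValueError("recording shorter than one analysis window")
    hop = cfg.hop
    frames = sliding_window_view(x, m)[::hop]  # (n_frames, m)
    w = cfg.window_values()
    X = np.fft.rfft(frames * w, n=cfg.fft_size, axis=1).T  # (n_bins, n_frames)

    n_frames = frames.shape[0]
    frame_times = (np.arange(n_frames) * hop + m / 2.0) / rec.sample_rate
    bin_freqs = np.fft.rfftfreq(cfg.fft_size, d=1.0 / rec.sample_rate)

    wsum = w.sum()
    amp = np.abs(X) * (2.0 / wsum)
    amp[0] /= 2.0
    if cfg.fft_size % 2 == 0:
        amp[-1] /= 2.0
    rms = amp / np.sqrt(2.0)
    level_db = 20.0 * np.log10(np.maximum(rms, _EPS) / P_REF) + rec.calibration_offset
    return Spectrogram(values=X, frame_times=frame_times, bin_freqs=bin_freqs, level_db=level_db)


def istft(spec: Spectrogram, cfg: STFTConfig) -> np.ndarray:
    """Overlap-add inverse of :func:`stft` (analysis-convention sanity check).

    Reconstructs the interior of the original signal (edges are attenuated
    where window overlap is incomplete).
    """
    m = cfg.window_length
    hop = cfg.hop
    w = cfg.window_values()
    frames = np.fft.irfft(spec.values.T, n=cfg.fft_size, axis=1)[:, :m]
    n = hop * (spec.n_frames - 1) + m
    out = np.zeros(n)
    norm = np.zeros(n)
    for k in range(spec.n_frames):
        sl = slice(k * hop, k * hop + m)
        out[sl] += frames[k] * w
        norm[sl] += w * w
    good = norm > 1e-8
    out[good] /= norm[good]
    return out
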