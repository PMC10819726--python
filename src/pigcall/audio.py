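"""WAV input/output and signal conditioning for vocalization clips.

A clip is a short, pre-cut mono recording containing one vocalization.
This module handles reading/writing 16-bit PCM WAV, pre-emphasis,
framing/windowing, and an optional spectral noise gate for recordings
made in noisy barns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, istft, stft

__all__ = [
    "AudioClip",
    "FrameSequence",
    "DenoiseConfig",
    "ValidationError",
    "read_wav",
    "write_wav",
    "pre_emphasize",
    "frame_signal",
    "spectral_noise_gate",
]

CLASS_NAMES = ("grunt", "squeal", "cough")


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class AudioClip:
    """Labeled mono waveform; the unit of classification.

    Parameters
    ----------
    samples : ndarray
        Mono waveform, float values in [-1, 1].
    sample_rate : int
        Sampling frequency in Hz (canonical recordings use 44100).
    label : str, optional
        One of ``grunt``, ``squeal``, ``cough``.
    id : str
        Clip identifier, used in feature tables and file names.
    """

    samples: np.ndarray
    sample_rate: int
    label: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValidationError("clip must contain a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("clip contains non-finite samples")
        if not (isinstance(self.sample_rate, (int, np.integer)) and self.sample_rate > 0):
            raise ValidationError("sample_rate must be a positive integer")
        if self.label is not None and self.label not in CLASS_NAMES:
            raise ValidationError(f"unknown label {self.label!r}; expected one of {CLASS_NAMES}")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def replace_samples(self, samples: np.ndarray) -> "AudioClip":
        return AudioClip(samples=samples, sample_rate=self.sample_rate, label=self.label, id=self.id)


@dataclass
class FrameSequence:
    """Equal-length analysis frames cut from one clip.

    Frames store the *raw* signal segments; the window is recorded here
    and applied by consumers (energy, spectra) so that both windowed and
    unwindowed views remain available.
    """

    frames: np.ndarray  # K x frame_length
    frame_length: int
    hop: int
    window_name: str = "hamming"
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        if self.frames.shape[1] != self.frame_length:
            raise ValidationError("every frame must have exactly frame_length samples")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def window(self) -> np.ndarray:
        if self.window_name == "rectangular":
            return np.ones(self.frame_length)
        return get_window(self.window_name, self.frame_length, fftbins=False)

    @property
    def windowed(self) -> np.ndarray:
        return self.frames * self.window


@dataclass
class DenoiseConfig:
    """Spectral noise-gate settings, mirroring adaptive-reduction presets.

    reduction_db: attenuation applied to gated bins, dB (>= 0).
    amount: fraction of the reduction actually applied, in [0, 1].
    snr_threshold_db: margin above the noise estimate below which a bin
        is considered noise.
    """

    reduction_db: float = 20.0
    amount: float = 0.8
    snr_threshold_db: float = 3.0

    def __post_init__(self) -> None:
        if self.reduction_db < 0:
            raise ValidationError("reduction_db must be >= 0")
        if not 0.0 <= self.amount <= 1.0:
            raise ValidationError("amount must lie in [0, 1]")


def read_wav(path: str | Path) -> AudioClip:
    """Read a PCM WAV file into an :class:`AudioClip`.

    Integer samples are scaled to [-1, 1] by the type's full scale;
    multi-channel audio is mean-downmixed to mono.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sample_rate, data = wavfile.read(path)
    if data.size == 0:
        raise ValidationError(f"{path} contains no audio samples")
    if data.ndim > 1:
        data = data.astype(np.float64).mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        # divide by the positive full scale, matching write_wav's rounding
        samples = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        samples = data.astype(np.float64)
    return AudioClip(samples=samples, sample_rate=int(sample_rate), id=path.stem)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM WAV."""
    scaled = np.clip(clip.samples, -1.0, 1.0)
    data = np.round(scaled * 32767.0).astype(np.int16)
    wavfile.write(Path(path), clip.sample_rate, data)


def pre_emphasize(clip: AudioClip, alpha: float = 0.97) -> AudioClip:
    """First-order high-pass: y[n] = x[n] - alpha * x[n-1], y[0] = x[0]."""
    if not 0.0 <= alpha < 1.0:
        raise ValidationError("pre-emphasis coefficient must satisfy 0 <= alpha < 1")
    x = clip.samples
    y = np.empty_like(x)
    y[0] = x[0]
    y[1:] = x[1:] - alpha * x[:-1]
    return clip.replace_samples(y)


def frame_signal(
    clip: AudioClip,
    frame_length: int,
    hop: int,
    window_name: str = "hamming",
) -> FrameSequence:
    """Cut the clip into K = floor((L - frame_length)/hop) + 1 frames."""
    if hop < 1:
        raise ValidationError("hop must be >= 1 sample")
    x = clip.samples
    if frame_length > len(x):
        raise ValidationError(
            f"clip of {len(x)} samples shorter than one frame ({frame_length})"
        )
    n_frames = (len(x) - frame_length) // hop + 1
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    return FrameSequence(
        frames=x[idx],
        frame_length=frame_length,
        hop=hop,
        window_name=window_name,
        sample_rate=clip.sample_rate,
    )


def spectral_noise_gate(
    clip: AudioClip,
    noise_profile: AudioClip | None = None,
    cfg: DenoiseConfig | None = None,
    n_fft: int = 2048,
) -> AudioClip:
    """Attenuate spectrogram bins that sit near the noise floor.

    A per-frequency noise ceiling is estimated either from an explicit
    noise-only profile clip or, when ``noise_profile`` is None, from the
    lowest-energy 10% of the clip's own STFT frames; the per-bin maximum
    over those frames is used so that fluctuating noise stays under the
    gate.  Bins whose magnitude falls below ceiling + ``snr_threshold_db``
    are attenuated by ``amount * reduction_db`` dB; louder bins pass
    unchanged, so the gate never adds energy.
    """
    cfg = cfg or DenoiseConfig()
    hop = n_fft // 4
    if len(clip.samples) < n_fft:
        raise ValidationError("clip shorter than one analysis frame")

    freqs, times, spec = stft(clip.samples, fs=clip.sample_rate, nperseg=n_fft, noverlap=n_fft - hop)
    mag = np.abs(spec)

    if noise_profile is not None:
        if noise_profile.sample_rate != clip.sample_rate:
            raise ValidationError("noise profile sample rate must match the clip")
        if len(noise_profile.samples) < n_fft:
            raise ValidationError("noise profile shorter than one analysis frame")
        _, _, noise_spec = stft(
            noise_profile.samples, fs=clip.sample_rate, nperseg=n_fft, noverlap=n_fft - hop
        )
        noise_mag = np.abs(noise_spec).max(axis=1)
    else:
        frame_energy = (mag**2).sum(axis=0)
        n_low = max(1, int(np.ceil(0.1 * mag.shape[1])))
        quiet = np.argsort(frame_energy)[:n_low]
        noise_mag = mag[:, quiet].max(axis=1)

    threshold = noise_mag[:, None] * 10.0 ** (cfg.snr_threshold_db / 20.0)
    attenuation = 10.0 ** (-(cfg.amount * cfg.reduction_db) / 20.0)
    gain = np.where(mag < threshold, attenuation, 1.0)

    _, cleaned = istft(spec * gain, fs=clip.sample_rate, nperseg=n_fft, noverlap=n_fft - hop)
    out = np.zeros(len(clip.samples))
    m = min(len(out), len(cleaned))
    out[:m] = cleaned[:m]
    return clip.replace_samples(out)
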