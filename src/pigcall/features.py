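"""Acoustic feature extraction: the 33-dimensional fused clip descriptor.

Per clip the pipeline computes

* short-time energy (STE), averaged over frames (1 value);
* frequency centroid averaged over frames, FC_avg (1 value);
* four formant frequencies FF-1..FF-4 from an all-pole model, plus the
  three first-order differences dFF-21/32/43 (7 values);
* 12 static MFCC (DCT coefficients 2..13 of the log mel spectrum) and
  12 first-order difference coefficients, each averaged over frames
  (24 values).

The flattened order is fixed:
``[STE, FC, FF1..FF4, dFF21, dFF32, dFF43, MFCC1..12, dMFCC1..12]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct, rfft, rfftfreq
from scipy.signal import resample_poly

from .audio import AudioClip, FrameSequence, ValidationError, frame_signal, pre_emphasize

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "MelFilterbank",
    "FEATURE_NAMES",
    "short_time_energy",
    "clip_ste",
    "frequency_centroid_frame",
    "fc_avg",
    "estimate_formants",
    "formant_differences",
    "hz_to_mel",
    "mel_to_hz",
    "build_mel_filterbank",
    "mfcc_static",
    "delta_coefficients",
    "extract_features",
    "features_to_frame",
    "write_feature_csv",
    "read_feature_csv",
]

FEATURE_NAMES: tuple[str, ...] = (
    "ste",
    "fc",
    "ff1",
    "ff2",
    "ff3",
    "ff4",
    "dff21",
    "dff32",
    "dff43",
    *[f"mfcc{i}" for i in range(1, 13)],
    *[f"dmfcc{i}" for i in range(1, 13)],
)


@dataclass
class FeatureConfig:
    """Analysis settings shared by all feature extractors.

    frame_ms / hop_ms / window: short-time analysis grid (25/10 ms,
    Hamming — standard speech-analysis values).
    preemphasis: first-order high-pass coefficient.
    n_fft: FFT length for spectra (frames are zero-padded).
    n_mels / n_mfcc: mel filterbank size and retained cepstral count.
    max_formant_hz / lpc_order / formant_bandwidth_hz: all-pole formant
    settings (working rate 2 * max_formant_hz, order-14 prediction to
    resolve four resonances plus source tilt, 400 Hz bandwidth cutoff).
    voiced_energy_frac: frames below this fraction of the loudest frame's
    energy are excluded from formant voting.
    """

    frame_ms: float = 25.0
    hop_ms: float = 10.0
    window: str = "hamming"
    preemphasis: float = 0.97
    n_fft: int = 2048
    n_mels: int = 26
    n_mfcc: int = 12
    log_floor: float = 1e-10
    max_formant_hz: float = 5500.0
    lpc_order: int = 14
    formant_bandwidth_hz: float = 400.0
    min_formant_hz: float = 90.0
    voiced_energy_frac: float = 0.1
    min_vote_frac: float = 0.2

    def frame_length(self, sample_rate: int) -> int:
        return int(round(self.frame_ms * sample_rate / 1000.0))

    def hop(self, sample_rate: int) -> int:
        return max(1, int(round(self.hop_ms * sample_rate / 1000.0)))

    def frame(self, clip: AudioClip) -> FrameSequence:
        return frame_signal(
            clip,
            frame_length=self.frame_length(clip.sample_rate),
            hop=self.hop(clip.sample_rate),
            window_name=self.window,
        )


@dataclass
class FeatureVector:
    """The fused 33-dimensional descriptor of one clip."""

    ste: float
    fc_avg: float
    ff: np.ndarray  # 4 ascending formant frequencies, Hz
    dff: np.ndarray  # 3 first-order formant differences, Hz
    mfcc: np.ndarray  # 12 clip-averaged static coefficients
    dmfcc: np.ndarray  # 12 clip-averaged delta coefficients
    label: str | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.ff = np.asarray(self.ff, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        self.mfcc = np.asarray(self.mfcc, dtype=float)
        self.dmfcc = np.asarray(self.dmfcc, dtype=float)
        if self.ff.shape != (4,) or self.dff.shape != (3,):
            raise ValidationError("expected 4 formants and 3 differences")
        if self.mfcc.shape != (12,) or self.dmfcc.shape != (12,):
            raise ValidationError("expected 12 MFCC and 12 delta-MFCC values")
        if not np.all(np.isfinite(self.as_array())):
            raise ValidationError("feature vector contains non-finite values")

    def as_array(self) -> np.ndarray:
        """Flatten in the documented order; always 33 values."""
        return np.concatenate(
            [[self.ste, self.fc_avg], self.ff, self.dff, self.mfcc, self.dmfcc]
        )


# ---------------------------------------------------------------------------
# time-domain / spectral frame features


def short_time_energy(fs: FrameSequence) -> np.ndarray:
    """Per-frame energy: E(n) = sum over the frame of (x * w)^2."""
    return (fs.windowed**2).sum(axis=1)


def clip_ste(fs: FrameSequence) -> float:
    """Clip-level STE: arithmetic mean of the per-frame energies."""
    return float(short_time_energy(fs).mean())


def frequency_centroid_frame(
    frame: np.ndarray, sample_rate: int, n_fft: int | None = None
) -> float:
    """Power-weighted mean frequency of one (already windowed) frame.

    Returns NaN for an all-zero frame, which callers exclude from the
    clip average.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.any(frame):
        return float("nan")
    n_fft = n_fft or len(frame)
    power = np.abs(rfft(frame, n=n_fft)) ** 2
    freqs = rfftfreq(n_fft, d=1.0 / sample_rate)
    return float((freqs * power).sum() / power.sum())


def fc_avg(fs: FrameSequence, n_fft: int | None = None) -> float:
    """Mean frequency centroid over the valid (non-silent) frames."""
    values = np.array(
        [frequency_centroid_frame(f, fs.sample_rate, n_fft=n_fft) for f in fs.windowed]
    )
    valid = values[np.isfinite(values)]
    if valid.size == 0:
        raise ValidationError("no non-silent frames: frequency centroid undefined")
    return float(valid.mean())


# ---------------------------------------------------------------------------
# formants


def _lpc_autocorrelation(x: np.ndarray, order: int) -> np.ndarray:
    """All-pole coefficients a[1..p] by the autocorrelation (Levinson) method.

    Returns the full polynomial [1, a1, ..., ap] of A(z); the model is
    x[n] ~ -sum a_k x[n-k].
    """
    r = np.correlate(x, x, mode="full")[len(x) - 1 : len(x) + order]
    if r[0] <= 0:
        raise ValidationError("zero-energy frame has no all-pole model")
    a = np.zeros(order + 1)
    a[0] = 1.0
    err = r[0]
    for i in range(1, order + 1):
        acc = r[i] + a[1:i] @ r[i - 1 : 0 : -1]
        k = -acc / err
        a[1 : i + 1] = a[1 : i + 1] + k * a[i - 1 :: -1][: i]
        err *= 1.0 - k * k
        if err <= 0:
            break
    return a


def _frame_formants(frame: np.ndarray, sample_rate: int, cfg: FeatureConfig) -> np.ndarray:
    """Formant candidates of one frame: pole angles of the LP polynomial.

    Keeps positive-frequency roots inside the admissible band whose
    bandwidth is below the cutoff; returns them sorted ascending.
    """
    a = _lpc_autocorrelation(frame, cfg.lpc_order)
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * sample_rate / (2.0 * np.pi)
    with np.errstate(divide="ignore"):
        bandwidths = -np.log(np.abs(roots)) * sample_rate / np.pi
    keep = (
        (freqs > cfg.min_formant_hz)
        & (freqs < sample_rate / 2.0 - cfg.min_formant_hz)
        & (bandwidths < cfg.formant_bandwidth_hz)
    )
    return np.sort(freqs[keep])


def estimate_formants(clip: AudioClip, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Estimate the clip's four formant frequencies FF-1..FF-4 (Hz).

    The clip is resampled to twice the maximum formant frequency,
    pre-emphasized, and framed; each energetic frame contributes the
    first four stable all-pole resonances, and the clip value is the
    per-formant median over contributing frames.
    """
    cfg = cfg or FeatureConfig()
    target_rate = int(round(2 * cfg.max_formant_hz))
    if clip.sample_rate != target_rate:
        g = np.gcd(clip.sample_rate, target_rate)
        resampled = resample_poly(clip.samples, target_rate // g, clip.sample_rate // g)
        work = AudioClip(resampled, target_rate, label=clip.label, id=clip.id)
    else:
        work = clip

    frame_length = cfg.frame_length(target_rate)
    if len(work.samples) < 2 * frame_length:
        raise ValidationError("clip too short for formant analysis (need >= 2 frames)")
    fs = cfg.frame(pre_emphasize(work, cfg.preemphasis))

    energies = short_time_energy(fs)
    energetic = energies >= cfg.voiced_energy_frac * energies.max()
    votes = []
    for frame in fs.windowed[energetic]:
        cand = _frame_formants(frame, target_rate, cfg)
        if len(cand) >= 4:
            votes.append(cand[:4])
    # a clip without consistent resonance structure (e.g. plain noise)
    # yields stable pole sets in only a small minority of frames
    if not votes or len(votes) < cfg.min_vote_frac * int(energetic.sum()):
        raise ValidationError(
            "formant tracks unstable: too few frames with 4 stable resonances "
            f"({len(votes)}/{int(energetic.sum())} energetic frames)"
        )
    return np.median(np.asarray(votes), axis=0)


def formant_differences(ff: np.ndarray) -> np.ndarray:
    """First-order formant differences (FF2-FF1, FF3-FF2, FF4-FF3)."""
    ff = np.asarray(ff, dtype=float)
    if ff.shape != (4,):
        raise ValidationError("expected exactly 4 formant frequencies")
    if np.any(np.diff(ff) <= 0):
        raise ValidationError("formant frequencies must be strictly ascending")
    return np.diff(ff)


# ---------------------------------------------------------------------------
# MFCC


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


@dataclass
class MelFilterbank:
    """Triangular mel bandpass filters over one-sided FFT bins."""

    n_filters: int
    n_fft: int
    sample_rate: int
    filters: np.ndarray = field(repr=False)  # n_filters x (n_fft//2 + 1)

    def apply(self, magnitude: np.ndarray) -> np.ndarray:
        """Filter a (frames x bins) magnitude spectrum into mel energies."""
        return magnitude @ self.filters.T


def build_mel_filterbank(n_filters: int, n_fft: int, sample_rate: int) -> MelFilterbank:
    """Triangular filters with centers uniform on the mel scale, 0..Nyquist."""
    if n_filters < 13:
        raise ValidationError("need at least 13 mel filters for 12 cepstral coefficients")
    if n_fft & (n_fft - 1):
        raise ValidationError("n_fft must be a power of two")
    mel_points = np.linspace(0.0, hz_to_mel(sample_rate / 2.0), n_filters + 2)
    hz_points = np.asarray(mel_to_hz(mel_points))
    bin_freqs = rfftfreq(n_fft, d=1.0 / sample_rate)
    filters = np.zeros((n_filters, len(bin_freqs)))
    for i in range(n_filters):
        left, center, right = hz_points[i : i + 3]
        up = (bin_freqs - left) / (center - left)
        down = (right - bin_freqs) / (right - center)
        filters[i] = np.maximum(0.0, np.minimum(up, down))
        if not filters[i].any():
            raise ValidationError(
                f"mel filter {i} covers no FFT bin: n_fft too small for {n_filters} filters"
            )
    return MelFilterbank(n_filters=n_filters, n_fft=n_fft, sample_rate=sample_rate, filters=filters)


def mfcc_static(clip: AudioClip, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Per-frame static MFCC matrix (K x 12).

    Chain: pre-emphasis, framing + Hamming window, FFT magnitude, mel
    filterbank, log energies (floored), DCT-II (orthonormal); the 2nd to
    13th coefficients are kept, dropping the overall-level 1st.
    """
    cfg = cfg or FeatureConfig()
    fs = cfg.frame(pre_emphasize(clip, cfg.preemphasis))
    fb = build_mel_filterbank(cfg.n_mels, cfg.n_fft, clip.sample_rate)
    magnitude = np.abs(rfft(fs.windowed, n=cfg.n_fft, axis=1))
    mel_energy = fb.apply(magnitude)
    log_energy = np.log(np.maximum(mel_energy, cfg.log_floor))
    cepstra = dct(log_energy, type=2, norm="ortho", axis=1)
    return cepstra[:, 1 : cfg.n_mfcc + 1]


def delta_coefficients(static: np.ndarray) -> np.ndarray:
    """Adjacent-frame first difference; the first delta row is zero."""
    static = np.atleast_2d(np.asarray(static, dtype=float))
    delta = np.zeros_like(static)
    delta[1:] = static[1:] - static[:-1]
    return delta


# ---------------------------------------------------------------------------
# assembly


def extract_features(clip: AudioClip, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Compute the fused 33-dimensional feature vector for one clip."""
    cfg = cfg or FeatureConfig()
    fs = cfg.frame(clip)
    ff = estimate_formants(clip, cfg)
    static = mfcc_static(clip, cfg)
    return FeatureVector(
        ste=clip_ste(fs),
        fc_avg=fc_avg(fs, n_fft=cfg.n_fft),
        ff=ff,
        dff=formant_differences(ff),
        mfcc=static.mean(axis=0),
        dmfcc=delta_coefficients(static).mean(axis=0),
        label=clip.label,
        id=clip.id,
    )


def features_to_frame(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into the canonical table (one row per clip)."""
    rows = []
    for v in vectors:
        row = {"id": v.id, "label": v.label}
        row.update(dict(zip(FEATURE_NAMES, v.as_array())))
        rows.append(row)
    return pd.DataFrame(rows, columns=["id", "label", *FEATURE_NAMES])


def write_feature_csv(path, vectors: list[FeatureVector]) -> None:
    features_to_frame(vectors).to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("id", "label", *FEATURE_NAMES) if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    return df
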