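"""Multi-channel heart-signal feature extraction.

The extractor turns one PCG recording into a stack of equal-shape log-mel
spectrogram channels plus scalar side features. The boundary pipeline runs in
six stages: (1) amplitude normalization to [-1, 1], (2) zero-phase Butterworth
low-pass at 150 Hz, (3) Hilbert envelope, (4) threshold selection at
mean + population std of the envelope, (5) thresholding into a binary
fundamental-heart-sound (FHS) mask separating S1/S2 lobes from the systolic/
diastolic remainder, (6) log-mel spectrograms of the separated envelope
channels. A causal moving-average smoother can be applied to the envelope
before thresholding, which stabilizes the murmur channel on noisy signals.

Channel order in the output tensor is fixed:
``spec, s1s2, murmurs, envelope, s_s1s2, s_murmurs, s_envelope``
(enabled subset, in that order), where ``spec`` is the log-mel of the
normalized raw signal, the middle channels derive from the raw envelope, and
the ``s_``-prefixed channels derive from the smoothed envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .io_formats import PcgRecording

__all__ = [
    "MelConfig",
    "SmoothingConfig",
    "BoundaryConfig",
    "EnvelopeSignal",
    "BoundaryMask",
    "FeatureSet",
    "FeatureTensor",
    "FEATURE_IDS",
    "normalize_amplitude",
    "butterworth_lowpass",
    "hilbert_envelope",
    "smooth",
    "compute_threshold",
    "detect_fhs_boundaries",
    "split_channels",
    "mel_scale",
    "mel_inverse",
    "mel_filterbank",
    "log_mel_spectrogram",
    "mean_peak_interval",
    "fix_duration",
    "build_feature_tensor",
    "MCHeartFeaturizer",
]


@dataclass(frozen=True)
class MelConfig:
    """Log-mel spectrogram parameters (STFT framing + mel filterbank)."""

    window: int = 512
    hop: int = 256
    n_mels: int = 140
    rate: int = 4000
    fmin: float = 0.0
    fmax: float | None = None  # None -> Nyquist
    ref_mode: str = "max"  # "max": dB relative to the global maximum
    ref_value: float = 1.0  # used when ref_mode == "fixed"
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.hop > self.window:
            raise ValueError("hop must not exceed window")
        if self.n_mels < 1:
            raise ValueError("n_mels must be >= 1")
        if self.ref_mode not in ("max", "fixed"):
            raise ValueError("ref_mode must be 'max' or 'fixed'")


@dataclass(frozen=True)
class SmoothingConfig:
    """Causal moving-average window size (samples)."""

    window_size: int = 70

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass(frozen=True)
class BoundaryConfig:
    """Cleanup applied to the thresholded FHS mask.

    Mask runs shorter than ``min_run_s`` are discarded and zero-gaps shorter
    than ``max_gap_s`` are filled (gaps first), removing speckle that raw
    thresholding of a noisy envelope produces. Both default to a fraction of
    an S1 lobe; set to 0 to disable.
    """

    min_run_s: float = 0.02
    max_gap_s: float = 0.01


@dataclass
class EnvelopeSignal:
    """Nonnegative instantaneous-amplitude signal."""

    values: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


@dataclass
class BoundaryMask:
    """Binary FHS mask aligned to the envelope samples (1 = S1/S2)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        self.mask = self.mask.astype(np.float64)


@dataclass(frozen=True)
class FeatureSet:
    """Which channels and side features to extract (one row of the feature
    combination table; see :data:`FEATURE_IDS`)."""

    spec: bool = True
    pi: bool = True
    s1s2: bool = False
    murmurs: bool = False
    envelope: bool = False
    s_s1s2: bool = False
    s_murmurs: bool = False
    s_envelope: bool = False
    trim: int = 0
    sample_sec: float = 50.0

    def __post_init__(self) -> None:
        if not any(
            (self.spec, self.s1s2, self.murmurs, self.envelope,
             self.s_s1s2, self.s_murmurs, self.s_envelope)
        ):
            raise ValueError("at least one spectrogram channel must be enabled")

    @property
    def channel_names(self) -> list[str]:
        order = ("spec", "s1s2", "murmurs", "envelope",
                 "s_s1s2", "s_murmurs", "s_envelope")
        return [name for name in order if getattr(self, name)]


#: Feature combinations by id. Id 2 (demographic features) is intentionally
#: not provided; ids 11 and 12 drop the peak-interval scalar.
FEATURE_IDS: dict[int, FeatureSet] = {
    1: FeatureSet(),
    3: FeatureSet(s1s2=True, murmurs=True),
    4: FeatureSet(s1s2=True),
    5: FeatureSet(murmurs=True),
    6: FeatureSet(envelope=True),
    7: FeatureSet(s_s1s2=True, s_murmurs=True),
    8: FeatureSet(s_s1s2=True),
    9: FeatureSet(s_murmurs=True),
    10: FeatureSet(s_envelope=True),
    11: FeatureSet(pi=False, s1s2=True, murmurs=True),
    12: FeatureSet(pi=False, s_murmurs=True),
}


@dataclass
class FeatureTensor:
    """Stacked equal-shape log-mel channels plus named scalar features."""

    channels: np.ndarray  # (n_channels, n_mels, n_frames)
    channel_names: list[str]
    scalars: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3:
            raise ValueError("channels must be (n_channels, n_mels, n_frames)")
        if len(self.channel_names) != self.channels.shape[0]:
            raise ValueError("one name per channel required")
        if len(set(self.scalars)) != len(self.scalars):
            raise ValueError("scalar names must be unique")


# ---------------------------------------------------------------------------
# Stage operations


def normalize_amplitude(signal: np.ndarray) -> np.ndarray:
    """Scale by the maximum absolute amplitude, mapping into [-1, 1]."""
    x = np.asarray(signal, dtype=np.float64)
    peak = np.max(np.abs(x)) if x.size else 0.0
    if peak == 0.0:
        raise ValueError("cannot normalize an all-zero signal")
    return x / peak


def butterworth_lowpass(
    signal: np.ndarray, cutoff_hz: float = 150.0, order: int = 2, rate: int = 4000
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    if not 0 < cutoff_hz < rate / 2:
        raise ValueError(f"cutoff must lie in (0, Nyquist={rate / 2}), got {cutoff_hz}")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=np.float64))


def hilbert_envelope(signal: np.ndarray, rate: int) -> EnvelopeSignal:
    """Magnitude of the analytic signal (nonnegative everywhere)."""
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples for an analytic signal")
    return EnvelopeSignal(values=np.abs(sps.hilbert(x)), rate=rate)


def smooth(signal: np.ndarray, cfg: SmoothingConfig | int = SmoothingConfig()) -> np.ndarray:
    """Causal moving average with zero-padded history; same length as input.

    ``y[n] = (1/N) * sum_{m=0}^{N-1} x[n-m]`` with ``x[k] = 0`` for k < 0, so
    the first N-1 outputs ramp up from the zero history; N=1 is the identity.
    """
    n = cfg.window_size if isinstance(cfg, SmoothingConfig) else int(cfg)
    if n < 1:
        raise ValueError("smoothing window must be >= 1")
    x = np.asarray(signal, dtype=np.float64)
    return np.convolve(x, np.full(n, 1.0 / n), mode="full")[: x.size]


def compute_threshold(env: EnvelopeSignal | np.ndarray) -> float:
    """FHS detection threshold: mean plus population standard deviation."""
    v = env.values if isinstance(env, EnvelopeSignal) else np.asarray(env, float)
    return float(np.mean(v) + np.std(v, ddof=0))


def _fill_runs(mask: np.ndarray, value: bool, max_len: int) -> np.ndarray:
    """Flip runs of `value` shorter than max_len samples to the opposite."""
    out = mask.copy()
    n = out.size
    i = 0
    while i < n:
        if out[i] == value:
            j = i
            while j < n and out[j] == value:
                j += 1
            if j - i < max_len:
                out[i:j] = not value
            i = j
        else:
            i += 1
    return out


def detect_fhs_boundaries(
    env: EnvelopeSignal,
    thsh: float,
    boundary: BoundaryConfig = BoundaryConfig(0.0, 0.0),
) -> BoundaryMask:
    """Threshold the envelope into the binary FHS mask (1 where env >= Thsh).

    Optional cleanup per ``boundary``: sub-``max_gap_s`` zero-gaps are filled
    first, then sub-``min_run_s`` one-runs removed.
    """
    if thsh < 0:
        raise ValueError("threshold must be nonnegative")
    mask = env.values >= thsh
    gap = int(round(boundary.max_gap_s * env.rate))
    run = int(round(boundary.min_run_s * env.rate))
    if gap > 1:
        mask = _fill_runs(mask, False, gap)
    if run > 1:
        mask = _fill_runs(mask, True, run)
    return BoundaryMask(mask.astype(np.float64))


def split_channels(
    env: EnvelopeSignal, mask: BoundaryMask
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the envelope into FHS (mask=1) and murmur (mask=0) channels.

    By construction ``fhs + murmur == envelope`` exactly, elementwise.
    """
    v, m = env.values, mask.mask
    if v.shape != m.shape:
        raise ValueError(f"envelope {v.shape} and mask {m.shape} lengths differ")
    return v * m, v * (1.0 - m)


# ---------------------------------------------------------------------------
# Log-mel spectrogram


def mel_scale(f_hz):
    """Hz to mel: 2595 * log10(1 + f/700)."""
    f = np.asarray(f_hz, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be nonnegative")
    out = 2595.0 * np.log10(1.0 + f / 700.0)
    return float(out) if np.isscalar(f_hz) else out


def mel_inverse(m):
    m = np.asarray(m, dtype=np.float64)
    out = 700.0 * (10.0 ** (m / 2595.0) - 1.0)
    return float(out) if out.ndim == 0 else out


def mel_filterbank(cfg: MelConfig) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank over the rFFT bins.

    Returns ``(weights, centers_hz)`` where weights has shape
    ``(n_mels, window // 2 + 1)`` and the band edges are equally spaced on
    the mel axis between fmin and fmax.
    """
    fmax = cfg.fmax if cfg.fmax is not None else cfg.rate / 2.0
    edges_mel = np.linspace(mel_scale(cfg.fmin), mel_scale(fmax), cfg.n_mels + 2)
    edges_hz = mel_inverse(edges_mel)
    bin_freqs = np.fft.rfftfreq(cfg.window, d=1.0 / cfg.rate)
    weights = np.zeros((cfg.n_mels, bin_freqs.size))
    for i in range(cfg.n_mels):
        lo, mid, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (bin_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - bin_freqs) / max(hi - mid, 1e-12)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
    return weights, edges_hz[1:-1]


def log_mel_spectrogram(signal: np.ndarray, cfg: MelConfig) -> np.ndarray:
    """Hamming-window STFT power -> mel filterbank -> dB.

    Framing drops the last partial window: with L samples the output has
    ``1 + (L - window) // hop`` frames, shape ``(n_mels, frames)``. With
    ``ref_mode='max'`` the global maximum of the output is 0 dB.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < cfg.window:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one window ({cfg.window})"
        )
    n_frames = 1 + (x.size - cfg.window) // cfg.hop
    frames = np.lib.stride_tricks.sliding_window_view(x, cfg.window)[:: cfg.hop]
    frames = frames[:n_frames] * np.hamming(cfg.window)
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2  # (frames, bins)
    weights, _ = mel_filterbank(cfg)
    mel_power = weights @ power.T  # (n_mels, frames)
    mel_power = np.maximum(mel_power, cfg.log_floor)
    ref = float(mel_power.max()) if cfg.ref_mode == "max" else cfg.ref_value
    return 10.0 * np.log10(mel_power / ref)


# ---------------------------------------------------------------------------
# Scalar features and duration handling


def mean_peak_interval(
    signal: np.ndarray,
    rate: int,
    kappa: float = 0.25,
    min_distance_s: float = 0.1,
    smoothing: SmoothingConfig = SmoothingConfig(70),
) -> float:
    """Mean spacing (seconds) between prominent envelope peaks.

    Peaks are detected on the smoothed Hilbert envelope with prominence at
    least ``kappa * (max - median)`` and spacing at least ``min_distance_s``.
    Murmur energy between the S1/S2 lobes adds peaks, shortening the mean
    interval relative to murmur-free signals. When fewer than two peaks are
    found the recording duration is returned as a sentinel.
    """
    x = np.asarray(signal, dtype=np.float64)
    duration = x.size / rate
    if x.size < 2:
        return duration
    env = smooth(hilbert_envelope(x, rate).values, smoothing)
    prominence = kappa * (env.max() - np.median(env))
    peaks, _ = sps.find_peaks(
        env,
        distance=max(1, int(round(min_distance_s * rate))),
        prominence=max(prominence, 1e-12),
    )
    if peaks.size < 2:
        return duration
    return float(np.mean(np.diff(peaks)) / rate)


def fix_duration(
    signal: np.ndarray, rate: int, sample_sec: float = 50.0, trim: int = 0
) -> np.ndarray:
    """Trim both ends, then force a fixed duration.

    Longer signals are cropped from the start; shorter ones are cyclically
    tiled and then cropped, so the output always has exactly
    ``round(sample_sec * rate)`` samples.
    """
    x = np.asarray(signal, dtype=np.float64)
    if trim < 0:
        raise ValueError("trim must be nonnegative")
    if trim > 0:
        if 2 * trim >= x.size:
            raise ValueError(f"trim of {trim} samples leaves no signal")
        x = x[trim:-trim]
    target = int(round(sample_sec * rate))
    if target < 1:
        raise ValueError("sample_sec too small")
    if x.size >= target:
        return x[:target].copy()
    reps = -(-target // x.size)  # ceil
    return np.tile(x, reps)[:target]


# ---------------------------------------------------------------------------
# Full pipeline


def build_feature_tensor(
    rec: PcgRecording,
    fs: FeatureSet = FEATURE_IDS[9],
    mel: MelConfig | None = None,
    smoothing: SmoothingConfig = SmoothingConfig(70),
    boundary: BoundaryConfig = BoundaryConfig(),
    cutoff_hz: float = 150.0,
    order: int = 2,
    peak_kappa: float = 0.25,
    peak_min_distance_s: float = 0.1,
) -> FeatureTensor:
    """Run the six-stage pipeline and assemble the multi-channel tensor."""
    mel = mel if mel is not None else MelConfig(rate=rec.rate)
    if mel.rate != rec.rate:
        mel = replace(mel, rate=rec.rate)

    x = fix_duration(rec.samples, rec.rate, fs.sample_sec, fs.trim)
    xn = normalize_amplitude(x)
    xf = butterworth_lowpass(xn, cutoff_hz, order, rec.rate)
    env = hilbert_envelope(xf, rec.rate)

    branches: dict[str, np.ndarray] = {}
    if fs.s1s2 or fs.murmurs or fs.envelope:
        mask = detect_fhs_boundaries(env, compute_threshold(env), boundary)
        fhs, murmur = split_channels(env, mask)
        branches.update(s1s2=fhs, murmurs=murmur, envelope=env.values)
    if fs.s_s1s2 or fs.s_murmurs or fs.s_envelope:
        env_s = EnvelopeSignal(smooth(env.values, smoothing), rec.rate)
        mask_s = detect_fhs_boundaries(env_s, compute_threshold(env_s), boundary)
        fhs_s, murmur_s = split_channels(env_s, mask_s)
        branches.update(s_s1s2=fhs_s, s_murmurs=murmur_s, s_envelope=env_s.values)
    branches["spec"] = xn

    # One shared dB reference (the recording's global maximum across all
    # channels) so relative channel energies survive; a per-channel maximum
    # would self-normalize a quiet murmur channel up to 0 dB.
    fixed = replace(mel, ref_mode="fixed", ref_value=1.0)
    stack = np.stack(
        [log_mel_spectrogram(branches[name], fixed) for name in fs.channel_names]
    )
    if mel.ref_mode == "max":
        stack = stack - stack.max()
    channels = list(stack)
    scalars: dict[str, float] = {}
    if fs.pi:
        scalars["mean_peak_interval"] = mean_peak_interval(
            xn, rec.rate, peak_kappa, peak_min_distance_s, smoothing
        )
    return FeatureTensor(
        channels=np.stack(channels), channel_names=fs.channel_names, scalars=scalars
    )


class MCHeartFeaturizer(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer from recordings to feature tensors.

    Parameters mirror the pipeline configuration keys (``trim``,
    ``sample_sec``, ``n_mels``, ``window``, ``hop``, ``cutoff``, ``order``,
    ``smoothing_window``); ``feature_id`` selects a row of the feature
    combination table, or pass a :class:`FeatureSet` via ``feature_set``.
    """

    def __init__(
        self,
        feature_id: int = 9,
        feature_set: FeatureSet | None = None,
        sample_sec: float = 50.0,
        trim: int = 0,
        n_mels: int = 140,
        window: int = 512,
        hop: int = 256,
        cutoff: float = 150.0,
        order: int = 2,
        smoothing_window: int = 70,
        min_run_s: float = 0.02,
        max_gap_s: float = 0.01,
        peak_kappa: float = 0.25,
        peak_min_distance_s: float = 0.1,
        drop_other_sites: bool = True,
    ) -> None:
        self.feature_id = feature_id
        self.feature_set = feature_set
        self.sample_sec = sample_sec
        self.trim = trim
        self.n_mels = n_mels
        self.window = window
        self.hop = hop
        self.cutoff = cutoff
        self.order = order
        self.smoothing_window = smoothing_window
        self.min_run_s = min_run_s
        self.max_gap_s = max_gap_s
        self.peak_kappa = peak_kappa
        self.peak_min_distance_s = peak_min_distance_s
        self.drop_other_sites = drop_other_sites

    def _resolved_feature_set(self) -> FeatureSet:
        base = self.feature_set
        if base is None:
            if self.feature_id not in FEATURE_IDS:
                raise ValueError(
                    f"unknown feature id {self.feature_id}; "
                    f"known: {sorted(FEATURE_IDS)}"
                )
            base = FEATURE_IDS[self.feature_id]
        return replace(base, trim=self.trim, sample_sec=self.sample_sec)

    def fit(self, X=None, y=None) -> "MCHeartFeaturizer":
        self.feature_set_ = self._resolved_feature_set()
        return self

    def transform(self, X: list[PcgRecording]) -> list[FeatureTensor]:
        fs = self._resolved_feature_set()
        out = []
        for rec in X:
            mel = MelConfig(
                window=self.window, hop=self.hop, n_mels=self.n_mels, rate=rec.rate
            )
            out.append(
                build_feature_tensor(
                    rec,
                    fs,
                    mel=mel,
                    smoothing=SmoothingConfig(self.smoothing_window),
                    boundary=BoundaryConfig(self.min_run_s, self.max_gap_s),
                    cutoff_hz=self.cutoff,
                    order=self.order,
                    peak_kappa=self.peak_kappa,
                    peak_min_distance_s=self.peak_min_distance_s,
                )
            )
        return out


def tensors_to_arrays(tensors: list[FeatureTensor]) -> tuple[np.ndarray, np.ndarray]:
    """Stack feature tensors into (X, scalars) arrays for the classifier."""
    X = np.stack([t.channels for t in tensors])
    names = sorted(tensors[0].scalars) if tensors else []
    scalars = np.array([[t.scalars[k] for k in names] for t in tensors], dtype=np.float64)
    if scalars.size == 0:
        scalars = np.zeros((len(tensors), 0))
    return X, scalars
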