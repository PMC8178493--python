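"""Formant measurement from sustained-vowel WAV recordings.

The measurement chain mirrors a standard clinical-phonetics workflow: load a
mono 44.1 kHz WAV, locate a 200-ms steady phonation window, and estimate
F1/F2 inside it.  The default estimator is linear-prediction root-finding
(downsample to twice the gender-specific formant ceiling, pre-emphasize,
fit an all-pole model per 25-ms subframe, keep roots with narrow
bandwidths, take the subframe median).  A 512-point-FFT spectral-envelope
peak picker is retained as an alternative dialect (``method="fft512"``);
its frequency resolution at 44.1 kHz is ~86 Hz per bin, which is why the
LP route is the default.
"""

from __future__ import annotations

import logging
import wave
from dataclasses import dataclass
from math import gcd
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal
from scipy.linalg import solve_toeplitz

from .synthetic import VOWELS, AudioClip, DEFAULT_RATE

__all__ = [
    "SteadySegment",
    "VowelMeasurement",
    "FormantProfile",
    "FormantConfig",
    "FormantEstimationError",
    "read_wav",
    "find_steady_segment",
    "estimate_formants",
    "extract_profile",
]

logger = logging.getLogger(__name__)


class FormantEstimationError(ValueError):
    """Raised when no admissible formant pair can be measured."""


@dataclass(frozen=True)
class FormantConfig:
    """Tunables of the estimation chain (defaults follow Praat conventions)."""

    frame: float = 0.200            # steady-segment length, s
    subframe: float = 0.025         # analysis subframe, s
    subframe_hop: float = 0.005     # subframe hop, s
    preemphasis: float = 0.97
    ceiling: Mapping[str, float] = None  # type: ignore[assignment]
    max_bandwidth: float = 400.0    # Hz; admissibility of LPC roots
    min_frequency: float = 90.0     # Hz; discard near-DC roots
    min_root_modulus: float = 0.7
    silence_floor: float = 0.10     # fraction of peak window RMS

    def __post_init__(self) -> None:
        if self.ceiling is None:
            object.__setattr__(self, "ceiling", {"male": 5000.0, "female": 5500.0})


DEFAULT_CONFIG = FormantConfig()


@dataclass(frozen=True)
class SteadySegment:
    """A fixed-length window of stable phonation within a clip."""

    start: float
    duration: float
    samples: np.ndarray
    rate: int


@dataclass(frozen=True)
class VowelMeasurement:
    """F1/F2 (Hz) for one vowel, with a [0, 1] quality score."""

    vowel: str
    f1: float
    f2: float
    method: str
    quality: float
    higher: tuple[float, ...] = ()   # optional F3..F5, extraction-only

    def __post_init__(self) -> None:
        if self.vowel not in VOWELS:
            raise ValueError(f"vowel must be one of {VOWELS}")
        if not 0 < self.f1 < self.f2:
            raise ValueError("requires 0 < F1 < F2")
        if not 0.0 <= self.quality <= 1.0:
            raise ValueError("quality must lie in [0, 1]")


@dataclass(frozen=True)
class FormantProfile:
    """One speaker-session's measurements for the three corner vowels."""

    speaker: str
    gender: str
    timepoint: str
    measurements: Mapping[str, VowelMeasurement]

    def __post_init__(self) -> None:
        if set(self.measurements) != set(VOWELS):
            raise ValueError(f"profile needs exactly one measurement per vowel {VOWELS}")
        for v, m in self.measurements.items():
            if m.vowel != v:
                raise ValueError(f"measurement labelled {m.vowel} stored under {v}")

    def f1(self, vowel: str) -> float:
        return self.measurements[vowel].f1

    def f2(self, vowel: str) -> float:
        return self.measurements[vowel].f2


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_wav(path: str | Path) -> AudioClip:
    """Load a PCM WAV as a mono clip normalized to [-1, 1].

    Multi-channel input is averaged to mono and input at a rate other than
    44.1 kHz is resampled to 44.1 kHz; both adjustments are logged.
    """
    path = Path(path)
    try:
        with wave.open(str(path), "rb") as fh:
            n_channels = fh.getnchannels()
            width = fh.getsampwidth()
            rate = fh.getframerate()
            n_frames = fh.getnframes()
            raw = fh.readframes(n_frames)
    except (wave.Error, EOFError) as exc:
        raise ValueError(f"{path}: not a readable PCM WAV file ({exc})") from exc
    if n_frames == 0 or len(raw) == 0:
        raise ValueError(f"{path}: zero-length audio")
    if width == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(np.float64) / 32768.0
    elif width == 1:
        data = (np.frombuffer(raw, dtype=np.uint8).astype(np.float64) - 128.0) / 128.0
    elif width == 4:
        data = np.frombuffer(raw, dtype="<i4").astype(np.float64) / 2147483648.0
    else:
        raise ValueError(f"{path}: unsupported sample width {width}")
    if n_channels > 1:
        usable = (len(data) // n_channels) * n_channels
        data = data[:usable].reshape(-1, n_channels).mean(axis=1)
        logger.warning("%s: %d-channel input averaged to mono", path, n_channels)
    if rate != DEFAULT_RATE:
        g = gcd(DEFAULT_RATE, rate)
        data = signal.resample_poly(data, DEFAULT_RATE // g, rate // g)
        logger.warning("%s: resampled %d Hz -> %d Hz", path, rate, DEFAULT_RATE)
        rate = DEFAULT_RATE
    peak = np.max(np.abs(data))
    if peak > 1.0:
        data = data / peak
    return AudioClip(samples=data, rate=rate, bit_depth=8 * width)


# ---------------------------------------------------------------------------
# steady-segment framing
# ---------------------------------------------------------------------------

def _frame_view(x: np.ndarray, flen: int, hop: int) -> np.ndarray:
    n = 1 + (len(x) - flen) // hop
    return np.lib.stride_tricks.as_strided(
        x, shape=(n, flen), strides=(x.strides[0] * hop, x.strides[0])
    )


def find_steady_segment(clip: AudioClip, frame: float = 0.200) -> SteadySegment:
    """Locate the most stable ``frame``-length window of the clip.

    Stability cost per candidate window = variance of short-time log-energy
    plus variance of the spectral centroid (in kHz) across 25-ms subframes.
    Only windows whose RMS reaches 10% of the loudest window's RMS are
    admissible; ties break toward the earliest start.
    """
    x = clip.samples
    rate = clip.rate
    flen = int(round(frame * rate))
    if len(x) < flen:
        raise ValueError(
            f"clip of {len(x)/rate:.3f} s is shorter than the {frame:.3f}-s frame"
        )
    sublen = int(round(0.025 * rate))
    subhop = sublen // 2
    subs = _frame_view(x, sublen, subhop)
    win = np.hamming(sublen)
    sw = subs * win
    energy = np.sum(sw**2, axis=1)
    spec = np.abs(np.fft.rfft(sw, axis=1))
    freqs = np.fft.rfftfreq(sublen, 1.0 / rate) / 1000.0  # kHz
    power = spec**2
    centroid = (power @ freqs) / np.maximum(power.sum(axis=1), 1e-30)
    log_e = np.log(np.maximum(energy, 1e-30))

    subs_per_frame = max(1, (flen - sublen) // subhop + 1)
    n_windows = len(subs) - subs_per_frame + 1
    if n_windows < 1:
        raise ValueError("clip too short for subframe analysis")
    rms = np.sqrt(
        np.convolve(energy, np.ones(subs_per_frame) / subs_per_frame, "valid")
    )
    admissible = rms >= DEFAULT_CONFIG.silence_floor * rms.max()
    if rms.max() <= 0 or not admissible.any():
        raise ValueError("all-silence clip: no admissible steady window")

    def windowed_var(v):
        c = np.convolve(v, np.ones(subs_per_frame) / subs_per_frame, "valid")
        c2 = np.convolve(v**2, np.ones(subs_per_frame) / subs_per_frame, "valid")
        return np.maximum(c2 - c**2, 0.0)

    cost = windowed_var(log_e) + windowed_var(centroid)
    cost = np.where(admissible, cost, np.inf)
    # earliest window within tolerance of the minimum cost; 1e-6 is far below
    # any audible stability difference but absorbs floating-point ties
    cmin = cost.min()
    best = int(np.argmax(cost <= cmin + 1e-6))
    start = best * subhop
    return SteadySegment(
        start=start / rate, duration=flen / rate, samples=x[start : start + flen], rate=rate
    )


# ---------------------------------------------------------------------------
# formant estimation
# ---------------------------------------------------------------------------

def _lpc_roots_formants(frame: np.ndarray, order: int, rate: float, cfg: FormantConfig):
    r = np.correlate(frame, frame, "full")[len(frame) - 1 : len(frame) + order]
    if r[0] <= 0:
        return np.array([])
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    except np.linalg.LinAlgError:
        return np.array([])
    roots = np.roots(np.concatenate(([1.0], -a)))
    roots = roots[np.imag(roots) > 1e-2]
    freq = np.angle(roots) * rate / (2.0 * np.pi)
    bw = -rate / np.pi * np.log(np.abs(roots))
    ok = (
        (freq > cfg.min_frequency)
        & (freq < rate / 2.0 - 50.0)
        & (bw < cfg.max_bandwidth)
        & (np.abs(roots) > cfg.min_root_modulus)
    )
    return np.sort(freq[ok])


def _fft512_formants(frame: np.ndarray, rate: float, ceiling: float):
    """Spectral-envelope peak picking on a 512-point magnitude spectrum.

    ``frame`` is expected at the downsampled analysis rate, where 512
    samples span several pitch periods and one bin is ~20 Hz.
    """
    n = 512
    seg = frame[:n] if len(frame) >= n else np.pad(frame, (0, n - len(frame)))
    spec = np.abs(np.fft.rfft(seg * np.hamming(n)))
    logmag = np.log(np.maximum(spec, 1e-12))
    # cepstral smoothing: keep quefrencies below 2 ms -> spectral envelope
    cep = np.fft.irfft(logmag)
    cutoff = int(0.002 * rate)
    lifter = np.zeros_like(cep)
    lifter[0] = 1.0
    lifter[1:cutoff] = 2.0
    env = np.fft.rfft(cep[: len(cep)] * lifter[: len(cep)]).real[: len(logmag)]
    freqs = np.arange(len(env)) * rate / n
    # resonance peaks stand ~2 log-units proud; ripple stays well under 0.3
    peaks, _ = signal.find_peaks(env, prominence=0.35)
    cands = []
    for p in peaks:
        f = freqs[p]
        if not 90.0 < f < ceiling:
            continue
        # parabolic interpolation around the envelope peak
        if 0 < p < len(env) - 1:
            denom = env[p - 1] - 2 * env[p] + env[p + 1]
            if denom < 0:
                f += 0.5 * (env[p - 1] - env[p + 1]) / denom * rate / n
        cands.append(f)
    return np.sort(cands)


def estimate_formants(
    seg: SteadySegment,
    gender: str,
    method: str = "lp",
    config: FormantConfig = DEFAULT_CONFIG,
    vowel: str = "A",
) -> VowelMeasurement:
    """Estimate F1/F2 inside a steady segment.

    ``lp``: downsample to 2x the gender formant ceiling, pre-emphasize,
    fit LPC of order 2 + rate/1000 per Hamming subframe, keep polynomial
    roots with bandwidth < 400 Hz, and take the median across subframes.
    ``fft512``: 512-point spectral-envelope peak picking per subframe with
    the same aggregation.  Quality = fraction of subframes yielding at
    least two admissible formants.
    """
    ceiling = config.ceiling[gender]
    x, rate = seg.samples, seg.rate
    if method == "lp":
        fsd = int(2 * ceiling)
        g = gcd(fsd, rate)
        xd = signal.resample_poly(x, fsd // g, rate // g)
        xd = signal.lfilter([1.0, -config.preemphasis], [1.0], xd)
        order = int(2 + fsd / 1000)
        flen = int(round(config.subframe * fsd))
        hop = max(1, int(round(config.subframe_hop * fsd)))
        win = np.hamming(flen)
        f1s, f2s, f_high, total = [], [], [], 0
        for s in range(0, len(xd) - flen + 1, hop):
            total += 1
            cand = _lpc_roots_formants(xd[s : s + flen] * win, order, fsd, config)
            if len(cand) >= 2:
                f1s.append(cand[0])
                f2s.append(cand[1])
                f_high.append(tuple(cand[2:5]))
    elif method == "fft512":
        # same downsampled band as `lp`: 512 points then cover ~50 ms, so the
        # envelope resolves F1 instead of drowning in the pitch mainlobe
        fsd = int(2 * ceiling)
        g = gcd(fsd, rate)
        y = signal.resample_poly(x, fsd // g, rate // g)
        y = signal.lfilter([1.0, -config.preemphasis], [1.0], y)
        flen = 512
        hop = max(1, int(round(0.010 * fsd)))
        f1s, f2s, f_high, total = [], [], [], 0
        for s in range(0, len(y) - flen + 1, hop):
            total += 1
            cand = _fft512_formants(y[s : s + flen], fsd, ceiling)
            if len(cand) >= 2:
                f1s.append(cand[0])
                f2s.append(cand[1])
                f_high.append(tuple(cand[2:5]))
    else:
        raise ValueError("method must be 'lp' or 'fft512'")

    quality = len(f1s) / max(total, 1)
    if not f1s:
        raise FormantEstimationError(
            f"no subframe yielded two admissible formants (method={method})"
        )
    f1 = float(np.median(f1s))
    f2 = float(np.median(f2s))
    if f1 >= f2:
        raise FormantEstimationError(f"aggregated F1 {f1:.0f} >= F2 {f2:.0f} Hz")
    lens = {len(h) for h in f_high}
    higher: tuple[float, ...] = ()
    if lens and min(lens) > 0:
        k = min(min(lens), 3)
        higher = tuple(
            float(np.median([h[i] for h in f_high])) for i in range(k)
        )
    return VowelMeasurement(
        vowel=vowel, f1=f1, f2=f2, method=method, quality=quality, higher=higher
    )


def extract_profile(
    clips: Mapping[str, Sequence[AudioClip] | AudioClip],
    speaker: str,
    gender: str,
    timepoint: str = "pre",
    method: str = "lp",
    config: FormantConfig = DEFAULT_CONFIG,
) -> FormantProfile:
    """Measure all three corner vowels of one session.

    ``clips`` maps each vowel label to one clip or a list of repetitions;
    repetitions are aggregated by the median of their F1 and F2.
    """
    missing = set(VOWELS) - set(clips)
    if missing:
        raise ValueError(f"missing vowel clips: {sorted(missing)}")
    measurements = {}
    for v in VOWELS:
        reps = clips[v] if isinstance(clips[v], (list, tuple)) else [clips[v]]
        per_rep = []
        for clip in reps:
            try:
                seg = find_steady_segment(clip, config.frame)
                per_rep.append(estimate_formants(seg, gender, method, config, vowel=v))
            except (ValueError, FormantEstimationError) as exc:
                logger.warning("%s /%s/: repetition failed (%s)", speaker, v, exc)
        if not per_rep:
            raise FormantEstimationError(f"vowel {v}: every repetition failed for {speaker}")
        measurements[v] = VowelMeasurement(
            vowel=v,
            f1=float(np.median([m.f1 for m in per_rep])),
            f2=float(np.median([m.f2 for m in per_rep])),
            method=method,
            quality=float(np.mean([m.quality for m in per_rep])),
        )
    return FormantProfile(
        speaker=speaker, gender=gender, timepoint=timepoint, measurements=measurements
    )
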