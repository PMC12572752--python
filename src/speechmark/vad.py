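"""Energy-based voice activity detection.

Framewise log-energy (25 ms windows, 10 ms hop), DC removal, Gaussian
smoothing, a two-means threshold on the smoothed trace, and run-length
segmentation into alternating speech/pause intervals.  A separate
autocorrelation F0 tracker supplies voiced segments for the voiced-rate
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from speechmark.io_preprocess import AudioSignal

#: energy floor applied before the log (avoids -inf on digital silence)
ENERGY_FLOOR = 1e-10

DEFAULT_FRAME_LEN = 0.025
DEFAULT_HOP = 0.010
DEFAULT_GAUSSIAN_WIDTH = 0.010
DEFAULT_MIN_SEG = 0.050


@dataclass
class EnergyTrace:
    """Per-frame log energy with frame geometry."""

    values: np.ndarray
    frame_len: float
    hop: float
    duration: float  # seconds covered by the source signal

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def frame_times(self) -> np.ndarray:
        """Frame-center times in seconds."""
        return np.arange(self.values.size) * self.hop + self.frame_len / 2.0

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SegmentationResult:
    """Speech/pause tiling of a recording."""

    segments: list[tuple[float, float, str]]  # (start, end, "speech"|"pause")
    threshold: float
    energy: EnergyTrace | None = None

    @property
    def duration(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0

    def of_label(self, label: str) -> list[tuple[float, float]]:
        return [(s, e) for s, e, lab in self.segments if lab == label]

    def validate(self) -> None:
        prev_end, prev_label = 0.0, None
        for s, e, lab in self.segments:
            assert e > s, "segment end must exceed start"
            assert abs(s - prev_end) < 1e-9, "segments must tile without gaps"
            assert lab != prev_label, "adjacent segments must alternate labels"
            prev_end, prev_label = e, lab


@dataclass
class VoicingResult:
    voiced_segments: list[tuple[float, float]] = field(default_factory=list)
    f0_track: np.ndarray = field(default_factory=lambda: np.zeros(0))


# ---------------------------------------------------------------------------


def compute_log_energy(
    signal: AudioSignal,
    frame_len: float = DEFAULT_FRAME_LEN,
    hop: float = DEFAULT_HOP,
) -> EnergyTrace:
    """Log of mean squared amplitude per frame; trailing partial frame dropped."""
    n_frame = int(round(frame_len * signal.sample_rate))
    n_hop = int(round(hop * signal.sample_rate))
    x = signal.samples
    if x.size < n_frame:
        raise ValueError("signal shorter than one analysis frame")
    n_frames = (x.size - n_frame) // n_hop + 1
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    energy = np.maximum((frames**2).mean(axis=1), ENERGY_FLOOR)
    return EnergyTrace(
        values=np.log(energy), frame_len=frame_len, hop=hop, duration=signal.duration
    )


def gaussian_kernel(width: float, hop: float) -> np.ndarray:
    """Unit-sum Gaussian kernel with sigma = width/2, truncated at +/- 3 sigma."""
    sigma = (width / 2.0) / hop  # in frames
    radius = max(1, int(np.ceil(3.0 * sigma)))
    t = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def smooth_energy(
    trace: EnergyTrace, gaussian_width: float = DEFAULT_GAUSSIAN_WIDTH
) -> EnergyTrace:
    """Mean-subtract then Gaussian-smooth the trace (reflected edges)."""
    if len(trace) == 0:
        raise ValueError("empty energy trace")
    kernel = gaussian_kernel(gaussian_width, trace.hop)
    radius = (kernel.size - 1) // 2
    values = trace.values - trace.values.mean()
    padded = np.pad(values, radius, mode="reflect") if values.size > 1 else np.repeat(
        values, 2 * radius + 1
    )
    smoothed = np.convolve(padded, kernel, mode="valid")
    return EnergyTrace(
        values=smoothed, frame_len=trace.frame_len, hop=trace.hop, duration=trace.duration
    )


def estimate_threshold(trace: EnergyTrace, tol: float = 1e-12, max_iter: int = 200) -> float:
    """Two-means threshold on the (smoothed) log-energy distribution.

    Cluster centers start at the 10th/90th percentiles; after convergence the
    threshold is the midpoint of the two cluster means.  Raises on a
    zero-variance trace (no speech/silence contrast to separate).
    """
    v = trace.values
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("energy trace has no variance; cannot estimate threshold")
    lo, hi = np.percentile(v, 10.0), np.percentile(v, 90.0)
    if lo == hi:
        lo, hi = v.min(), v.max()
    for _ in range(max_iter):
        boundary = (lo + hi) / 2.0
        low_mask = v <= boundary
        new_lo = v[low_mask].mean() if low_mask.any() else lo
        new_hi = v[~low_mask].mean() if (~low_mask).any() else hi
        if abs(new_lo - lo) < tol and abs(new_hi - hi) < tol:
            lo, hi = new_lo, new_hi
            break
        lo, hi = new_lo, new_hi
    return (lo + hi) / 2.0


def _frame_bounds(trace: EnergyTrace) -> np.ndarray:
    """Time boundaries assigning each frame an interval centred on it.

    Frame i owns [center_i - hop/2, center_i + hop/2), clipped so the first
    interval starts at 0 and the last ends at the recording duration.
    """
    centers = trace.frame_times
    bounds = np.empty(centers.size + 1)
    bounds[1:-1] = (centers[:-1] + centers[1:]) / 2.0
    bounds[0] = 0.0
    bounds[-1] = trace.duration
    return bounds


def segment_speech_pause(
    trace: EnergyTrace,
    threshold: float,
    min_seg: float = DEFAULT_MIN_SEG,
) -> SegmentationResult:
    """Threshold frames and convert label runs to a speech/pause tiling.

    Segments shorter than ``min_seg`` are merged into their longer neighbour
    (label flips), then adjacent same-label segments are coalesced.
    """
    if len(trace) == 0:
        raise ValueError("empty energy trace")
    labels = np.where(trace.values > threshold, "speech", "pause")
    bounds = _frame_bounds(trace)

    segments: list[list] = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            segments.append([bounds[run_start], bounds[i], str(labels[run_start])])
            run_start = i

    # merge short segments into a neighbour until stable
    changed = True
    while changed and len(segments) > 1:
        changed = False
        durations = [e - s for s, e, _ in segments]
        i = int(np.argmin(durations))
        if durations[i] < min_seg:
            if i == 0:
                segments[1][0] = segments[0][0]
                del segments[0]
            elif i == len(segments) - 1:
                segments[-2][1] = segments[-1][1]
                del segments[-1]
            else:
                # absorb into the longer neighbour
                left, right = segments[i - 1], segments[i + 1]
                if (left[1] - left[0]) >= (right[1] - right[0]):
                    left[1] = segments[i][1]
                else:
                    right[0] = segments[i][0]
                del segments[i]
            # coalesce same-label neighbours
            j = 1
            while j < len(segments):
                if segments[j][2] == segments[j - 1][2]:
                    segments[j - 1][1] = segments[j][1]
                    del segments[j]
                else:
                    j += 1
            changed = True

    result = SegmentationResult(
        segments=[(float(s), float(e), lab) for s, e, lab in segments],
        threshold=threshold,
        energy=trace,
    )
    result.validate()
    return result


def segment_recording(
    signal: AudioSignal,
    frame_len: float = DEFAULT_FRAME_LEN,
    hop: float = DEFAULT_HOP,
    gaussian_width: float = DEFAULT_GAUSSIAN_WIDTH,
    min_seg: float = DEFAULT_MIN_SEG,
) -> SegmentationResult:
    """Full VAD chain: log-energy -> smoothing -> threshold -> segmentation.

    The threshold is estimated per recording.
    """
    trace = smooth_energy(compute_log_energy(signal, frame_len, hop), gaussian_width)
    threshold = estimate_threshold(trace)
    return segment_speech_pause(trace, threshold, min_seg)


# ---------------------------------------------------------------------------
# voiced rate
# ---------------------------------------------------------------------------


def voiced_rate(
    signal: AudioSignal,
    frame_len: float = 0.040,
    hop: float = DEFAULT_HOP,
    fmin: float = 60.0,
    fmax: float = 400.0,
    voicing_threshold: float = 0.5,
) -> tuple[VoicingResult, float]:
    """Voiced segments per second via short-time autocorrelation F0 tracking.

    A frame is voiced when its normalized autocorrelation peak within the
    [fmin, fmax] lag range reaches ``voicing_threshold``; maximal runs of
    voiced frames form voiced segments.
    """
    sr = signal.sample_rate
    n_frame = int(round(frame_len * sr))
    n_hop = int(round(hop * sr))
    x = signal.samples
    if x.size < n_frame:
        return VoicingResult(), 0.0
    n_frames = (x.size - n_frame) // n_hop + 1
    idx = np.arange(n_frame)[None, :] + n_hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)

    lag_min = max(2, int(np.floor(sr / fmax)))
    lag_max = min(n_frame - 1, int(np.ceil(sr / fmin)))
    if lag_min >= lag_max:
        raise ValueError("frame too short for the requested F0 search range")

    # full autocorrelation per frame via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n_frame)))
    spectra = np.fft.rfft(frames, nfft, axis=1)
    acf = np.fft.irfft(spectra * np.conj(spectra), nfft, axis=1)[:, : lag_max + 1]
    r0 = acf[:, 0]
    silent = r0 < n_frame * ENERGY_FLOOR
    r0 = np.where(silent, 1.0, r0)
    norm = acf[:, lag_min : lag_max + 1] / r0[:, None]
    best_lag = norm.argmax(axis=1) + lag_min
    best_val = norm.max(axis=1)
    voiced = (best_val >= voicing_threshold) & ~silent
    f0 = np.where(voiced, sr / best_lag, 0.0)

    times = np.arange(n_frames) * hop + frame_len / 2.0
    segments: list[tuple[float, float]] = []
    start = None
    for i, v in enumerate(voiced):
        if v and start is None:
            start = times[i]
        elif not v and start is not None:
            segments.append((start, times[i - 1]))
            start = None
    if start is not None:
        segments.append((start, times[-1]))

    rate = len(segments) / signal.duration
    return VoicingResult(voiced_segments=segments, f0_track=f0), rate


# ---------------------------------------------------------------------------


def write_segments_tsv(seg: SegmentationResult, path: str | Path) -> None:
    lines = ["start_s\tend_s\tlabel"]
    lines += [f"{s!r}\t{e!r}\t{lab}" for s, e, lab in seg.segments]
    Path(path).write_text("\n".join(lines) + "\n")


def read_segments_tsv(path: str | Path) -> SegmentationResult:
    lines = Path(path).read_text().splitlines()
    segments = []
    for line in lines[1:]:
        if not line.strip():
            continue
        s, e, lab = line.split("\t")
        segments.append((float(s), float(e), lab))
    result = SegmentationResult(segments=segments, threshold=float("nan"))
    result.validate()
    return result
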