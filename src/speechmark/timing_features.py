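"""Speech-timing feature extraction.

Whole-recording features are ratios and summary statistics over the
speech/pause segmentation plus the voiced rate.  Word-level features are
duration and count statistics per token category ("all", "stop",
"content", "other", "stop_content", and a per-syllable expansion).

Column naming is stable: ``timing__<base>__<category>__<stat>`` for
word-level statistic features, ``timing__<base>__<stat>`` for
whole-recording series and ``timing__<name>`` for scalars.  Features that
cannot be computed (empty category, too few values) are emitted as NaN —
an absent-value marker, never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from speechmark.io_preprocess import AlignedTranscript, Token, tokens_in_categories
from speechmark.vad import SegmentationResult, VoicingResult

STAT_NAMES = ("mean", "sd", "skewness", "kurtosis", "min", "max")

#: word-level category selectors: name -> base-category set ("syllables" is special)
WORD_CATEGORIES: dict[str, tuple[str, ...]] = {
    "all": ("all",),
    "stop": ("stop",),
    "content": ("content",),
    "other": ("other",),
    "stop_content": ("stop", "content"),
    "syllables": ("syllables",),
}


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    skewness: float
    kurtosis: float
    min: float
    max: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in STAT_NAMES}


def summary_stats(values: Sequence[float]) -> SummaryStats:
    """Six summary statistics of a series.

    sd is the sample standard deviation (ddof=1; 0 for a single value).
    Skewness is the adjusted Fisher–Pearson form; kurtosis is excess
    kurtosis with sample-size correction.  Both are defined as 0 whenever
    the variance is 0 or the series is too short for the correction.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size == 0:
        raise ValueError("summary_stats requires a non-empty series")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        skew = kurt = 0.0
    else:
        n = x.size
        d = x - mean
        m2 = float((d**2).mean())
        g1 = float((d**3).mean()) / m2**1.5
        skew = math.sqrt(n * (n - 1)) / (n - 2) * g1 if n > 2 else 0.0
        if n > 3:
            m4 = float((d**4).mean()) / m2**2
            kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * m4 - 3 * (n - 1))
        else:
            kurt = 0.0
    return SummaryStats(mean, sd, skew, kurt, float(x.min()), float(x.max()))


def _stats_columns(prefix: str, values: Sequence[float]) -> dict[str, float]:
    if len(values) == 0:
        return {f"{prefix}__{s}": math.nan for s in STAT_NAMES}
    return {f"{prefix}__{s}": v for s, v in summary_stats(values).as_dict().items()}


# ---------------------------------------------------------------------------


def whole_recording_features(
    seg: SegmentationResult, voicing_rate: float | None = None
) -> dict[str, float]:
    """Ratio features and duration statistics over the segmentation.

    - ``pause_duration_ratio`` / ``speech_segment_duration_ratio``: time
      fractions of the recording (they sum to 1);
    - ``pause_ratio``: count of pause segments over all segments;
    - summary statistics over individual pause and speech-segment durations;
    - ``voiced_rate`` if supplied.
    """
    if not seg.segments:
        raise ValueError("empty segmentation")
    pauses = [e - s for s, e in seg.of_label("pause")]
    speech = [e - s for s, e in seg.of_label("speech")]
    total = seg.duration
    pause_time = float(sum(pauses))

    out: dict[str, float] = {
        "timing__pause_duration_ratio": pause_time / total,
        "timing__speech_segment_duration_ratio": 1.0 - pause_time / total,
        "timing__pause_ratio": len(pauses) / (len(pauses) + len(speech)),
    }
    out.update(_stats_columns("timing__pause_duration", pauses))
    out.update(_stats_columns("timing__speech_segment_duration", speech))
    out["timing__voiced_rate"] = math.nan if voicing_rate is None else float(voicing_rate)
    return out


def _category_tokens(transcript: AlignedTranscript, category: str) -> list[Token]:
    selector = WORD_CATEGORIES[category]
    if selector == ("syllables",):
        return list(transcript.tokens)
    return tokens_in_categories(transcript.tokens, selector)


def word_level_features(
    transcript: AlignedTranscript,
    seg: SegmentationResult,
    category: str,
) -> dict[str, float]:
    """Duration/count features for one token category.

    ``word_duration``: stats over token durations; ``normalized_word_duration``:
    stats over duration per syllable; ``word_count``: token count;
    ``normalized_word_count``: tokens per second of speech.  The ``syllables``
    category expands each token into per-syllable durations.
    """
    if category not in WORD_CATEGORIES:
        raise KeyError(f"unknown category {category!r}")
    tokens = _category_tokens(transcript, category)
    speech_time = sum(e - s for s, e in seg.of_label("speech"))

    if category == "syllables":
        durations = [
            t.duration / t.n_syllables for t in tokens for _ in range(t.n_syllables)
        ]
        norm_durations = durations
        count = sum(t.n_syllables for t in tokens)
    else:
        durations = [t.duration for t in tokens]
        norm_durations = [t.duration / t.n_syllables for t in tokens]
        count = len(tokens)

    prefix = f"timing__word_duration__{category}"
    out = _stats_columns(prefix, durations)
    out.update(_stats_columns(f"timing__normalized_word_duration__{category}", norm_durations))
    out[f"timing__word_count__{category}"] = float(count) if tokens else math.nan
    out[f"timing__normalized_word_count__{category}"] = (
        count / speech_time if tokens and speech_time > 0 else math.nan
    )
    return out


def timing_feature_vector(
    seg: SegmentationResult,
    transcript: AlignedTranscript,
    voicing: VoicingResult | None = None,
    voicing_rate: float | None = None,
    categories: Iterable[str] = WORD_CATEGORIES,
) -> dict[str, float]:
    """All timing features for one recording (whole-recording + word-level)."""
    out = whole_recording_features(seg, voicing_rate)
    for category in categories:
        out.update(word_level_features(transcript, seg, category))
    return out


def feature_names(vector: Mapping[str, float], modality: str | None = None) -> list[str]:
    names = list(vector)
    if modality is not None:
        names = [n for n in names if n.startswith(f"{modality}__")]
    return names
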