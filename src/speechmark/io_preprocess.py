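"""Audio and transcript I/O.

Audio is read from PCM WAV, mixed down to mono, resampled (16 kHz by
default) and peak-normalized.  Time-aligned transcripts travel in a small
TSV/JSON dialect with one record per token: surface form, onset/offset in
seconds, coarse POS tag, syllable count and a stop-word flag.  Cohorts are
described by a JSON manifest listing one participant per entry.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

POS_TAGS = ("noun", "verb", "adjective", "adverb", "other")
CONTENT_POS = frozenset(("noun", "verb", "adjective", "adverb"))

TRANSCRIPT_COLUMNS = ("token", "onset_s", "offset_s", "pos", "syllables", "is_stop")

#: characters stripped from CHAT-annotated transcripts
CHAT_SPECIAL_CHARS = "?–()+[]<>&@/\\^~«»—“”‹›"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class AudioSignal:
    """Mono audio samples with their sample rate."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.size == 0:
            raise ValueError("zero-length signal")

    @property
    def duration(self) -> float:
        """Length in seconds (= n_samples / sample_rate)."""
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class Token:
    """One time-aligned word."""

    text: str
    onset: float
    offset: float
    pos: str
    n_syllables: int
    is_stop: bool

    @property
    def is_content(self) -> bool:
        return self.pos in CONTENT_POS

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def validate(self, index: int | None = None) -> None:
        where = "" if index is None else f" (token {index}: {self.text!r})"
        if self.pos not in POS_TAGS:
            raise ValueError(f"unknown POS tag {self.pos!r}{where}")
        if not self.offset > self.onset:
            raise ValueError(f"offset must exceed onset{where}")
        if self.onset < 0:
            raise ValueError(f"negative onset{where}")
        if self.n_syllables < 1:
            raise ValueError(f"syllable count must be >= 1{where}")
        if self.is_stop and self.is_content:
            raise ValueError(f"token cannot be both stop and content word{where}")


@dataclass
class AlignedTranscript:
    """Ordered token sequence for one recording."""

    tokens: list[Token]
    recording_id: str = ""

    def __post_init__(self) -> None:
        prev_onset = -math.inf
        for i, tok in enumerate(self.tokens):
            tok.validate(i)
            if tok.onset < prev_onset:
                raise ValueError(f"token onsets must be non-decreasing (token {i})")
            prev_onset = tok.onset

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


@dataclass
class ParticipantRecord:
    id: str
    group: str  # "patient" | "control"
    transcript_path: str | None = None
    audio_path: str | None = None
    segments_path: str | None = None  # precomputed segmentation TSV
    mmse: int | None = None
    language: str = ""


@dataclass
class CohortManifest:
    """Participant roster for one cohort / language."""

    participants: list[ParticipantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique")
        for p in self.participants:
            if p.group not in ("patient", "control"):
                raise ValueError(f"unknown group {p.group!r} for {p.id}")
            if p.mmse is not None and not (0 <= p.mmse <= 30):
                raise ValueError(f"MMSE out of range for {p.id}")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls([ParticipantRecord(**entry) for entry in raw["participants"]])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "participants": [
                {k: v for k, v in vars(p).items() if v is not None}
                for p in self.participants
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def load_audio(path: str | Path, target_rate: int = 16000) -> AudioSignal:
    """Read a PCM WAV file as mono float audio at ``target_rate``.

    Multi-channel input is averaged to mono; integer PCM is scaled to
    [-1, 1]; the result is peak-normalized unless the file is silent.
    """
    rate, data = wavfile.read(path)
    data = np.asarray(data, dtype=np.float64)
    if data.size == 0:
        raise ValueError(f"zero-length audio file: {path}")
    if data.ndim > 1:
        data = data.mean(axis=1)
    # integer PCM -> [-1, 1)
    info_max = {np.int16: 2**15, np.int32: 2**31, np.uint8: 2**7}
    raw = wavfile.read(path)[1]
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(info_max.get(raw.dtype.type, np.abs(data).max() or 1.0))
        if raw.dtype == np.uint8:
            data = data - 128.0
        data = data / scale
    if rate != target_rate:
        frac = Fraction(target_rate, int(rate)).limit_denominator(1000)
        data = resample_poly(data, frac.numerator, frac.denominator)
    peak = np.abs(data).max()
    if peak > 0:
        data = data / peak
    return AudioSignal(samples=data, sample_rate=target_rate)


def clean_chat_transcript(raw: str) -> str:
    """Strip CHAT markup characters and collapse whitespace.

    Removes the annotation character set (``?``, en/em dashes, parentheses,
    ``+`` and related markup symbols) and collapses runs of whitespace into
    single spaces.
    """
    table = {ord(c): " " for c in CHAT_SPECIAL_CHARS}
    text = raw.translate(table)
    return re.sub(r"\s+", " ", text).strip()


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in ("1", "true", "yes"):
        return True
    if v in ("0", "false", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _token_from_fields(fields: dict, row: int) -> Token:
    try:
        return Token(
            text=str(fields["token"]),
            onset=float(fields["onset_s"]),
            offset=float(fields["offset_s"]),
            pos=str(fields["pos"]),
            n_syllables=int(fields["syllables"]),
            is_stop=fields["is_stop"]
            if isinstance(fields["is_stop"], bool)
            else _parse_bool(fields["is_stop"]),
        )
    except KeyError as exc:
        raise ValueError(f"missing required column {exc.args[0]!r} in row {row}") from exc


def read_aligned_transcript(path: str | Path) -> AlignedTranscript:
    """Read an aligned transcript from TSV or JSON (by file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            raw = json.load(fh)
        tokens = [_token_from_fields(rec, i) for i, rec in enumerate(raw["tokens"])]
        return AlignedTranscript(tokens, recording_id=raw.get("recording_id", path.stem))

    lines = path.read_text().splitlines()
    if not lines:
        return AlignedTranscript([], recording_id=path.stem)
    header = lines[0].split("\t")
    missing = set(TRANSCRIPT_COLUMNS) - set(header)
    if missing:
        raise ValueError(f"missing required column(s) {sorted(missing)} in {path}")
    tokens = []
    for i, line in enumerate(lines[1:]):
        if not line.strip():
            continue
        fields = dict(zip(header, line.split("\t")))
        tok = _token_from_fields(fields, i)
        try:
            tok.validate(i)
        except ValueError as exc:
            raise ValueError(f"{path} row {i + 1}: {exc}") from exc
        tokens.append(tok)
    return AlignedTranscript(tokens, recording_id=path.stem)


def write_aligned_transcript(
    transcript: AlignedTranscript, path: str | Path, fmt: str | None = None
) -> None:
    """Write a transcript as TSV or JSON; format inferred from extension."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        payload = {
            "recording_id": transcript.recording_id,
            "tokens": [
                {
                    "token": t.text,
                    "onset_s": t.onset,
                    "offset_s": t.offset,
                    "pos": t.pos,
                    "syllables": t.n_syllables,
                    "is_stop": t.is_stop,
                }
                for t in transcript
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    lines = ["\t".join(TRANSCRIPT_COLUMNS)]
    for t in transcript:
        lines.append(
            "\t".join(
                [t.text, repr(t.onset), repr(t.offset), t.pos, str(t.n_syllables),
                 "true" if t.is_stop else "false"]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def write_wav(signal: AudioSignal, path: str | Path) -> None:
    """Write mono audio as 16-bit PCM WAV."""
    clipped = np.clip(signal.samples, -1.0, 1.0)
    wavfile.write(path, signal.sample_rate, (clipped * 32767).astype(np.int16))


def tokens_in_categories(
    tokens: Iterable[Token], categories: Sequence[str]
) -> list[Token]:
    """Select tokens belonging to any of ``categories``.

    Categories: ``all`` (everything), ``stop``, ``content``, ``other``
    (neither stop nor content).
    """
    cats = set(categories)
    if "all" in cats:
        return list(tokens)
    out = []
    for t in tokens:
        if ("stop" in cats and t.is_stop) or ("content" in cats and t.is_content):
            out.append(t)
        elif "other" in cats and not t.is_stop and not t.is_content:
            out.append(t)
    return out
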