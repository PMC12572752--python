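"""Glue: per-participant feature extraction into a cohort feature table.

Participants may carry raw audio (VAD is run and the voiced rate is
computed) or a precomputed segmentation (timing features come straight
from the segments; voiced rate is emitted as absent).  Denoising and
cepstral normalization are intentionally not applied — inputs are assumed
clean — and a warning records that.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from speechmark.io_preprocess import (
    AlignedTranscript,
    AudioSignal,
    CohortManifest,
    load_audio,
    read_aligned_transcript,
)
from speechmark.lexsem_features import (
    EmbeddingTable,
    HypernymGraph,
    lexsem_feature_vector,
)
from speechmark.timing_features import timing_feature_vector
from speechmark.vad import (
    SegmentationResult,
    read_segments_tsv,
    segment_recording,
    voiced_rate,
)

logger = logging.getLogger(__name__)

_warned_no_denoise = False


def _warn_no_denoise() -> None:
    global _warned_no_denoise
    if not _warned_no_denoise:
        logger.warning(
            "denoising/cepstral normalization are not applied; inputs assumed clean"
        )
        _warned_no_denoise = True


def extract_participant_features(
    transcript: AlignedTranscript,
    graph: HypernymGraph,
    table: EmbeddingTable,
    audio: AudioSignal | None = None,
    segmentation: SegmentationResult | None = None,
) -> dict[str, float]:
    """Timing + lexsem features for one participant."""
    _warn_no_denoise()
    rate = None
    if segmentation is None:
        if audio is None:
            raise ValueError("need either audio or a precomputed segmentation")
        segmentation = segment_recording(audio)
    if audio is not None:
        _, rate = voiced_rate(audio)
    features = timing_feature_vector(segmentation, transcript, voicing_rate=rate)
    features.update(lexsem_feature_vector(transcript, graph, table))
    return features


def extract_cohort_features(cohort) -> pd.DataFrame:
    """Feature table (participants x features) for a SyntheticCohort."""
    rows = {}
    for p in cohort.participants:
        rows[p.id] = extract_participant_features(
            p.transcript,
            cohort.graph,
            cohort.embeddings,
            audio=p.audio,
            segmentation=None if p.audio is not None else p.segmentation,
        )
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def extract_manifest_features(
    manifest: CohortManifest,
    graph: HypernymGraph,
    table: EmbeddingTable,
    target_rate: int = 16000,
) -> pd.DataFrame:
    """Feature table for an on-disk cohort described by a manifest."""
    rows = {}
    for p in manifest.participants:
        if p.transcript_path is None:
            raise ValueError(f"participant {p.id} has no transcript")
        transcript = read_aligned_transcript(p.transcript_path)
        audio = load_audio(p.audio_path, target_rate) if p.audio_path else None
        # precomputed segments take precedence; audio still feeds voiced rate
        seg = read_segments_tsv(p.segments_path) if p.segments_path else None
        rows[p.id] = extract_participant_features(
            transcript, graph, table, audio=audio, segmentation=seg
        )
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index_label="participant_id")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="participant_id")
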