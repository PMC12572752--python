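"""Synthetic two-group, two-"language" cohorts.

Each participant gets a latent severity (patients centred at 1, controls
at 0).  Severity drives: (1) the silence fraction of an alternating
speech/pause segment plan whose pause durations are lognormal, (2) MMSE
via a linear model with noise, and — through group-level parameters —
(3) POS mixtures, (4) hypernym-depth distributions of produced nouns, and
(5) the cluster-jump probability that controls adjacent embedding-distance
variance.  Audio, when requested, renders speech bursts as amplitude-
modulated sawtooth carriers plus noise and pauses as low-level noise, so
both the energy VAD and the autocorrelation F0 tracker are exercised.

``generate_language_pair`` produces a source cohort and a target cohort
that shares the timing effect; in ``scrambled_lexsem`` mode the target's
lexico-semantic group effects are independently re-randomized and its
vocabulary (and embedding table) is disjoint from the source's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

from speechmark.io_preprocess import (
    AlignedTranscript,
    AudioSignal,
    CohortManifest,
    ParticipantRecord,
    Token,
)
from speechmark.lexsem_features import EmbeddingTable, HypernymGraph
from speechmark.vad import SegmentationResult

POS_ORDER = ("noun", "verb", "adjective", "adverb", "other")


# ---------------------------------------------------------------------------
# bundled toy lexicon
# ---------------------------------------------------------------------------

#: semantic fields: field -> chain of increasingly specific nouns under "entity"
_FIELD_CHAINS = {
    "animal": ["animal", "dog", "bulldog", "french_bulldog", "show_french_bulldog"],
    "plant": ["plant", "tree", "conifer", "pine", "scots_pine", "dwarf_scots_pine"],
    "vehicle": ["vehicle", "wheeled_vehicle", "car", "sedan", "taxi_sedan",
                "city_taxi_sedan", "night_city_taxi_sedan"],
    "tool": ["tool", "hand_tool", "hammer", "claw_hammer", "steel_claw_hammer",
             "small_steel_claw_hammer", "old_small_steel_claw_hammer",
             "rusty_old_small_steel_claw_hammer"],
    "food": ["food", "baked_goods", "cookie", "chocolate_cookie",
             "dark_chocolate_cookie"],
    "person": ["person", "child", "boy", "schoolboy", "young_schoolboy"],
    "building": ["building", "house", "kitchen", "kitchen_counter",
                 "marble_kitchen_counter"],
    "clothing": ["clothing", "garment", "dress", "summer_dress",
                 "cotton_summer_dress", "blue_cotton_summer_dress",
                 "light_blue_cotton_summer_dress",
                 "faded_light_blue_cotton_summer_dress",
                 "old_faded_light_blue_cotton_summer_dress"],
    "water": ["substance", "liquid", "water", "tap_water", "cold_tap_water",
              "filtered_cold_tap_water"],
    "furniture": ["furniture", "seat", "stool", "three_legged_stool",
                  "wooden_three_legged_stool"],
}

#: extra leaves hanging off chain nodes to widen each depth level
_EXTRA_CHILDREN = {
    "animal": ["mammal", "bird"],
    "mammal": ["cat", "rodent"],
    "cat": ["tabby_cat"],
    "tree": ["oak", "willow"],
    "car": ["coupe", "hatchback"],
    "child": ["girl", "toddler"],
    "kitchen": ["cupboard"],
    "cookie": ["biscuit_variant"],
    "dog": ["terrier", "poodle"],
    "terrier": ["fox_terrier"],
}

_VERBS = ["fall", "reach", "wash", "overflow", "steal", "stand", "dry", "climb",
          "pour", "watch", "slip", "spill", "grab", "lean", "point", "laugh",
          "open_up", "tip_over", "run_off", "look_on"]
_ADJECTIVES = ["tall", "wet", "small", "open", "busy", "quiet", "full", "high",
               "empty", "young"]
_ADVERBS = ["quickly", "slowly", "quietly", "almost", "nearly", "barely",
            "softly", "loudly", "gently", "badly"]
_STOP_WORDS = ["the", "a", "is", "and", "of", "to", "in", "on", "it", "that"]
_FILLERS = ["uh", "um", "eh"]


def _build_parents(prefix: str = "") -> dict[str, list[str]]:
    p = prefix
    parents: dict[str, list[str]] = {}
    for chain in _FIELD_CHAINS.values():
        parent = p + "entity"
        for node in chain:
            parents.setdefault(p + node, []).append(parent)
            parent = p + node
    for parent_node, children in _EXTRA_CHILDREN.items():
        for child in children:
            parents.setdefault(p + child, []).append(p + parent_node)
    return parents


def bundled_toy_lexicon(
    prefix: str = "", dim: int = 16, seed: int = 7
) -> tuple[HypernymGraph, EmbeddingTable]:
    """Deterministic toy hypernym graph + clustered embedding table.

    The graph contains the chain entity -> animal -> dog -> bulldog at
    depths 1, 2, 3, with other semantic-field chains reaching depth ~9 so
    all three granularity bins are populated.  Embeddings live in one tight
    cluster per semantic field (plus one cluster each for verbs,
    adjectives, adverbs, and function words), so adjacent-word distances
    are small within a field and large across fields.
    """
    parents = _build_parents(prefix)
    graph = HypernymGraph(parents=parents, root=prefix + "entity")

    rng = np.random.default_rng(seed)
    clusters = semantic_clusters(prefix)
    vectors: dict[str, np.ndarray] = {}
    for field_words in clusters.values():
        center = rng.normal(0.0, 1.0, dim)
        center /= np.linalg.norm(center)
        for word in [w for pos_words in field_words.values() for w in pos_words]:
            if word in vectors:
                continue
            v = center + rng.normal(0.0, 0.05, dim)
            vectors[word] = v / np.linalg.norm(v)
    func_center = rng.normal(0.0, 1.0, dim)
    func_center /= np.linalg.norm(func_center)
    for w in _STOP_WORDS + _FILLERS + ["entity"]:
        v = func_center + rng.normal(0.0, 0.05, dim)
        vectors[prefix + w] = v / np.linalg.norm(v)
    table = EmbeddingTable(vectors=vectors, language=prefix.rstrip("_") or "toy")
    return graph, table


def _field_nouns(name: str) -> set[str]:
    members = set(_FIELD_CHAINS[name])
    for _ in range(3):  # fixpoint over the shallow extra-children map
        for parent_node, children in _EXTRA_CHILDREN.items():
            if parent_node in members:
                members.update(children)
    return members


def semantic_clusters(prefix: str = "") -> dict[str, dict[str, list[str]]]:
    """field -> {pos -> words}: nouns from the field's subtree; verbs,
    adjectives and adverbs dealt round-robin across fields so that staying
    within a field is possible for every content POS."""
    fields = sorted(_FIELD_CHAINS)
    clusters: dict[str, dict[str, list[str]]] = {
        name: {
            "noun": sorted(prefix + m for m in _field_nouns(name)),
            "verb": [],
            "adjective": [],
            "adverb": [],
        }
        for name in fields
    }
    for pos, pool in (("verb", _VERBS), ("adjective", _ADJECTIVES), ("adverb", _ADVERBS)):
        for i, word in enumerate(pool):
            clusters[fields[i % len(fields)]][pos].append(prefix + word)
    return clusters


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class GroupLexsemEffect:
    """Per-group lexico-semantic generation parameters."""

    pos_probs: dict[str, float]
    depth_mean: float
    depth_sd: float
    jump_prob: float  # probability of jumping to a new semantic cluster


@dataclass
class CohortConfig:
    n_per_group: int = 25
    seed: int = 0
    language: str = "en"
    transfer_mode: str = "aligned"  # | "scrambled_lexsem"
    duration: float = 30.0  # approximate recording length, seconds

    # timing effect
    base_silence_fraction: float = 0.30
    timing_effect: float = 0.15  # silence-fraction shift per unit severity
    pause_sigma: float = 0.35  # lognormal sigma of pause durations
    speech_mean: float = 1.2  # mean speech-burst duration (s)
    speech_sigma: float = 0.30
    severity_sd: float = 0.35
    snr_db: float = 30.0

    # lexsem effect (defaults: patients more general nouns, fewer nouns,
    # more erratic semantic trajectories)
    control_lexsem: GroupLexsemEffect = field(
        default_factory=lambda: GroupLexsemEffect(
            pos_probs={"noun": 0.30, "verb": 0.15, "adjective": 0.07,
                       "adverb": 0.05, "other": 0.43},
            depth_mean=4.0, depth_sd=1.0, jump_prob=0.15,
        )
    )
    patient_lexsem: GroupLexsemEffect = field(
        default_factory=lambda: GroupLexsemEffect(
            pos_probs={"noun": 0.20, "verb": 0.12, "adjective": 0.04,
                       "adverb": 0.04, "other": 0.60},
            depth_mean=2.2, depth_sd=0.8, jump_prob=0.45,
        )
    )

    # MMSE model: mmse = intercept + coef * severity + N(0, noise_sd), clipped
    mmse_intercept: float = 27.0
    mmse_coef: float = -6.0
    mmse_noise_sd: float = 2.0

    with_audio: bool = False
    sample_rate: int = 16000

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 < self.base_silence_fraction < 1.0:
            raise ValueError("silence fraction must lie in (0, 1)")
        if self.mmse_noise_sd < 0:
            raise ValueError("mmse_noise_sd must be >= 0")
        if self.transfer_mode not in ("aligned", "scrambled_lexsem"):
            raise ValueError(f"unknown transfer_mode {self.transfer_mode!r}")

    def zero_effect(self) -> "CohortConfig":
        """A null copy: identical distributions for patients and controls."""
        return replace(
            self,
            timing_effect=0.0,
            patient_lexsem=GroupLexsemEffect(
                pos_probs=dict(self.control_lexsem.pos_probs),
                depth_mean=self.control_lexsem.depth_mean,
                depth_sd=self.control_lexsem.depth_sd,
                jump_prob=self.control_lexsem.jump_prob,
            ),
            mmse_coef=0.0,
        )


@dataclass
class SyntheticParticipant:
    id: str
    group: str
    language: str
    segmentation: SegmentationResult
    transcript: AlignedTranscript
    severity: float
    mmse: int
    audio: AudioSignal | None = None


@dataclass
class SyntheticCohort:
    participants: list[SyntheticParticipant]
    config: CohortConfig
    graph: HypernymGraph
    embeddings: EmbeddingTable
    ground_truth: dict[str, dict]

    def manifest(self) -> CohortManifest:
        return CohortManifest(
            [
                ParticipantRecord(
                    id=p.id, group=p.group, mmse=p.mmse, language=p.language
                )
                for p in self.participants
            ]
        )


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _plan_segments(
    rng: np.random.Generator, config: CohortConfig, silence_fraction: float
) -> list[tuple[float, float, str]]:
    """Alternating speech/pause tiling with the requested silence fraction."""
    speech_mu = math.log(config.speech_mean) - config.speech_sigma**2 / 2.0
    pause_mean = config.speech_mean * silence_fraction / (1.0 - silence_fraction)
    pause_mu = math.log(pause_mean) - config.pause_sigma**2 / 2.0

    segments: list[tuple[float, float, str]] = []
    t = 0.0
    label = "speech"
    while t < config.duration or label == "pause":
        if label == "speech":
            d = float(rng.lognormal(speech_mu, config.speech_sigma))
            d = max(d, 0.3)
        else:
            d = float(rng.lognormal(pause_mu, config.pause_sigma))
            d = max(d, 0.26)
        segments.append((t, t + d, label))
        t += d
        label = "pause" if label == "speech" else "speech"
    return segments


def _render_audio(
    rng: np.random.Generator,
    segments: list[tuple[float, float, str]],
    config: CohortConfig,
) -> AudioSignal:
    """Speech = AM sawtooth + noise; pauses = low-level noise (SNR per config)."""
    sr = config.sample_rate
    n = int(round(segments[-1][1] * sr))
    speech_amp = 0.3
    # sawtooth rms ~ amp/sqrt(3)
    speech_power = (speech_amp**2) / 3.0
    noise_rms = math.sqrt(speech_power / (10.0 ** (config.snr_db / 10.0)))
    x = rng.normal(0.0, noise_rms, n)
    for s, e, lab in segments:
        if lab != "speech":
            continue
        i0, i1 = int(round(s * sr)), min(int(round(e * sr)), n)
        t = np.arange(i1 - i0) / sr
        f0 = float(rng.uniform(100.0, 200.0))
        phase = (t * f0) % 1.0
        saw = 2.0 * phase - 1.0
        am = 1.0 + 0.1 * np.sin(2.0 * math.pi * 3.0 * t + rng.uniform(0, 2 * math.pi))
        x[i0:i1] += speech_amp * am * saw
    peak = np.abs(x).max()
    return AudioSignal(samples=x / peak, sample_rate=sr)


def _draw_word(
    rng: np.random.Generator,
    pos: str,
    effect: GroupLexsemEffect,
    clusters: dict[str, dict[str, list[str]]],
    depth_of: dict[str, int],
    state: dict,
    prefix: str,
) -> tuple[str, bool, int]:
    """Pick a word form for ``pos``; returns (text, is_stop, n_syllables).

    Content words follow a cluster-jump process: with probability
    ``effect.jump_prob`` the current semantic field switches, otherwise the
    word is drawn from the current field.  The jump rate controls the
    variance of adjacent embedding distances downstream.
    """
    if pos == "other":
        # mostly stop words, occasionally non-stop fillers
        if rng.random() < 0.85:
            return prefix + _STOP_WORDS[rng.integers(len(_STOP_WORDS))], True, 1
        return prefix + _FILLERS[rng.integers(len(_FILLERS))], False, 1

    field_names = sorted(clusters)
    if state["cluster"] is None or rng.random() < effect.jump_prob:
        state["cluster"] = field_names[rng.integers(len(field_names))]
        state["jumps"] += 1
    candidates = clusters[state["cluster"]][pos]
    if pos == "noun":
        target = rng.normal(effect.depth_mean, effect.depth_sd)
        gaps = np.array([abs(depth_of[w] - target) for w in candidates])
        best = np.flatnonzero(gaps == gaps.min())
        word = candidates[int(best[rng.integers(best.size)])]
    else:
        word = candidates[rng.integers(len(candidates))]
    # syllable count independent of the word form: the form length tracks
    # hypernym depth here, and coupling them would leak the lexsem effect
    # into the timing channel
    syllables = int(rng.integers(1, 4))
    return word, False, syllables


def _fill_tokens(
    rng: np.random.Generator,
    segments: list[tuple[float, float, str]],
    effect: GroupLexsemEffect,
    clusters: dict[str, dict[str, list[str]]],
    depth_of: dict[str, int],
    prefix: str,
) -> tuple[list[Token], dict]:
    pos_names = list(POS_ORDER)
    pos_p = np.array([effect.pos_probs[p] for p in pos_names])
    pos_p = pos_p / pos_p.sum()
    state = {"cluster": None, "jumps": 0}
    tokens: list[Token] = []
    pos_counts = {p: 0 for p in pos_names}
    depths_produced: list[float] = []
    for s, e, lab in segments:
        if lab != "speech":
            continue
        t = s + float(rng.uniform(0.01, 0.04))
        while True:
            dur = float(rng.uniform(0.15, 0.35))
            if t + dur > e - 0.01:
                break
            pos = pos_names[rng.choice(len(pos_names), p=pos_p)]
            text, is_stop, syl = _draw_word(
                rng, pos, effect, clusters, depth_of, state, prefix
            )
            tokens.append(
                Token(text=text, onset=t, offset=t + dur, pos=pos,
                      n_syllables=syl, is_stop=is_stop)
            )
            pos_counts[pos] += 1
            t += dur + float(rng.uniform(0.01, 0.05))
    truth = {"pos_counts": pos_counts, "n_jumps": state["jumps"]}
    return tokens, truth


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a deterministic cohort from ``config`` (same seed, same bytes)."""
    rng = np.random.default_rng(config.seed)
    prefix = "" if config.language == "en" else config.language + "_"
    graph, table = bundled_toy_lexicon(prefix=prefix)
    clusters = semantic_clusters(prefix)
    depth_of = {n: graph.node_depth(n) for n in graph.nodes}

    participants: list[SyntheticParticipant] = []
    ground_truth: dict[str, dict] = {}
    for group in ("control", "patient"):
        effect = config.patient_lexsem if group == "patient" else config.control_lexsem
        base_sev = 1.0 if group == "patient" else 0.0
        for k in range(config.n_per_group):
            pid = f"{config.language}_{group}_{k:03d}"
            severity = float(rng.normal(base_sev, config.severity_sd))
            silence = float(
                np.clip(
                    config.base_silence_fraction + config.timing_effect * severity,
                    0.05, 0.90,
                )
            )
            segments = _plan_segments(rng, config, silence)
            seg_result = SegmentationResult(segments=segments, threshold=math.nan)
            seg_result.validate()
            tokens, lex_truth = _fill_tokens(
                rng, segments, effect, clusters, depth_of, prefix
            )
            transcript = AlignedTranscript(tokens, recording_id=pid)
            mmse_clean = config.mmse_intercept + config.mmse_coef * severity
            mmse = int(
                np.clip(round(mmse_clean + rng.normal(0.0, config.mmse_noise_sd)), 0, 30)
            )
            audio = _render_audio(rng, segments, config) if config.with_audio else None
            participants.append(
                SyntheticParticipant(
                    id=pid, group=group, language=config.language,
                    segmentation=seg_result, transcript=transcript,
                    severity=severity, mmse=mmse, audio=audio,
                )
            )
            total = segments[-1][1]
            pause_time = sum(e - s for s, e, lab in segments if lab == "pause")
            ground_truth[pid] = {
                "severity": severity,
                "target_silence_fraction": silence,
                "realized_silence_fraction": pause_time / total,
                "segments": segments,
                "mmse_noise_free": mmse_clean,
                **lex_truth,
            }
    return SyntheticCohort(
        participants=participants, config=config, graph=graph,
        embeddings=table, ground_truth=ground_truth,
    )


def _scramble_lexsem(config: CohortConfig, rng: np.random.Generator) -> CohortConfig:
    """Re-randomize the target's lexico-semantic group effects.

    The POS-mixture group effect is neutralized (both groups draw from the
    averaged mixture): token-category composition also feeds the word-level
    *timing* counts, so flipping it would corrupt the timing channel that
    the construction must preserve.  The granularity-depth and
    semantic-variability effect directions are each kept or flipped by an
    independent coin, so their source/target contrast-sign agreement is at
    chance across seeds.
    """
    ctrl, pat = config.control_lexsem, config.patient_lexsem
    mean_pos = {
        k: (ctrl.pos_probs[k] + pat.pos_probs[k]) / 2.0 for k in ctrl.pos_probs
    }
    new_ctrl = GroupLexsemEffect(
        pos_probs=dict(mean_pos), depth_mean=ctrl.depth_mean,
        depth_sd=ctrl.depth_sd, jump_prob=ctrl.jump_prob,
    )
    new_pat = GroupLexsemEffect(
        pos_probs=dict(mean_pos), depth_mean=pat.depth_mean,
        depth_sd=pat.depth_sd, jump_prob=pat.jump_prob,
    )
    if rng.random() < 0.5:  # granularity-depth direction
        new_ctrl.depth_mean, new_pat.depth_mean = new_pat.depth_mean, new_ctrl.depth_mean
        new_ctrl.depth_sd, new_pat.depth_sd = new_pat.depth_sd, new_ctrl.depth_sd
    if rng.random() < 0.5:  # variability direction
        new_ctrl.jump_prob, new_pat.jump_prob = new_pat.jump_prob, new_ctrl.jump_prob
    return replace(config, control_lexsem=new_ctrl, patient_lexsem=new_pat)


def generate_language_pair(
    config: CohortConfig, target_n_per_group: int | None = None
) -> tuple[SyntheticCohort, SyntheticCohort]:
    """Source cohort plus a second-"language" target cohort.

    The target always shares the timing effect.  In ``scrambled_lexsem``
    mode its lexsem effect directions are re-randomized per component and
    its vocabulary/embedding table is disjoint (language-prefixed words).
    """
    source = generate_cohort(replace(config, transfer_mode="aligned"))
    target_config = replace(
        config,
        seed=config.seed + 104729,  # decorrelated but seed-derived
        n_per_group=target_n_per_group or config.n_per_group,
    )
    if config.transfer_mode == "scrambled_lexsem":
        scramble_rng = np.random.default_rng(config.seed + 7919)
        target_config = _scramble_lexsem(target_config, scramble_rng)
        target_config = replace(target_config, language="es")
    target = generate_cohort(target_config)
    return source, target


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Write WAVs (if rendered), transcripts, segment TSVs, manifest, truth."""
    import json

    from speechmark.io_preprocess import write_aligned_transcript, write_wav
    from speechmark.vad import write_segments_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest()
    for participant, record in zip(cohort.participants, manifest.participants):
        tpath = out / f"{participant.id}.transcript.tsv"
        write_aligned_transcript(participant.transcript, tpath)
        record.transcript_path = str(tpath)
        spath = out / f"{participant.id}.segments.tsv"
        write_segments_tsv(participant.segmentation, spath)
        record.segments_path = str(spath)
        if participant.audio is not None:
            wpath = out / f"{participant.id}.wav"
            write_wav(participant.audio, wpath)
            record.audio_path = str(wpath)
    manifest.to_json(out / "manifest.json")
    truth = {
        pid: {k: v for k, v in rec.items() if k != "segments"}
        for pid, rec in cohort.ground_truth.items()
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
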