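"""Lexico-semantic feature extraction.

Three families: word-class ratios (noun/verb/adjective/adverb proportions
over all words and over content words), semantic granularity (minimum
hypernym-path length to the root concept), and semantic variability
(variance of the distance series between embedding vectors of successive
filtered words).

Out-of-vocabulary words are excluded from granularity and variability
statistics (with a log record), never zero-imputed.  Absent features are
NaN.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from speechmark.io_preprocess import AlignedTranscript, Token
from speechmark.timing_features import STAT_NAMES, summary_stats

logger = logging.getLogger(__name__)

ROOT_CONCEPT = "entity"
CONTENT_CLASSES = ("noun", "verb", "adjective", "adverb")

#: default depth-bin boundaries: low <= 4, intermediate 5-7, high >= 8
DEFAULT_BINS = (4, 8)

VARIANT_NAMES = ("content", "nonrep_all", "nonrep_content")


@dataclass
class HypernymGraph:
    """Directed hypernym links toward a single root concept.

    ``parents`` maps each node to its hypernyms; ``word_to_nodes`` maps a
    surface form to candidate concept nodes (a word may be polysemous).
    """

    parents: dict[str, list[str]]
    word_to_nodes: dict[str, list[str]] = field(default_factory=dict)
    root: str = ROOT_CONCEPT
    _depth_cache: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.word_to_nodes:
            self.word_to_nodes = {n: [n] for n in self.nodes}
        self._check_acyclic_rooted()

    @property
    def nodes(self) -> set[str]:
        out = set(self.parents)
        for ps in self.parents.values():
            out.update(ps)
        return out

    def _check_acyclic_rooted(self) -> None:
        for node in self.nodes:
            if self.node_depth(node) is None:
                raise ValueError(f"root {self.root!r} unreachable from node {node!r}")

    def node_depth(self, node: str) -> int | None:
        """BFS shortest hypernym-path length (edge count) from node to root."""
        if node in self._depth_cache:
            return self._depth_cache[node]
        seen = {node}
        queue = deque([(node, 0)])
        while queue:
            current, d = queue.popleft()
            if current == self.root:
                self._depth_cache[node] = d
                return d
            for parent in self.parents.get(current, ()):
                if parent not in seen:
                    seen.add(parent)
                    queue.append((parent, d + 1))
        return None

    @classmethod
    def from_edge_list(
        cls, path: str | Path, word_map: Mapping[str, Sequence[str]] | None = None
    ) -> "HypernymGraph":
        """Load from a TSV of (child, parent) pairs, optionally with a word map."""
        parents: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            child, parent = line.split("\t")[:2]
            parents.setdefault(child, []).append(parent)
        wm = {w: list(ns) for w, ns in word_map.items()} if word_map else {}
        return cls(parents=parents, word_to_nodes=wm)

    @classmethod
    def from_wordnet(cls) -> "HypernymGraph":  # pragma: no cover - optional asset
        """Build from the NLTK WordNet noun hierarchy, when nltk is installed."""
        from nltk.corpus import wordnet as wn

        parents: dict[str, list[str]] = {}
        word_to_nodes: dict[str, list[str]] = {}
        for synset in wn.all_synsets(pos="n"):
            name = synset.name()
            parents[name] = [h.name() for h in synset.hypernyms()]
            for lemma in synset.lemma_names():
                word_to_nodes.setdefault(lemma.lower(), []).append(name)
        return cls(parents=parents, word_to_nodes=word_to_nodes, root="entity.n.01")


@dataclass
class EmbeddingTable:
    """Word -> vector map with a fixed dimension."""

    vectors: dict[str, np.ndarray]
    language: str = ""

    def __post_init__(self) -> None:
        dims = {np.asarray(v).shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {dims}")
        for w, v in self.vectors.items():
            arr = np.asarray(v, dtype=np.float64)
            if np.linalg.norm(arr) == 0:
                raise ValueError(f"zero-norm vector for word {w!r}")
            self.vectors[w] = arr

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).size if self.vectors else 0

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    @classmethod
    def from_word2vec_text(cls, path: str | Path, language: str = "") -> "EmbeddingTable":
        """Read word2vec-style text (optional count/dim header line)."""
        vectors: dict[str, np.ndarray] = {}
        lines = Path(path).read_text().splitlines()
        start = 1 if lines and len(lines[0].split()) == 2 else 0
        for line in lines[start:]:
            parts = line.rstrip().split(" ")
            if len(parts) < 2:
                continue
            vectors[parts[0]] = np.array([float(p) for p in parts[1:]])
        return cls(vectors=vectors, language=language)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def word_class_ratios(transcript: AlignedTranscript) -> dict[str, float]:
    """Noun/verb/adjective/adverb proportions over all and over content words."""
    if len(transcript) == 0:
        raise ValueError("empty transcript")
    total = len(transcript)
    counts = {pos: 0 for pos in CONTENT_CLASSES}
    for tok in transcript:
        if tok.pos in counts:
            counts[tok.pos] += 1
    n_content = sum(counts.values())
    out: dict[str, float] = {}
    for pos in CONTENT_CLASSES:
        out[f"lexsem__{pos}_ratio__all"] = counts[pos] / total
        out[f"lexsem__{pos}_ratio__content"] = (
            counts[pos] / n_content if n_content else math.nan
        )
    return out


def granularity(word: str, graph: HypernymGraph) -> int | None:
    """Minimum hypernym-path length from any sense of ``word`` to the root.

    Returns None (absent marker) for out-of-vocabulary words.
    """
    nodes = graph.word_to_nodes.get(word.lower())
    if not nodes:
        logger.debug("out-of-vocabulary word for granularity: %r", word)
        return None
    depths = [d for d in (graph.node_depth(n) for n in nodes) if d is not None]
    return min(depths) if depths else None


def granularity_features(
    transcript: AlignedTranscript,
    graph: HypernymGraph,
    bins: tuple[int, int] = DEFAULT_BINS,
    content_only: bool = False,
) -> dict[str, float]:
    """Depth statistics plus low/intermediate/high-granularity proportions.

    Bin proportions are computed over the *total* word count, so the three
    proportions sum to the in-vocabulary fraction of the text.
    """
    low_max, high_min = bins
    if not low_max < high_min:
        raise ValueError("bins must satisfy low_max < high_min")
    tokens = [t for t in transcript if t.is_content] if content_only else list(transcript)
    total = len(tokens)
    depths = []
    for tok in tokens:
        d = granularity(tok.text, graph)
        if d is not None:
            depths.append(d)
    out: dict[str, float] = {}
    if depths:
        stats = summary_stats(depths).as_dict()
        out.update({f"lexsem__granularity__{s}": v for s, v in stats.items()})
        arr = np.asarray(depths)
        out["lexsem__granularity_low_proportion"] = float((arr <= low_max).sum()) / total
        out["lexsem__granularity_intermediate_proportion"] = (
            float(((arr > low_max) & (arr < high_min)).sum()) / total
        )
        out["lexsem__granularity_high_proportion"] = float((arr >= high_min).sum()) / total
    else:
        logger.warning("no in-vocabulary words for granularity in %s", transcript.recording_id)
        out.update({f"lexsem__granularity__{s}": math.nan for s in STAT_NAMES})
        for b in ("low", "intermediate", "high"):
            out[f"lexsem__granularity_{b}_proportion"] = math.nan
    return out


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    return 1.0 - float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))


def euclidean_distance(u: np.ndarray, v: np.ndarray) -> float:
    return float(np.linalg.norm(u - v))


def _variant_tokens(tokens: Sequence[Token], variant: str) -> list[Token]:
    if variant == "content":
        return [t for t in tokens if t.is_content]
    if variant == "nonrep_all":
        pool = list(tokens)
    elif variant == "nonrep_content":
        pool = [t for t in tokens if t.is_content]
    else:
        raise KeyError(f"unknown variant {variant!r}")
    collapsed: list[Token] = []
    for tok in pool:
        if not collapsed or collapsed[-1].text.lower() != tok.text.lower():
            collapsed.append(tok)
    return collapsed


def semantic_variability(
    transcript: AlignedTranscript,
    table: EmbeddingTable,
    variant: str = "content",
    metric: str = "cosine",
) -> float:
    """Sample variance of distances between successive in-vocabulary vectors.

    ``variant`` filters the token sequence: ``content`` keeps content words;
    the ``nonrep_*`` variants additionally collapse runs of identical
    adjacent word forms.  Returns NaN when fewer than 2 distances remain.
    """
    dist = {"cosine": cosine_distance, "euclidean": euclidean_distance}[metric]
    tokens = _variant_tokens(transcript.tokens, variant)
    vectors = []
    for tok in tokens:
        key = tok.text.lower()
        if key in table:
            vectors.append(table[key])
        else:
            logger.debug("out-of-vocabulary word for variability: %r", tok.text)
    if len(vectors) < 3:
        return math.nan
    series = np.array([dist(vectors[i], vectors[i + 1]) for i in range(len(vectors) - 1)])
    return float(series.var(ddof=1))


def lexsem_feature_vector(
    transcript: AlignedTranscript,
    graph: HypernymGraph,
    table: EmbeddingTable,
    bins: tuple[int, int] = DEFAULT_BINS,
    metric: str = "cosine",
) -> dict[str, float]:
    """All lexico-semantic features for one transcript."""
    out = word_class_ratios(transcript)
    out.update(granularity_features(transcript, graph, bins))
    for variant in VARIANT_NAMES:
        out[f"lexsem__semantic_variability__{variant}"] = semantic_variability(
            transcript, table, variant, metric
        )
    return out
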