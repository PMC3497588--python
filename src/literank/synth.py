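"""Synthetic fixtures: mini vocabularies, planted-topic corpora, scores.

Every pipeline stage is testable without a PubMed download: this module
generates (a) a small MeSH-like heading list whose tokens cover a set of
synthetic topic vocabularies, (b) per-factor citation collections in which
each factor's documents draw most tokens from its assigned topic and the
rest from a shared background vocabulary (planted ground truth for ranking
tests), and (c) association-score samples drawn from a specified tri-modal
mixture (ground truth for curve-fit recovery tests).

All generators are deterministic under a fixed seed. The synthetic words
("t03w07", "bgw12") are deliberately artificial: no attempt is made to
imitate real biomedical language statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    FACTOR_CATEGORIES,
    CitationRecord,
    DocumentCollection,
    FactorSpec,
    write_factor_table,
    write_medline,
)
from .dictionary import MeshHeading
from .disease_model import TriModalParams
from .errors import InputError

__all__ = [
    "PlantedCorpusConfig",
    "topic_vocabulary",
    "generate_mesh_fixture",
    "generate_planted_corpus",
    "sample_trimodal",
    "write_corpus",
]


@dataclass(frozen=True)
class PlantedCorpusConfig:
    """Ground-truth layout of a planted-topic corpus.

    Defaults give 6 topics x 4 factors with 50 documents per factor at 30%
    background noise — small enough to decompose in seconds, structured
    enough that topic queries separate same-topic from other factors.
    """

    n_topics: int = 6
    words_per_topic: int = 20
    n_factors: int = 24
    docs_per_factor: int = 50
    doc_length: int = 40
    background_noise: float = 0.3
    n_background_words: int = 100
    seed: int = 0
    topic_of_factor: dict[str, int] | None = field(default=None)

    def __post_init__(self):
        for name in ("n_topics", "words_per_topic", "n_factors",
                     "docs_per_factor", "doc_length"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be positive")
        if not (0 <= self.background_noise < 1):
            raise InputError("background_noise must lie in [0, 1)")

    def factor_names(self) -> list[str]:
        return [f"factor{i:02d}" for i in range(self.n_factors)]

    def topic_assignment(self) -> dict[str, int]:
        """Factor -> topic; round-robin unless given explicitly."""
        if self.topic_of_factor is not None:
            return dict(self.topic_of_factor)
        return {
            name: i % self.n_topics
            for i, name in enumerate(self.factor_names())
        }


def topic_vocabulary(
    config: PlantedCorpusConfig,
) -> tuple[list[list[str]], list[str]]:
    """Deterministic synthetic vocabularies (independent of the seed).

    Topic t owns words "t{t}w{j}"; the shared background vocabulary is
    "bgw{j}". All words are alphanumeric and >= 3 characters, so they
    survive dictionary filtering.
    """
    topics = [
        [f"t{t:02d}w{j:02d}" for j in range(config.words_per_topic)]
        for t in range(config.n_topics)
    ]
    background = [f"bgw{j:03d}" for j in range(config.n_background_words)]
    return topics, background


def generate_mesh_fixture(
    n_headings: int,
    seed: int = 0,
    config: PlantedCorpusConfig | None = None,
) -> list[MeshHeading]:
    """Multiword MeSH-like headings covering the synthetic vocabularies.

    Every topic word (and every background word) appears in at least one
    heading, so the derived dictionary covers the whole planted corpus;
    remaining headings are random multiword draws.
    """
    if n_headings < 1:
        raise InputError("n_headings must be >= 1")
    config = config or PlantedCorpusConfig()
    topics, background = topic_vocabulary(config)
    all_words = [w for t in topics for w in t] + background
    rng = np.random.default_rng(seed)

    per_heading = max(3, -(-len(all_words) // n_headings))  # ceil
    headings: list[MeshHeading] = []
    for start in range(0, len(all_words), per_heading):
        chunk = all_words[start:start + per_heading]
        headings.append(MeshHeading(" ".join(chunk)))
    while len(headings) < n_headings:
        size = int(rng.integers(2, 6))
        words = rng.choice(all_words, size=size, replace=False)
        headings.append(MeshHeading(" ".join(words)))
    return headings[:n_headings] if len(headings) > n_headings else headings


def generate_planted_corpus(
    config: PlantedCorpusConfig,
) -> tuple[DocumentCollection, dict]:
    """Per-factor citation collections with planted topic structure.

    Each document of a factor assigned to topic t draws each token from
    topic t's vocabulary with probability (1 - background_noise) and from
    the background vocabulary otherwise. The returned ground truth records
    the factor-to-topic map and both vocabularies.
    """
    rng = np.random.default_rng(config.seed)
    topics, background = topic_vocabulary(config)
    assignment = config.topic_assignment()
    factors = [
        FactorSpec(
            name=name,
            query_terms=(name,),
            category=FACTOR_CATEGORIES[i % len(FACTOR_CATEGORIES)],
        )
        for i, name in enumerate(config.factor_names())
    ]
    documents_of: dict[str, list[CitationRecord]] = {}
    for fi, factor in enumerate(factors):
        topic_words = topics[assignment[factor.name]]
        docs = []
        for di in range(config.docs_per_factor):
            from_background = rng.random(config.doc_length) < config.background_noise
            tokens = [
                background[rng.integers(len(background))]
                if bg
                else topic_words[rng.integers(len(topic_words))]
                for bg in from_background
            ]
            n_title = min(5, len(tokens))
            docs.append(
                CitationRecord(
                    pmid=f"9{fi:03d}{di:04d}",
                    title=" ".join(tokens[:n_title]).capitalize(),
                    abstract=" ".join(tokens[n_title:]),
                    year=2000 + di % 20,
                )
            )
        documents_of[factor.name] = docs
    collection = DocumentCollection(factors=factors, documents_of=documents_of)
    ground_truth = {
        "topic_of_factor": assignment,
        "topic_words": topics,
        "background_words": background,
        "seed": config.seed,
    }
    return collection, ground_truth


def sample_trimodal(
    params: TriModalParams, n: int, seed: int = 0
) -> np.ndarray:
    """Draw scores from the mixture the tri-modal curve describes.

    Component i is chosen with probability proportional to alpha_i*sigma_i
    (each unnormalized component integrates to alpha_i*sigma_i*sqrt(pi)),
    and a value is drawn from a Gaussian with mean mu_i and standard
    deviation sigma_i/sqrt(2) — the density proportional to
    exp(-((x-mu_i)/sigma_i)^2). Samples are clipped to [-1, 1] (a known,
    negligible boundary-mass artifact for realistic parameter ranges).
    """
    if n < 1:
        raise InputError("n must be >= 1")
    weights = np.array(
        [a * s for a, s in zip(params.alpha, params.sigma)], dtype=float
    )
    if weights.sum() <= 0:
        raise InputError("all amplitudes are zero; nothing to sample")
    rng = np.random.default_rng(seed)
    components = rng.choice(3, size=n, p=weights / weights.sum())
    mus = np.asarray(params.mu)[components]
    sds = np.asarray(params.sigma)[components] / np.sqrt(2.0)
    return np.clip(rng.normal(mus, sds), -1.0, 1.0)


def write_corpus(
    collection: DocumentCollection,
    out_dir: str | Path,
    ground_truth: dict | None = None,
) -> dict[str, Path]:
    """Emit MEDLINE files (one per factor), a factor table, ground truth.

    Returns the factor-name -> MEDLINE-file mapping usable with
    :func:`literank.corpus.assemble_collection`.
    """
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    for factor in collection.factors:
        path = out / f"{factor.name.replace(' ', '_')}.medline"
        write_medline(collection.documents_of[factor.name], path)
        files[factor.name] = path
    write_factor_table(collection.factors, out / "factors.tsv")
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=2) + "\n", encoding="utf-8"
        )
    return files
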