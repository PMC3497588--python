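"""MeSH-derived dictionaries for the latent-semantic engine.

Medical Subject Headings (MeSH) are multiword controlled-vocabulary terms
("Reproductive and Urinary Physiological Phenomena"). This module reduces a
set of headings to the flat, filtered single-word dictionary that
parameterizes the term-document matrix: every heading is split into
lowercase word tokens, then duplicates, stop words and words shorter than a
minimum length are removed, and the survivors are sorted lexicographically
so the dictionary is deterministic for a given input set.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import InputError

__all__ = [
    "MeshHeading",
    "Dictionary",
    "tokenize_heading",
    "tokenize_text",
    "build_vocabulary",
    "filter_vocabulary",
    "load_mesh_headings",
    "load_stopwords",
    "save_dictionary",
    "load_dictionary",
]

#: Tokens are maximal runs of ASCII letters/digits after normalization;
#: hyphens, slashes, commas etc. all delimit. Alphanumerics like "b12" are
#: legitimate tokens (vitamin names depend on them).
_TOKEN_RE = re.compile(r"[0-9a-z]+")

DEFAULT_MIN_LENGTH = 3


def _normalize(text: str) -> str:
    """NFKD-normalize, strip diacritics, lowercase."""
    decomposed = unicodedata.normalize("NFKD", text)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return stripped.lower()


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH subject heading, optionally with its tree numbers."""

    label: str
    tree_numbers: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.label.strip():
            raise InputError("MeSH heading label is empty")


@dataclass(frozen=True)
class Dictionary:
    """Ordered, filtered word vocabulary.

    ``words`` is lexicographically sorted and duplicate-free; ``index_of``
    maps each word to its 0-based row in the term-document matrix;
    ``provenance`` records the source and filter settings that produced it.
    """

    words: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(
            self, "index_of", {w: i for i, w in enumerate(self.words)}
        )
        if len(self.index_of) != len(self.words):
            raise InputError("dictionary contains duplicate words")

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index_of

    def __iter__(self):
        return iter(self.words)


def tokenize_text(text: str) -> list[str]:
    """Split arbitrary text into lowercase word tokens.

    The single tokenizer used everywhere (headings, abstracts, queries):
    split on any non-alphanumeric character, lowercase, keep order, no
    filtering.
    """
    return _TOKEN_RE.findall(_normalize(text))


def tokenize_heading(heading: MeshHeading | str) -> list[str]:
    """Reduce one heading to its single-word tokens, before any filtering.

    >>> tokenize_heading(MeshHeading("Heart-Assist Devices"))
    ['heart', 'assist', 'devices']
    """
    label = heading.label if isinstance(heading, MeshHeading) else heading
    if not label.strip():
        raise InputError("cannot tokenize an empty heading")
    return tokenize_text(label)


def build_vocabulary(headings: Sequence[MeshHeading | str]) -> list[str]:
    """Concatenate the tokens of all headings; duplicates retained."""
    if not headings:
        raise InputError("heading list is empty")
    tokens: list[str] = []
    for h in headings:
        tokens.extend(tokenize_heading(h))
    return tokens


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one word per line, ``#`` comments).

    With no path, the versioned English list shipped with the package is
    used.
    """
    if path is None:
        text = (
            resources.files("literank.data")
            .joinpath("stopwords_en.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(_normalize(line))
    return frozenset(words)


def filter_vocabulary(
    tokens: Iterable[str],
    stoplist: frozenset[str] | set[str] | None = None,
    min_length: int = DEFAULT_MIN_LENGTH,
    provenance: dict | None = None,
) -> Dictionary:
    """Remove duplicates, stop words and short words; sort lexicographically.

    ``stoplist=None`` uses the packaged English list. Raises
    :class:`InputError` if nothing survives filtering.
    """
    if min_length < 1:
        raise InputError(f"min_length must be >= 1, got {min_length}")
    if stoplist is None:
        stoplist = load_stopwords()
    kept = sorted(
        {t for t in tokens if len(t) >= min_length and t not in stoplist}
    )
    if not kept:
        raise InputError("no words survive filtering (empty dictionary)")
    prov = dict(provenance or {})
    prov.setdefault("min_length", min_length)
    prov.setdefault("stoplist_size", len(stoplist))
    return Dictionary(words=tuple(kept), provenance=prov)


def _read_flat_list(lines: Iterable[str]) -> list[MeshHeading]:
    headings = []
    for line in lines:
        line = line.strip()
        if line:
            headings.append(MeshHeading(line))
    return headings


def _read_descriptor_export(lines: Iterable[str]) -> list[MeshHeading]:
    """Parse the MeSH ASCII descriptor dialect (``MH = ...`` / ``MN = ...``)."""
    headings: list[MeshHeading] = []
    label: str | None = None
    trees: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if line.startswith("MH = "):
            if label is not None:
                headings.append(MeshHeading(label, tuple(trees)))
            label = line[len("MH = "):].strip()
            trees = []
            if not label:
                raise InputError(f"empty MH field at line {lineno}")
        elif line.startswith("MN = "):
            tree = line[len("MN = "):].strip()
            if label is None:
                raise InputError(
                    f"MN field before any MH record at line {lineno}"
                )
            trees.append(tree)
    if label is not None:
        headings.append(MeshHeading(label, tuple(trees)))
    return headings


def load_mesh_headings(
    source: str | Path | IO[str], dialect: str = "flat_list"
) -> list[MeshHeading]:
    """Read headings from a flat list or a MeSH ASCII descriptor export.

    ``flat_list``: one heading per line. ``descriptor_export``: records
    introduced by ``MH = `` lines, tree numbers on ``MN = `` lines. Order
    is preserved.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    if dialect == "flat_list":
        headings = _read_flat_list(lines)
    elif dialect == "descriptor_export":
        headings = _read_descriptor_export(lines)
    else:
        raise InputError(f"unknown dialect {dialect!r}")
    if not headings:
        raise InputError("no headings found in source stream")
    return headings


def save_dictionary(dictionary: Dictionary, out_dir: str | Path) -> Path:
    """Write one word per line plus a JSON provenance sidecar.

    Returns the path of the word-list file. Output is byte-identical for
    identical inputs and settings.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    words_path = out / "dictionary.txt"
    words_path.write_text(
        "\n".join(dictionary.words) + "\n", encoding="utf-8"
    )
    sidecar = {
        "n_words": len(dictionary),
        "provenance": dictionary.provenance,
    }
    (out / "dictionary.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return words_path


def load_dictionary(in_dir: str | Path) -> Dictionary:
    """Inverse of :func:`save_dictionary`."""
    in_dir = Path(in_dir)
    words = tuple(
        w
        for w in (in_dir / "dictionary.txt")
        .read_text(encoding="utf-8")
        .splitlines()
        if w
    )
    prov = {}
    sidecar = in_dir / "dictionary.json"
    if sidecar.exists():
        prov = json.loads(sidecar.read_text(encoding="utf-8")).get(
            "provenance", {}
        )
    return Dictionary(words=words, provenance=prov)
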