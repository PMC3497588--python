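"""MEDLINE citation parsing and per-factor document collections.

The knowledge space is built from per-factor collections of PubMed
citations (title + abstract). Factors are the curated entities — diseases,
signs, chemical compounds, lifestyle exposures — whose association with a
query disease the engine scores. Parsing of the tagged MEDLINE export
format (PMID-, TI-, AB- fields) is delegated to Bio.Medline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import IO, Mapping, Sequence

from Bio import Medline

from .errors import InputError

__all__ = [
    "CitationRecord",
    "FactorSpec",
    "DocumentCollection",
    "parse_medline",
    "document_text",
    "assemble_collection",
    "write_medline",
    "read_factor_table",
    "write_factor_table",
    "reference_factors",
    "FACTOR_CATEGORIES",
]

logger = logging.getLogger(__name__)

FACTOR_CATEGORIES = (
    "disease/medical condition",
    "sign/symptom",
    "chemical compound",
    "environmental/lifestyle",
)


@dataclass(frozen=True)
class CitationRecord:
    """One citation: PMID, title, abstract (possibly empty), optional year."""

    pmid: str
    title: str = ""
    abstract: str = ""
    year: int | None = None

    def __post_init__(self):
        if not self.pmid:
            raise InputError("citation has empty PMID")
        if not (self.title or self.abstract):
            raise InputError(f"citation {self.pmid} has neither title nor abstract")


@dataclass(frozen=True)
class FactorSpec:
    """A curated factor: canonical name, retrieval synonyms, category."""

    name: str
    query_terms: tuple[str, ...]
    category: str = FACTOR_CATEGORIES[0]

    def __post_init__(self):
        if not self.name:
            raise InputError("factor name is empty")
        if not self.query_terms:
            raise InputError(f"factor {self.name!r} has no query terms")


@dataclass
class DocumentCollection:
    """Per-factor citation lists; the corpus the eigen space is built from."""

    factors: list[FactorSpec]
    documents_of: dict[str, list[CitationRecord]] = field(default_factory=dict)

    def __post_init__(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise InputError("duplicate factor names in collection")
        if set(self.documents_of) != set(names):
            raise InputError("documents_of keys do not match factor names")
        for name, docs in self.documents_of.items():
            if not docs:
                raise InputError(f"factor {name!r} has no documents")

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def n_documents(self) -> int:
        return sum(len(d) for d in self.documents_of.values())

    def counts(self) -> dict[str, int]:
        return {f.name: len(self.documents_of[f.name]) for f in self.factors}


def _parse_year(dp: str | None) -> int | None:
    if not dp:
        return None
    head = dp.strip()[:4]
    return int(head) if head.isdigit() else None


def parse_medline(source: str | Path | IO[str]) -> list[CitationRecord]:
    """Parse a MEDLINE tagged-format stream into citation records.

    Continuation lines are joined with single spaces (Bio.Medline
    semantics). Records lacking both title and abstract are dropped with a
    warning; a stream yielding no usable records is rejected.
    """
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        handle = open(source, encoding="utf-8")
        close = True
    try:
        records = []
        for raw in Medline.parse(handle):
            pmid = raw.get("PMID", "")
            title = (raw.get("TI") or "").strip()
            abstract = (raw.get("AB") or "").strip()
            if not pmid:
                continue
            if not (title or abstract):
                logger.warning(
                    "dropping citation %s: no title and no abstract", pmid
                )
                continue
            records.append(
                CitationRecord(
                    pmid=pmid,
                    title=title,
                    abstract=abstract,
                    year=_parse_year(raw.get("DP")),
                )
            )
    finally:
        if close:
            handle.close()
    if not records:
        raise InputError("no parseable MEDLINE records in stream")
    return records


def document_text(record: CitationRecord) -> str:
    """Title and abstract concatenated with a space; no other normalization."""
    if record.title and record.abstract:
        return f"{record.title} {record.abstract}"
    return record.title or record.abstract


def _wrap_field(tag: str, value: str) -> str:
    # MEDLINE uses a 4-char tag padded with '-' at column 5; continuation
    # lines are indented 6 spaces. We emit single-line fields (parsers join
    # continuations anyway, and values here contain no newlines).
    return f"{tag:<4}- {value}"


def write_medline(records: Sequence[CitationRecord], target: str | Path | IO[str]) -> None:
    """Serialize records back to MEDLINE tagged format (round-trip safe)."""
    buf = StringIO()
    for rec in records:
        buf.write(_wrap_field("PMID", rec.pmid) + "\n")
        if rec.year is not None:
            buf.write(_wrap_field("DP", str(rec.year)) + "\n")
        if rec.title:
            buf.write(_wrap_field("TI", rec.title) + "\n")
        if rec.abstract:
            buf.write(_wrap_field("AB", rec.abstract) + "\n")
        buf.write("\n")
    text = buf.getvalue()
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text, encoding="utf-8")


def assemble_collection(
    factors: Sequence[FactorSpec],
    files: Mapping[str, str | Path | IO[str]],
    min_year: int | None = None,
    max_year: int | None = None,
) -> DocumentCollection:
    """Parse one MEDLINE file per factor and build the collection.

    ``min_year``/``max_year`` optionally restrict citations by publication
    year (records without a year are kept). Per-factor counts and a
    min/mean/max summary are logged; a factor whose file yields no usable
    records raises :class:`InputError` naming the factor.
    """
    if not factors:
        raise InputError("factor list is empty")
    missing = [f.name for f in factors if f.name not in files]
    if missing:
        raise InputError(f"no MEDLINE file supplied for factors: {missing}")
    documents_of: dict[str, list[CitationRecord]] = {}
    for factor in factors:
        try:
            records = parse_medline(files[factor.name])
        except InputError as exc:
            raise InputError(
                f"factor {factor.name!r}: {exc}"
            ) from exc
        if min_year is not None or max_year is not None:
            records = [
                r
                for r in records
                if r.year is None
                or ((min_year is None or r.year >= min_year)
                    and (max_year is None or r.year <= max_year))
            ]
        if not records:
            raise InputError(
                f"factor {factor.name!r} has zero usable records after filtering"
            )
        documents_of[factor.name] = records
        logger.info("factor %s: %d documents", factor.name, len(records))
    counts = [len(v) for v in documents_of.values()]
    logger.info(
        "collection: %d factors, %d documents (min %d / mean %.1f / max %d per factor)",
        len(factors), sum(counts), min(counts), sum(counts) / len(counts), max(counts),
    )
    return DocumentCollection(factors=list(factors), documents_of=documents_of)


def read_factor_table(path: str | Path) -> list[FactorSpec]:
    """Read a factor list from a TSV: name, category, query_terms.

    ``query_terms`` are semicolon-joined; a missing column falls back to
    the factor name itself. Lines starting with '#' are comments.
    """
    factors = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        name = parts[0].strip()
        category = parts[1].strip() if len(parts) > 1 and parts[1].strip() else FACTOR_CATEGORIES[0]
        terms = (
            tuple(t.strip() for t in parts[2].split(";") if t.strip())
            if len(parts) > 2 and parts[2].strip()
            else (name,)
        )
        if not name:
            raise InputError(f"{path}: empty factor name at line {lineno}")
        factors.append(FactorSpec(name=name, query_terms=terms, category=category))
    if not factors:
        raise InputError(f"{path}: no factors found")
    return factors


def reference_factors() -> list[FactorSpec]:
    """The versioned, expert-curated reference factor list shipped with
    the package (diseases, signs, chemical compounds, lifestyle factors)."""
    from importlib import resources

    with resources.as_file(
        resources.files("literank.data").joinpath("reference_factors.tsv")
    ) as path:
        return read_factor_table(path)


def write_factor_table(factors: Sequence[FactorSpec], path: str | Path) -> None:
    lines = ["# name\tcategory\tquery_terms"]
    for f in factors:
        lines.append(f"{f.name}\t{f.category}\t{';'.join(f.query_terms)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
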