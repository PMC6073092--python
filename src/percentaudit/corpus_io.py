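"""Read, write and filter abstract records.

A corpus is a sequence of :class:`AbstractRecord`, one per paper, carried in
JSON-lines (one object per line) or CSV (comma-separated, quoted fields,
UTF-8, header row; ``publication_types`` ";"-joined).  Publication-type
filtering mirrors the include/exclude logic used to restrict a bibliographic
search to research articles: a record must carry at least one included type
and no excluded type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AbstractRecord",
    "CorpusFormatError",
    "DEFAULT_INCLUDE_TYPES",
    "DEFAULT_EXCLUDE_TYPES",
    "read_corpus",
    "write_corpus",
    "passes_type_filter",
    "filter_corpus",
]

#: Publication types that mark a record as a research article.
DEFAULT_INCLUDE_TYPES: tuple[str, ...] = (
    "Journal Article",
    "Clinical Trial",
    "Meta-Analysis",
    "Review",
    "Randomized Controlled Trial",
    "Multicenter Study",
)

#: Publication types that disqualify a record even when an included type is
#: present (e.g. a retraction of a clinical trial carries both).
DEFAULT_EXCLUDE_TYPES: tuple[str, ...] = (
    "Biography",
    "Conference",
    "Comment",
    "Corrected",
    "Editorial",
    "Erratum",
    "Guideline",
    "Historical",
    "News",
    "Lectures",
    "Letter",
    "Retraction",
)

_REQUIRED_FIELDS = ("record_id", "journal", "year", "publication_types", "abstract_text")


class CorpusFormatError(ValueError):
    """A record is malformed; the message names the offending row/line."""


@dataclass
class AbstractRecord:
    """One paper: identifier, journal, year, publication types, abstract text.

    ``abstract_text`` may be empty; such a record simply yields no percent
    mentions downstream.  ``journal`` is an opaque grouping label.
    """

    record_id: str
    journal: str
    year: int
    publication_types: list[str] = field(default_factory=list)
    abstract_text: str = ""

    def __post_init__(self) -> None:
        if not self.record_id:
            raise CorpusFormatError("record_id must be non-empty")
        self.year = int(self.year)


def _record_from_mapping(obj: dict, index: int) -> AbstractRecord:
    for key in _REQUIRED_FIELDS:
        if key not in obj or (isinstance(obj[key], float) and pd.isna(obj[key])):
            raise CorpusFormatError(f"record {index}: missing required field {key!r}")
    types = obj["publication_types"]
    if isinstance(types, str):
        types = [t for t in (s.strip() for s in types.split(";")) if t]
    return AbstractRecord(
        record_id=str(obj["record_id"]),
        journal=str(obj["journal"]),
        year=int(obj["year"]),
        publication_types=list(types),
        abstract_text="" if obj["abstract_text"] is None else str(obj["abstract_text"]),
    )


def read_corpus(path: str | Path, format: str = "jsonl") -> list[AbstractRecord]:
    """Read a corpus file into records, preserving input order.

    Parameters
    ----------
    path:
        File to read.
    format:
        ``"jsonl"`` (one JSON object per line) or ``"csv"``.

    Raises
    ------
    CorpusFormatError
        If a record is missing a required field (the message names the
        zero-based record index) or a ``record_id`` is duplicated.
    """
    path = Path(path)
    records: list[AbstractRecord] = []
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as handle:
            for index, line in enumerate(handle):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"record {index}: invalid JSON ({exc})") from exc
                records.append(_record_from_mapping(obj, index))
    elif format == "csv":
        frame = pd.read_csv(path, dtype={"record_id": str}, keep_default_na=False)
        missing = [c for c in _REQUIRED_FIELDS if c not in frame.columns]
        if missing:
            raise CorpusFormatError(f"missing required column(s): {', '.join(missing)}")
        for index, row in enumerate(frame.to_dict("records")):
            for key in ("record_id", "journal", "year"):
                if row[key] == "":
                    raise CorpusFormatError(f"record {index}: missing required field {key!r}")
            records.append(_record_from_mapping(row, index))
    else:
        raise ValueError(f"unknown corpus format: {format!r}")

    seen: set[str] = set()
    for record in records:
        if record.record_id in seen:
            raise CorpusFormatError(f"duplicate record_id: {record.record_id!r}")
        seen.add(record.record_id)
    return records


def write_corpus(records: Iterable[AbstractRecord], path: str | Path, format: str = "jsonl") -> None:
    """Write records to ``path`` in the named format (inverse of read_corpus)."""
    path = Path(path)
    rows = [
        {
            "record_id": r.record_id,
            "journal": r.journal,
            "year": r.year,
            "publication_types": r.publication_types,
            "abstract_text": r.abstract_text,
        }
        for r in records
    ]
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as handle:
            for row in rows:
                handle.write(json.dumps(row, ensure_ascii=False) + "\n")
    elif format == "csv":
        for row in rows:
            row["publication_types"] = ";".join(row["publication_types"])
        pd.DataFrame(rows, columns=list(_REQUIRED_FIELDS)).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")


def passes_type_filter(
    record: AbstractRecord,
    include_types: Sequence[str] = DEFAULT_INCLUDE_TYPES,
    exclude_types: Sequence[str] = DEFAULT_EXCLUDE_TYPES,
) -> bool:
    """True iff the record has ≥1 included type and no excluded type.

    Matching is case-insensitive substring on the record's type strings, so
    "Historical Article" matches the exclude entry "Historical"; bibliographic
    type strings vary in suffixes.
    """
    types = [t.casefold() for t in record.publication_types]
    has_include = any(inc.casefold() in t for t in types for inc in include_types)
    has_exclude = any(exc.casefold() in t for t in types for exc in exclude_types)
    return has_include and not has_exclude


def filter_corpus(
    records: Iterable[AbstractRecord],
    include_types: Sequence[str] = DEFAULT_INCLUDE_TYPES,
    exclude_types: Sequence[str] = DEFAULT_EXCLUDE_TYPES,
) -> list[AbstractRecord]:
    """Keep the records passing the publication-type filter, in order."""
    return [r for r in records if passes_type_filter(r, include_types, exclude_types)]
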