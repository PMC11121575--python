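"""Disease lexicon built from MeSH descriptor records.

PubMed indexes every article with MeSH descriptors; disease descriptors live
under 22 top-level disease categories of the MeSH tree. This module turns a
flat export of (term, category) pairs into a matching dictionary: normalized
descriptor string -> canonical display term. Matching against MH index lines
is exact on the normalized string — MeSH indexing uses descriptor names
verbatim, so no synonym expansion is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

from .errors import EmptyLexiconError, InvalidTermError

__all__ = [
    "MeshDescriptor",
    "DiseaseLexicon",
    "normalize_term",
    "build_lexicon",
    "match_heading",
    "read_descriptor_tsv",
    "write_lexicon_tsv",
]

# Unicode apostrophe variants seen in MeSH exports and PubMed MH lines.
_APOSTROPHES = str.maketrans({"’": "'", "‘": "'", "ʼ": "'", "´": "'"})
_WS = re.compile(r"\s+")


@dataclass(frozen=True)
class MeshDescriptor:
    """One MeSH disease descriptor record: a term plus its category labels."""

    term: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term.strip():
            raise InvalidTermError("descriptor term is empty")
        if not self.categories:
            raise InvalidTermError(f"descriptor {self.term!r} has no categories")


@dataclass
class DiseaseLexicon:
    """Matching dictionary: normalized term -> canonical display term.

    ``source_count`` is the number of raw descriptor records consumed;
    ``unique_count`` the number of deduplicated entries that survived
    category exclusion. Both are provenance metadata — they depend on the
    MeSH version of the export and are never invariants of the lexicon.
    """

    entries: dict[str, str]
    excluded_categories: frozenset[str] = frozenset()
    source_count: int = 0
    unique_count: int = field(default=0)

    def __post_init__(self) -> None:
        self.unique_count = len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, normalized: str) -> bool:
        return normalized in self.entries


def normalize_term(raw: str) -> str:
    """Normalize a MeSH heading or descriptor for exact matching.

    Lowercases, strips a leading major-topic marker ``*``, cuts any
    subheading suffix at the first ``/`` (``"Disease/therapy"`` ->
    ``"disease"``), trims and collapses whitespace, and maps Unicode
    apostrophes to ASCII.

    Raises
    ------
    InvalidTermError
        If the input is empty or whitespace-only (before or after cutting).
    """
    if not raw or not raw.strip():
        raise InvalidTermError("empty term")
    term = raw.strip()
    if term.startswith("*"):
        term = term[1:]
    term = term.split("/", 1)[0]
    term = _WS.sub(" ", term.strip()).translate(_APOSTROPHES).lower()
    if not term:
        raise InvalidTermError(f"term {raw!r} is empty after normalization")
    return term


def build_lexicon(
    descriptors: Iterable[MeshDescriptor],
    excluded_categories: Iterable[str] = (),
) -> DiseaseLexicon:
    """Build the disease lexicon from descriptor records.

    A descriptor is dropped only when *all* of its categories are excluded:
    a disease cross-listed under a retained category survives. Terms are
    normalized and deduplicated; the first-seen spelling becomes the
    canonical display term.

    Raises
    ------
    EmptyLexiconError
        If no entry survives exclusion and deduplication.
    """
    excluded = frozenset(excluded_categories)
    entries: dict[str, str] = {}
    source_count = 0
    for desc in descriptors:
        source_count += 1
        if desc.categories <= excluded:
            continue
        key = normalize_term(desc.term)
        entries.setdefault(key, desc.term.strip())
    if not entries:
        raise EmptyLexiconError(
            f"no lexicon entries survived ({source_count} records, "
            f"excluded categories: {sorted(excluded) or 'none'})"
        )
    return DiseaseLexicon(entries=entries, excluded_categories=excluded, source_count=source_count)


def match_heading(lexicon: DiseaseLexicon, heading: str) -> Optional[str]:
    """Return the canonical term for an MH line, or None.

    Exact-match semantics on the normalized heading: qualifiers and the
    major-topic marker are stripped by normalization, but no substring or
    fuzzy matching is performed (``"Alzheimer"`` does not match
    ``"Alzheimer Disease"``).
    """
    try:
        key = normalize_term(heading)
    except InvalidTermError:
        return None
    return lexicon.entries.get(key)


def read_descriptor_tsv(stream: IO[str]) -> list[MeshDescriptor]:
    """Read descriptors from a two-column TSV: ``term<TAB>category``.

    One descriptor per row (one term-category pair), so the raw record count
    matches the file; a term listed under several categories yields several
    records and survives exclusion if any of its rows does. A
    ``term<TAB>category`` header row is skipped if present.
    """
    descriptors: list[MeshDescriptor] = []
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InvalidTermError(f"line {lineno}: expected 2 tab-separated fields, got {len(parts)}")
        term, category = (p.strip() for p in parts)
        if lineno == 1 and (term.lower(), category.lower()) == ("term", "category"):
            continue
        if not term or not category:
            raise InvalidTermError(f"line {lineno}: empty term or category")
        descriptors.append(MeshDescriptor(term=term, categories=frozenset({category})))
    return descriptors


def write_lexicon_tsv(lexicon: DiseaseLexicon, stream: IO[str]) -> None:
    """Write ``normalized_term<TAB>canonical_term`` rows, sorted for stable diffs."""
    for key in sorted(lexicon.entries):
        stream.write(f"{key}\t{lexicon.entries[key]}\n")
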