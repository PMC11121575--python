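"""MEDLINE/PubMed text-format corpora.

The "PubMed format" download dialect: records separated by blank lines, each
line ``TAG - value`` with the tag padded to four characters, continuation
lines indented. Parsing is delegated to :mod:`Bio.Medline`; only the PMID
and MH (MeSH heading) fields are interpreted downstream, but all other tags
are carried opaquely so a round trip preserves them where present.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Optional

from Bio import Medline

from .errors import DuplicatePMIDError
from .lexicon import DiseaseLexicon, match_heading

__all__ = ["Article", "Corpus", "parse_medline", "write_medline", "disease_set"]

logger = logging.getLogger(__name__)

# Emission order for known tags; anything else follows alphabetically.
_TAG_ORDER = {"PMID": 0, "TI": 1, "AB": 2, "MH": 3}


@dataclass
class Article:
    """One MEDLINE record: PMID plus its MeSH index, raw MH strings in order."""

    pmid: str
    mesh_headings: list[str] = field(default_factory=list)
    extra_tags: dict[str, object] = field(default_factory=dict)


@dataclass
class Corpus:
    """A set of articles with no duplicate PMIDs plus free-text provenance."""

    articles: list[Article] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.articles)


def parse_medline(stream: IO[str], provenance: str = "") -> Corpus:
    """Parse a MEDLINE-format stream into a :class:`Corpus`.

    MH continuation lines are joined by a single space. Records lacking a
    PMID are skipped with a logged warning; a repeated PMID raises
    :class:`DuplicatePMIDError` because article counts drive every
    downstream statistic.
    """
    articles: list[Article] = []
    seen: set[str] = set()
    skipped = 0
    for record in Medline.parse(stream):
        pmid = record.get("PMID")
        if not pmid:
            skipped += 1
            continue
        pmid = str(pmid).strip()
        if pmid in seen:
            raise DuplicatePMIDError(f"duplicate PMID {pmid} in corpus")
        seen.add(pmid)
        headings = [str(h) for h in record.get("MH", [])]
        extra = {k: v for k, v in record.items() if k not in ("PMID", "MH")}
        articles.append(Article(pmid=pmid, mesh_headings=headings, extra_tags=extra))
    if skipped:
        logger.warning("skipped %d record(s) without a PMID", skipped)
    return Corpus(articles=articles, provenance=provenance)


def _emit(stream: IO[str], tag: str, value: str) -> None:
    # MH values are written unwrapped: the parser joins continuations with a
    # space, so wrapping inside a heading would not round-trip verbatim.
    stream.write(f"{tag:<4}- {value}\n")


def write_medline(corpus: Corpus, stream: IO[str]) -> None:
    """Write a corpus in MEDLINE text format readable by :func:`parse_medline`.

    ``parse_medline(write_medline(c))`` reproduces every article's PMID and
    MH list exactly; opaque tags captured at parse time are re-emitted.
    """
    for article in corpus.articles:
        _emit(stream, "PMID", article.pmid)
        tags = sorted(article.extra_tags, key=lambda t: (_TAG_ORDER.get(t, 99), t))
        for tag in tags:
            value = article.extra_tags[tag]
            values = value if isinstance(value, list) else [value]
            for v in values:
                _emit(stream, tag, str(v))
        for heading in article.mesh_headings:
            _emit(stream, "MH", heading)
        stream.write("\n")


def disease_set(article: Article, lexicon: DiseaseLexicon) -> set[str]:
    """Canonical disease terms mentioned in an article's MeSH index.

    Deduplicated: the same disease under two qualifiers counts once.
    Non-disease headings (e.g. "Comorbidity") simply do not match.
    """
    out: set[str] = set()
    for heading in article.mesh_headings:
        term: Optional[str] = match_heading(lexicon, heading)
        if term is not None:
            out.add(term)
    return out
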