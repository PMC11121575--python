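"""Disease gene sets and multimorbidity signatures.

Consumes GMT (Gene Matrix Transposed) collections of disease-associated
gene sets — one set per line: name, description, then gene symbols — and
groups genes by their exact disease membership. A multimorbidity signature
is a maximal grouping: a gene contained in the index disease's set and in
the sets of two or more comorbid diseases is listed once, under exactly the
diseases that contain it, never again under subsets of them. Signatures
therefore partition the multimorbid genes.

Gene symbols are compared case-insensitively after uppercasing; no alias or
homology resolution is attempted (input sets are expected to carry
already-harmonized single-species symbols).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable

from .errors import (
    DuplicateSetError,
    GMTParseError,
    InsufficientCollectionError,
    UnknownDiseaseError,
)

__all__ = [
    "GeneSetCollection",
    "MultimorbiditySignature",
    "read_gmt",
    "write_gmt",
    "common_genes",
    "multimorbidity_table",
    "pairwise_summary",
    "write_multimorbidity_tsv",
    "write_pairwise_tsv",
]


@dataclass
class GeneSetCollection:
    """Disease label -> gene-symbol set, with one label marked as the index."""

    sets: dict[str, set[str]]
    index_disease: str

    def __post_init__(self) -> None:
        if self.index_disease not in self.sets:
            raise UnknownDiseaseError(
                f"index disease {self.index_disease!r} not among sets {sorted(self.sets)}"
            )
        self.sets = {
            label: {g.strip().upper() for g in genes if g.strip()}
            for label, genes in self.sets.items()
        }


@dataclass(frozen=True)
class MultimorbiditySignature:
    """Genes whose disease membership is exactly ``diseases`` (index included)."""

    diseases: frozenset[str]
    genes: frozenset[str]

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def read_gmt(stream: IO[str], index_disease: str) -> GeneSetCollection:
    """Read a GMT stream: ``name<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a line collapse (set semantics); a repeated set
    name or a line with fewer than three fields is an error.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise GMTParseError(f"line {lineno}: expected >= 3 tab-separated fields")
        name = parts[0].strip()
        if not name:
            raise GMTParseError(f"line {lineno}: empty set name")
        if name in sets:
            raise DuplicateSetError(f"line {lineno}: duplicate set name {name!r}")
        sets[name] = {g.strip().upper() for g in parts[2:] if g.strip()}
    return GeneSetCollection(sets=sets, index_disease=index_disease)


def write_gmt(collection: GeneSetCollection, stream: IO[str]) -> None:
    for label in sorted(collection.sets):
        genes = "\t".join(sorted(collection.sets[label]))
        stream.write(f"{label}\tna\t{genes}\n")


def common_genes(collection: GeneSetCollection, disease_a: str, disease_b: str) -> set[str]:
    """Exact intersection of two disease gene sets."""
    for label in (disease_a, disease_b):
        if label not in collection.sets:
            raise UnknownDiseaseError(f"unknown disease label {label!r}")
    return collection.sets[disease_a] & collection.sets[disease_b]


def _row_sort_key(sig: MultimorbiditySignature) -> tuple:
    label = ", ".join(sorted(sig.diseases))
    return (-len(sig.diseases), -len(sig.genes), label)


def multimorbidity_table(collection: GeneSetCollection) -> list[MultimorbiditySignature]:
    """Group genes by exact disease membership; keep multimorbid signatures.

    A row requires the index disease plus at least two comorbid diseases
    (three or more diseases sharing the gene). Rows are sorted by number of
    diseases descending, then gene count descending, then label; each gene
    appears in exactly one row.

    Raises
    ------
    InsufficientCollectionError
        If the collection has fewer than three sets.
    """
    if len(collection.sets) < 3:
        raise InsufficientCollectionError(
            f"need index plus >= 2 comorbid sets, got {len(collection.sets)}"
        )
    membership: dict[str, set[str]] = {}
    for label, genes in collection.sets.items():
        for gene in genes:
            membership.setdefault(gene, set()).add(label)
    by_signature: dict[frozenset[str], set[str]] = {}
    for gene, labels in membership.items():
        if collection.index_disease in labels and len(labels) >= 3:
            by_signature.setdefault(frozenset(labels), set()).add(gene)
    rows = [
        MultimorbiditySignature(diseases=sig, genes=frozenset(genes))
        for sig, genes in by_signature.items()
    ]
    rows.sort(key=_row_sort_key)
    return rows


def pairwise_summary(collection: GeneSetCollection) -> list[tuple[str, int]]:
    """Common-gene count between the index disease and every other disease.

    Sorted by count descending, ties alphabetical.
    """
    idx = collection.index_disease
    out = [
        (label, len(common_genes(collection, idx, label)))
        for label in collection.sets
        if label != idx
    ]
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def write_multimorbidity_tsv(rows: Iterable[MultimorbiditySignature], stream: IO[str]) -> None:
    stream.write("diseases\tn_genes\tgenes\n")
    for row in rows:
        stream.write(
            f"{', '.join(sorted(row.diseases))}\t{row.n_genes}\t{', '.join(sorted(row.genes))}\n"
        )


def write_pairwise_tsv(pairs: Iterable[tuple[str, int]], stream: IO[str]) -> None:
    stream.write("disease\tn_common_genes\n")
    for label, n in pairs:
        stream.write(f"{label}\t{n}\n")
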