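"""Microbe-set libraries: the core knowledge representation.

A *microbe-set* is a named group of microbial taxa sharing an attribute
(a disease association, a co-mentioned mammalian gene, a taxonomic clade).
A *library* is a themed collection of such sets, analogous to a gene-set
library in gene-centric enrichment analysis, and is serialized in the
tab-delimited GMT dialect (term, description, members...).

Name matching throughout the package is case-insensitive; the stored
canonical spelling is the first occurrence seen.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from .errors import EmptyLibraryError, FormatError, InvalidNameError
from .names import normalize_taxon_name

__all__ = [
    "MicrobeSet",
    "MicrobeSetLibrary",
    "canonical_members",
    "parse_disbiome",
    "read_disbiome_json",
    "read_disbiome_tsv",
    "read_gmt",
    "write_gmt",
]

logger = logging.getLogger("msea")

PROVENANCES = ("taxonomy", "literature", "disbiome", "user")


def canonical_members(names: Iterable[str], normalize: bool = True) -> frozenset[str]:
    """Deduplicate member names case-insensitively, keeping the first spelling.

    When ``normalize`` is true each name passes through
    :func:`~msea.names.normalize_taxon_name` first.
    """
    seen: dict[str, str] = {}
    for raw in names:
        name = normalize_taxon_name(raw) if normalize else str(raw).strip()
        if not name:
            continue
        seen.setdefault(name.casefold(), name)
    return frozenset(seen.values())


@dataclass(frozen=True)
class MicrobeSet:
    """A named set of normalized microbe names.

    Attributes
    ----------
    term_id:
        Unique identifier within its library.
    term_label:
        Human-readable description (the GMT description column).
    members:
        Frozen set of canonical member names; never empty.
    """

    term_id: str
    term_label: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise EmptyLibraryError(f"microbe-set {self.term_id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_names(
        cls,
        term_id: str,
        names: Iterable[str],
        term_label: str | None = None,
        normalize: bool = True,
    ) -> "MicrobeSet":
        return cls(term_id, term_label if term_label is not None else term_id,
                   canonical_members(names, normalize=normalize))


@dataclass
class MicrobeSetLibrary:
    """A themed collection of microbe-sets keyed by term identifier."""

    name: str
    sets: dict[str, MicrobeSet] = field(default_factory=dict)
    provenance: str = "user"

    def __post_init__(self):
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        for term_id, ms in self.sets.items():
            if term_id != ms.term_id:
                raise ValueError(f"key {term_id!r} does not match term_id {ms.term_id!r}")

    @property
    def member_union(self) -> frozenset[str]:
        """Union of all member names across the library's sets."""
        out: set[str] = set()
        for ms in self.sets.values():
            out |= ms.members
        return frozenset(out)

    def add(self, microbe_set: MicrobeSet) -> None:
        if microbe_set.term_id in self.sets:
            raise ValueError(f"duplicate term_id {microbe_set.term_id!r}")
        self.sets[microbe_set.term_id] = microbe_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[MicrobeSet]:
        return iter(self.sets.values())

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.sets

    def __getitem__(self, term_id: str) -> MicrobeSet:
        return self.sets[term_id]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MicrobeSetLibrary):
            return NotImplemented
        return self.sets == other.sets


# ---------------------------------------------------------------------------
# Disbiome-style disease curation records
# ---------------------------------------------------------------------------

DIRECTIONS = ("elevated", "reduced")


def parse_disbiome(
    records: Iterable[tuple[str, str, str]],
    name: str = "disbiome",
) -> MicrobeSetLibrary:
    """Build a disease-centric library from (disease, organism, direction) records.

    Every organism reported with differential abundance for a disease joins
    that disease's set, regardless of the direction of change (elevated or
    reduced): the direction carries study-specific context, while set
    membership encodes only that an association was observed. Records with a
    blank organism are skipped with a logged warning.

    Raises
    ------
    EmptyLibraryError
        If no usable record remains.
    """
    grouped: dict[str, list[str]] = {}
    labels: dict[str, str] = {}
    skipped = 0
    for disease, organism, direction in records:
        disease = str(disease).strip()
        if direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {direction!r} (expected one of {DIRECTIONS})")
        if not str(organism).strip():
            skipped += 1
            logger.warning("skipping record for disease %r: blank organism", disease)
            continue
        if not disease:
            skipped += 1
            logger.warning("skipping record for organism %r: blank disease", organism)
            continue
        key = disease.casefold()
        labels.setdefault(key, disease)
        grouped.setdefault(key, []).append(organism)
    if not grouped:
        raise EmptyLibraryError(
            f"no usable disease-organism records ({skipped} skipped)"
        )
    library = MicrobeSetLibrary(name, provenance="disbiome")
    for key in sorted(grouped):
        disease = labels[key]
        library.add(MicrobeSet.from_names(disease, grouped[key], term_label=disease))
    return library


def read_disbiome_json(path: str | Path, name: str | None = None) -> MicrobeSetLibrary:
    """Read a Disbiome-style JSON export.

    Expects a JSON array of objects carrying ``disease_name``,
    ``organism_name`` and ``qualitative_outcome`` fields (``Elevated`` /
    ``Reduced``, case-insensitive); plain ``disease`` / ``organism`` /
    ``direction`` keys are accepted as well.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    records = []
    for rec in data:
        disease = rec.get("disease_name", rec.get("disease", ""))
        organism = rec.get("organism_name", rec.get("organism", ""))
        direction = str(rec.get("qualitative_outcome", rec.get("direction", ""))).strip().lower()
        records.append((disease, organism, direction))
    return parse_disbiome(records, name=name or path.stem)


def read_disbiome_tsv(path: str | Path, name: str | None = None) -> MicrobeSetLibrary:
    """Read disease records from a TSV with headers disease, organism, direction."""
    path = Path(path)
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            cols = {c: header.index(c) for c in ("disease", "organism", "direction")}
        except ValueError as exc:
            raise FormatError(f"missing header column: {exc}", line_number=1) from exc
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                raise FormatError("short record", line_number=lineno)
            records.append(
                (parts[cols["disease"]], parts[cols["organism"]],
                 parts[cols["direction"]].strip().lower())
            )
    return parse_disbiome(records, name=name or path.stem)


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    name: str | None = None,
    provenance: str = "user",
    normalize: bool = True,
) -> MicrobeSetLibrary:
    """Read a set library in GMT format (term, description, members...).

    Duplicate members on one line collapse to one (set semantics). With
    ``normalize`` (the default for microbe libraries) member names pass
    through the taxon-name normalizer; pass ``normalize=False`` for
    gene-set libraries whose symbols must stay verbatim.

    Raises
    ------
    FormatError
        On any line with fewer than three tab-delimited fields.
    """
    path = Path(path)
    library = MicrobeSetLibrary(name or path.stem, provenance=provenance)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"expected at least 3 tab-delimited fields, got {len(parts)}",
                    line_number=lineno,
                )
            term_id, description, *members = parts
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError("set has no members", line_number=lineno)
            try:
                library.add(
                    MicrobeSet.from_names(term_id, members, term_label=description,
                                          normalize=normalize)
                )
            except InvalidNameError as exc:
                raise FormatError(str(exc), line_number=lineno) from exc
    if not library.sets:
        raise EmptyLibraryError(f"{path} contains no sets")
    return library


def write_gmt(library: MicrobeSetLibrary, path: str | Path) -> None:
    """Write a library in GMT format (UTF-8, LF line endings, sorted members)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term_id in sorted(library.sets):
            ms = library.sets[term_id]
            fields = [ms.term_id, ms.term_label, *sorted(ms.members)]
            fh.write("\t".join(fields) + "\n")
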