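"""Core domain types for phylogenomic supermatrix assembly.

The pipeline operates on collections of per-orthogroup amino-acid
alignments over a shared taxon universe.  Each orthogroup holds at most
one sequence per taxon (the orthology-inference convention).  Matrices
may be in the 20-letter amino-acid alphabet or, after Dayhoff recoding,
in a six-state digit alphabet.

Two characters carry "no information" semantics throughout:

* ``-`` — an alignment gap (indel),
* ``?`` — missing data (taxon absent from the locus).

Both count as missing in matrix statistics, but they are never
conflated in the matrices themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

AMINO20 = "amino20"
DAYHOFF6 = "dayhoff6"

GAP = "-"
MISSING = "?"

#: The 20 canonical amino-acid letters, in lexicographic order.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: IUPAC ambiguity / non-standard letters tolerated on input.
AMBIGUOUS_AA = "BZJXUO"

ALPHABETS: dict[str, frozenset[str]] = {
    AMINO20: frozenset(CANONICAL_AA + AMBIGUOUS_AA + GAP + MISSING + "*"),
    DAYHOFF6: frozenset("012345" + GAP + MISSING),
}

#: Characters that carry no phylogenetic information in any alphabet.
NO_DATA = frozenset({GAP, MISSING})


class PhylocatError(Exception):
    """Base class for all pipeline errors."""


class AlignmentError(PhylocatError):
    """Malformed alignment (ragged rows, bad dimensions, ...)."""


class DuplicateTaxonError(AlignmentError):
    """More than one sequence for a taxon within one orthogroup."""


class AlphabetError(AlignmentError):
    """Residue outside the declared alphabet."""


class ScoreTrackError(PhylocatError):
    """Confidence-score track unusable (parse failure, length mismatch)."""


class PartitionError(PhylocatError):
    """Partition scheme violates contiguity/coverage."""


class EmptyMatrixError(PhylocatError):
    """An operation that requires characters received none."""


class UndefinedScoreError(PhylocatError):
    """A per-locus statistic is undefined (fewer than two usable rows)."""


class UsageError(PhylocatError):
    """Invalid argument combination supplied by the caller."""


class TaxonUniverse:
    """The ordered set of taxa a study spans.

    Order is lexicographic by default so that every emitted matrix is
    reproducible; a user-supplied explicit order is preserved when
    ``sort=False``.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[str], *, sort: bool = True) -> None:
        labels = list(labels)
        for lab in labels:
            if not isinstance(lab, str) or not lab or lab != lab.strip():
                raise UsageError(
                    f"taxon label {lab!r} is empty or carries whitespace"
                )
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise UsageError(f"duplicate taxon labels: {dupes}")
        if sort:
            labels = sorted(labels)
        self.labels: tuple[str, ...] = tuple(labels)
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __contains__(self, label: object) -> bool:
        return label in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonUniverse) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxonUniverse({len(self)} taxa)"

    def index(self, label: str) -> int:
        return self._index[label]


@dataclass
class OrthogroupAlignment:
    """One aligned locus: equal-length taxon-labelled residue rows."""

    id: str
    rows: dict[str, str]
    alphabet: str = AMINO20
    length: int | None = None

    def __post_init__(self) -> None:
        if self.alphabet not in ALPHABETS:
            raise UsageError(f"unknown alphabet {self.alphabet!r}")
        if self.length is None:
            self.length = len(next(iter(self.rows.values()), ""))

    @property
    def taxa(self) -> list[str]:
        return sorted(self.rows)

    def is_empty_row(self, taxon: str) -> bool:
        """True if the taxon's row carries only gap/missing characters."""
        row = self.rows[taxon]
        return all(c in NO_DATA for c in row)

    def non_empty_taxa(self) -> list[str]:
        return [t for t in self.taxa if not self.is_empty_row(t)]

    def subset_columns(self, keep: Iterable[int]) -> "OrthogroupAlignment":
        """New alignment containing only the (0-based) columns ``keep``."""
        keep = list(keep)
        rows = {t: "".join(s[j] for j in keep) for t, s in self.rows.items()}
        return OrthogroupAlignment(self.id, rows, self.alphabet, len(keep))

    def subset_taxa(self, taxa: Iterable[str]) -> "OrthogroupAlignment":
        wanted = set(taxa)
        rows = {t: s for t, s in self.rows.items() if t in wanted}
        return OrthogroupAlignment(self.id, rows, self.alphabet, self.length)


@dataclass
class ScoreTrack:
    """Per-column confidence scores for one alignment (ZORRO-style)."""

    og_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        self.scores = tuple(float(s) for s in self.scores)
        bad = [s for s in self.scores if s < 0]
        if bad:
            raise ScoreTrackError(
                f"score track {self.og_id!r}: negative scores {bad[:3]}"
            )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class OrthogroupSet:
    """A collection of orthogroup alignments over one taxon universe.

    Loci are kept sorted lexicographically by orthogroup id so that
    concatenation order — which the upstream tools leave unspecified —
    is deterministic.
    """

    universe: TaxonUniverse
    loci: list[OrthogroupAlignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda og: og.id)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[OrthogroupAlignment]:
        return iter(self.loci)

    def locus_ids(self) -> list[str]:
        return [og.id for og in self.loci]

    def replace_loci(self, loci: Iterable[OrthogroupAlignment]) -> "OrthogroupSet":
        return OrthogroupSet(self.universe, list(loci))


@dataclass
class PartitionScheme:
    """Per-locus coordinate ranges of a concatenated matrix.

    Coordinates are 1-based inclusive (the RAxML/NEXUS convention) and
    must tile ``1..L`` contiguously in entry order.
    """

    entries: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        expect = 1
        for lid, start, end in self.entries:
            if start != expect:
                raise PartitionError(
                    f"partition {lid!r} starts at {start}, expected {expect}"
                )
            if end < start:
                raise PartitionError(f"partition {lid!r}: end {end} < start {start}")
            expect = end + 1

    @classmethod
    def from_lengths(cls, lengths: Iterable[tuple[str, int]]) -> "PartitionScheme":
        entries, pos = [], 1
        for lid, n in lengths:
            entries.append((lid, pos, pos + n - 1))
            pos += n
        return cls(entries)

    @property
    def total_length(self) -> int:
        return self.entries[-1][2] if self.entries else 0

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SuperMatrix:
    """Concatenated character matrix plus its partition scheme."""

    universe: TaxonUniverse
    rows: dict[str, str]
    scheme: PartitionScheme
    alphabet: str = AMINO20

    def __post_init__(self) -> None:
        L = self.scheme.total_length
        if set(self.rows) != set(self.universe.labels):
            raise AlignmentError("supermatrix rows do not match taxon universe")
        for t, row in self.rows.items():
            if len(row) != L:
                raise AlignmentError(
                    f"row {t!r} has length {len(row)}, partition total is {L}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.universe)

    @property
    def length(self) -> int:
        return self.scheme.total_length


@dataclass
class OccupancyReport:
    """Descriptive statistics of a supermatrix and its source loci.

    ``percent_missing`` counts both ``?`` (absent taxon) and ``-``
    (alignment gap) cells; ``percent_missing_absent_only`` counts only
    ``?`` cells.  Both are reported because "% missing data" figures in
    the literature rarely say which convention they use.
    """

    per_locus: dict[str, int]
    per_taxon: dict[str, int]
    n_taxa: int
    n_loci: int
    total_cells: int
    missing_cells: int
    absent_cells: int

    @property
    def percent_missing(self) -> float:
        return 100.0 * self.missing_cells / self.total_cells if self.total_cells else 0.0

    @property
    def percent_missing_absent_only(self) -> float:
        return 100.0 * self.absent_cells / self.total_cells if self.total_cells else 0.0


def validate_alignment(og: OrthogroupAlignment) -> list[str]:
    """Invariant violations for one alignment; empty list iff well-formed."""
    violations: list[str] = []
    allowed = ALPHABETS[og.alphabet]
    for taxon, row in sorted(og.rows.items()):
        if len(row) != og.length:
            violations.append(
                f"locus {og.id!r}: row {taxon!r} has length {len(row)}, "
                f"expected {og.length}"
            )
        bad = sorted({c for c in row if c not in allowed})
        if bad:
            violations.append(
                f"locus {og.id!r}: row {taxon!r} contains characters {bad} "
                f"outside alphabet {og.alphabet!r}"
            )
    return violations


def validate(og_set: OrthogroupSet) -> list[str]:
    """All invariant violations of a set; empty list iff valid.

    This is a reporting operation: it never raises, so that a caller
    can collect every problem in a dataset in one pass.
    """
    violations: list[str] = []
    seen: set[str] = set()
    for og in og_set.loci:
        if og.id in seen:
            violations.append(f"duplicate locus id {og.id!r}")
        seen.add(og.id)
        for taxon in sorted(og.rows):
            if taxon not in og_set.universe:
                violations.append(
                    f"locus {og.id!r}: taxon {taxon!r} not in universe"
                )
        violations.extend(validate_alignment(og))
    return violations
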