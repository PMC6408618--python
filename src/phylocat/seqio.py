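"""Readers and writers for the formats the pipeline touches.

FASTA alignments are read through Biopython.  The remaining formats are
simple line formats with no established Python reader: ZORRO confidence
tracks (one real number per line, one line per alignment column),
relaxed PHYLIP (long labels, single-space separator), RAxML-style and
NEXUS partition files, and a TSV occupancy report.

All write/read pairs round-trip losslessly on valid input.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .core import (
    ALPHABETS,
    AMINO20,
    AlphabetError,
    AlignmentError,
    DuplicateTaxonError,
    OccupancyReport,
    OrthogroupAlignment,
    PartitionError,
    PartitionScheme,
    ScoreTrack,
    ScoreTrackError,
    SuperMatrix,
    TaxonUniverse,
    UsageError,
)

log = logging.getLogger(__name__)

FASTA_WIDTH = 80


def read_fasta_alignment(path: str | Path, alphabet: str = AMINO20) -> OrthogroupAlignment:
    """Read one aligned FASTA file into an :class:`OrthogroupAlignment`.

    The orthogroup id is the file stem.  Sequences are upper-cased and
    ``.`` gaps normalised to ``-``.  Ragged lengths, duplicate headers
    and residues outside *alphabet* are hard errors.
    """
    path = Path(path)
    allowed = ALPHABETS[alphabet]
    rows: dict[str, str] = {}
    length: int | None = None
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise DuplicateTaxonError(
                f"{path.name}: duplicate header {rec.id!r}"
            )
        seq = str(rec.seq).upper().replace(".", "-")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"{path.name}: record {rec.id!r} has length {len(seq)}, "
                f"previous records have {length}"
            )
        for pos, c in enumerate(seq, start=1):
            if c not in allowed:
                raise AlphabetError(
                    f"{path.name}: record {rec.id!r} position {pos}: "
                    f"character {c!r} not in alphabet {alphabet!r}"
                )
        rows[rec.id] = seq
    return OrthogroupAlignment(path.stem, rows, alphabet, length or 0)


def write_fasta_alignment(og: OrthogroupAlignment, path: str | Path, width: int = FASTA_WIDTH) -> None:
    """Write an alignment as wrapped FASTA, taxa in sorted order."""
    path = Path(path)
    with path.open("w") as fh:
        for taxon in og.taxa:
            fh.write(f">{taxon}\n")
            seq = og.rows[taxon]
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")


def read_alignment_dir(
    directory: str | Path,
    alphabet: str = AMINO20,
    pattern: str = "*.fasta",
) -> list[OrthogroupAlignment]:
    """Read every FASTA alignment in a directory, sorted by file name."""
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise UsageError(f"no {pattern} files under {directory}")
    return [read_fasta_alignment(p, alphabet) for p in files]


def write_phylip(sm: SuperMatrix, path: str | Path) -> None:
    """Write a supermatrix as relaxed PHYLIP.

    Relaxed means full-length labels separated from the sequence by a
    single space; the strict 10-character label convention truncates
    modern sample names into collisions and is deliberately not
    emitted.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{sm.n_taxa} {sm.length}\n")
        for taxon in sm.universe:
            fh.write(f"{taxon} {sm.rows[taxon]}\n")


def read_phylip(path: str | Path) -> tuple[int, int, dict[str, str]]:
    """Read a relaxed PHYLIP file back into (ntax, nchar, rows)."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise AlignmentError(f"{path.name}: malformed PHYLIP header")
        ntax, nchar = int(header[0]), int(header[1])
        rows: dict[str, str] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            label, seq = line.split(" ", 1)
            rows[label] = seq
    if len(rows) != ntax or any(len(s) != nchar for s in rows.values()):
        raise AlignmentError(f"{path.name}: body does not match header")
    return ntax, nchar, rows


def read_score_track(path: str | Path) -> ScoreTrack:
    """Read a ZORRO-format score track: one real number per line.

    Trailing blank lines are ignored; a non-numeric line is a parse
    error reported with its line number.
    """
    path = Path(path)
    scores: list[float] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                scores.append(float(text))
            except ValueError:
                raise ScoreTrackError(
                    f"{path.name}: line {lineno}: {text!r} is not a number"
                ) from None
    return ScoreTrack(path.stem, tuple(scores))


def write_score_track(track: ScoreTrack, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for s in track.scores:
            fh.write(f"{s:.6g}\n")


def write_partitions(
    scheme: PartitionScheme,
    path: str | Path,
    dialect: str = "raxml",
    model: str = "LG4X",
) -> None:
    """Write a partition file in RAxML or NEXUS charset dialect.

    Coordinates are 1-based inclusive.  *model* is the per-partition
    model token of the RAxML dialect only.
    """
    path = Path(path)
    if dialect not in ("raxml", "nexus"):
        raise UsageError(f"unknown partition dialect {dialect!r}")
    if not scheme.entries:
        log.warning("writing empty partition file %s", path)
    with path.open("w") as fh:
        if dialect == "raxml":
            for lid, start, end in scheme.entries:
                fh.write(f"{model}, {lid} = {start}-{end}\n")
        else:
            fh.write("#nexus\nbegin sets;\n")
            for lid, start, end in scheme.entries:
                fh.write(f"  charset {lid} = {start}-{end};\n")
            fh.write("end;\n")


_RAXML_RE = re.compile(r"^\s*\S+\s*,\s*(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*$")
_NEXUS_RE = re.compile(r"^\s*charset\s+(\S+)\s*=\s*(\d+)\s*-\s*(\d+)\s*;\s*$", re.I)


def read_partitions(path: str | Path) -> PartitionScheme:
    """Parse a partition file written by :func:`write_partitions`."""
    path = Path(path)
    entries: list[tuple[str, int, int]] = []
    lines = path.read_text().splitlines()
    nexus = bool(lines) and lines[0].strip().lower() == "#nexus"
    rx = _NEXUS_RE if nexus else _RAXML_RE
    for line in lines:
        m = rx.match(line)
        if m:
            entries.append((m.group(1), int(m.group(2)), int(m.group(3))))
    if not entries and any(l.strip() for l in lines):
        raise PartitionError(f"{path.name}: no partition entries recognised")
    return PartitionScheme(entries)


def write_occupancy_table(report: OccupancyReport, path: str | Path) -> None:
    """Write the occupancy/missingness report as a sectioned TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("[summary]\n")
        fh.write(f"n_taxa\t{report.n_taxa}\n")
        fh.write(f"n_loci\t{report.n_loci}\n")
        fh.write(f"total_cells\t{report.total_cells}\n")
        fh.write(f"missing_cells\t{report.missing_cells}\n")
        fh.write(f"absent_taxon_cells\t{report.absent_cells}\n")
        fh.write(f"percent_missing\t{report.percent_missing:.4f}\n")
        fh.write(
            f"percent_missing_absent_only\t{report.percent_missing_absent_only:.4f}\n"
        )
        fh.write("[taxa]\ntaxon\tn_loci\tfraction\n")
        for taxon in sorted(report.per_taxon):
            n = report.per_taxon[taxon]
            frac = n / report.n_loci if report.n_loci else 0.0
            fh.write(f"{taxon}\t{n}\t{frac:.4f}\n")
        fh.write("[loci]\nlocus\toccupancy\tfraction\n")
        for lid in sorted(report.per_locus):
            n = report.per_locus[lid]
            frac = n / report.n_taxa if report.n_taxa else 0.0
            fh.write(f"{lid}\t{n}\t{frac:.4f}\n")


def read_taxon_list(path: str | Path, *, sort: bool = True) -> TaxonUniverse:
    """Read a taxon universe from a plain list, one label per line."""
    labels = [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]
    return TaxonUniverse(labels, sort=sort)


def write_taxon_list(universe: TaxonUniverse | Iterable[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for label in universe:
            fh.write(label + "\n")
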