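"""Concatenation of orthogroups into a partitioned supermatrix.

Selected orthogroup alignments are joined column-wise in locus order.
Every taxon of the universe receives a row; where a taxon is absent
from a locus its block is filled with ``?`` (missing data), never
``-`` (which is reserved for alignment gaps).  A partition scheme
recording the 1-based inclusive column range of each locus is built
alongside, for per-locus models in downstream inference.
"""

from __future__ import annotations

from .core import (
    EmptyMatrixError,
    GAP,
    MISSING,
    OccupancyReport,
    OrthogroupSet,
    PartitionScheme,
    PhylocatError,
    SuperMatrix,
)
from .filters import occupancy


def concatenate(s: OrthogroupSet) -> SuperMatrix:
    """Concatenate every locus of *s* into one partitioned supermatrix."""
    if not s.loci:
        raise EmptyMatrixError("cannot concatenate an empty orthogroup set")
    alphabet = s.loci[0].alphabet
    scheme = PartitionScheme.from_lengths((og.id, og.length) for og in s)
    rows = {
        taxon: "".join(
            og.rows.get(taxon, MISSING * og.length) for og in s
        )
        for taxon in s.universe
    }
    return SuperMatrix(s.universe, rows, scheme, alphabet)


def missingness(sm: SuperMatrix, include_gaps: bool = True) -> float:
    """Percent of matrix cells carrying no character information.

    With *include_gaps* both ``?`` and ``-`` count (the whole-matrix
    cell fraction usually quoted as "% missing data"); without, only
    absent-taxon ``?`` cells count.
    """
    total = sm.n_taxa * sm.length
    if total == 0:
        raise EmptyMatrixError("missingness undefined for a 0-cell matrix")
    missing = sum(row.count(MISSING) for row in sm.rows.values())
    if include_gaps:
        missing += sum(row.count(GAP) for row in sm.rows.values())
    return 100.0 * missing / total


def occupancy_report(s: OrthogroupSet, sm: SuperMatrix) -> OccupancyReport:
    """Descriptive statistics of a supermatrix built from *s*.

    Per-locus occupancy, per-taxon locus counts, and overall missing
    percentages, all recomputed from the inputs and cross-checked for
    consistency (the matrix must actually derive from the set).
    """
    if sm.universe != s.universe or [e[0] for e in sm.scheme.entries] != s.locus_ids():
        raise PhylocatError("supermatrix was not built from this orthogroup set")
    per_locus = {og.id: occupancy(og) for og in s}
    per_taxon = {
        taxon: sum(
            1
            for og in s
            if taxon in og.rows and not og.is_empty_row(taxon)
        )
        for taxon in s.universe
    }
    total = sm.n_taxa * sm.length
    absent = sum(row.count(MISSING) for row in sm.rows.values())
    missing = absent + sum(row.count(GAP) for row in sm.rows.values())
    return OccupancyReport(
        per_locus=per_locus,
        per_taxon=per_taxon,
        n_taxa=sm.n_taxa,
        n_loci=len(s),
        total_cells=total,
        missing_cells=missing,
        absent_cells=absent,
    )
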