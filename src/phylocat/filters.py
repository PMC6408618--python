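"""Orthogroup filtering: site masking, occupancy selection, rate trimming.

Three filters are applied between orthology inference and
concatenation:

1. **Site masking** — columns whose alignment-confidence score (ZORRO
   scale, 0–10) falls below a threshold (default 5) are discarded.
2. **Occupancy selection** — orthogroups present in fewer than a
   minimum number of taxa are discarded.  The threshold may be given
   directly or derived from a fraction of the taxon universe.
3. **Rate-tail trimming** — orthogroups are ranked by a conservation
   proxy (mean percent pairwise identity across their sequences);
   the most conserved (slowest-evolving) and least conserved
   (fastest-evolving) tails are discarded to reduce rate-driven
   systematic error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np

from .core import (
    GAP,
    MISSING,
    OrthogroupAlignment,
    OrthogroupSet,
    ScoreTrack,
    ScoreTrackError,
    UndefinedScoreError,
    UsageError,
)

log = logging.getLogger(__name__)

DEFAULT_SCORE_THRESHOLD = 5.0

EXCLUDE_GAPS = "exclude_pairs_with_gap"
GAPS_MISMATCH = "count_as_mismatch"
GAP_POLICIES = (EXCLUDE_GAPS, GAPS_MISMATCH)

ROUNDINGS = ("ceil", "floor_plus_one", "explicit")


def mask_sites(
    og: OrthogroupAlignment,
    track: ScoreTrack,
    threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> OrthogroupAlignment:
    """Keep exactly the columns whose confidence score is >= *threshold*.

    Column order and the row set are unchanged.  The score track must
    have one score per alignment column; a mismatch is a hard error
    rather than a truncation, because silently shifted scores corrupt
    the masking.
    """
    if len(track.scores) != og.length:
        raise ScoreTrackError(
            f"locus {og.id!r}: {len(track.scores)} scores for "
            f"{og.length} columns"
        )
    keep = [j for j, s in enumerate(track.scores) if s >= threshold]
    if not keep and og.length:
        log.warning("locus %s: all %d columns masked out", og.id, og.length)
    return og.subset_columns(keep)


def occupancy(og: OrthogroupAlignment) -> int:
    """Number of taxa with at least one informative residue in the locus.

    Rows consisting entirely of gaps/missing characters do not count.
    """
    return len(og.non_empty_taxa())


def select_by_occupancy(s: OrthogroupSet, min_taxa: int) -> OrthogroupSet:
    """Retain loci with occupancy >= *min_taxa*; universe unchanged."""
    if min_taxa < 0:
        raise UsageError("min_taxa must be >= 0")
    return s.replace_loci(og for og in s if occupancy(og) >= min_taxa)


def min_taxa_for_fraction(
    n_taxa: int,
    fraction: float,
    rounding: str = "ceil",
    explicit_count: int | None = None,
) -> int:
    """Occupancy count threshold implied by a fraction of the universe.

    Published matrices state thresholds both ways ("50% occupancy",
    "55 or more taxa") and the printed pairs follow no single rounding
    rule, so the rule is explicit here:

    * ``ceil`` — smallest count whose fraction is >= the target.
    * ``floor_plus_one`` — strictly more than the target fraction.
    * ``explicit`` — pass ``explicit_count`` through unchanged and log
      the fraction it implies (the recommended mode for replicating a
      published matrix).
    """
    if not 0 < fraction <= 1:
        raise UsageError(f"fraction {fraction} outside (0, 1]")
    if rounding not in ROUNDINGS:
        raise UsageError(f"unknown rounding policy {rounding!r}")
    if rounding == "explicit":
        if explicit_count is None:
            raise UsageError("rounding='explicit' requires explicit_count")
        log.info(
            "explicit occupancy threshold %d of %d taxa (%.1f%%)",
            explicit_count, n_taxa, 100 * explicit_count / n_taxa,
        )
        return explicit_count
    if rounding == "ceil":
        return math.ceil(n_taxa * fraction)
    return math.floor(n_taxa * fraction) + 1


def pairwise_identity(
    a: str,
    b: str,
    gap_policy: str = EXCLUDE_GAPS,
) -> float | None:
    """Fraction of identical residues between two aligned sequences.

    Positions where both sequences are gap/missing never contribute.
    Under ``exclude_pairs_with_gap`` a position contributes only when
    both sequences carry a residue; under ``count_as_mismatch`` a
    residue aligned to a gap counts as a comparable mismatch.

    Returns ``None`` when no position is comparable.
    """
    if len(a) != len(b):
        raise UsageError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if gap_policy not in GAP_POLICIES:
        raise UsageError(f"unknown gap policy {gap_policy!r}")
    aa = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bb = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    nodata_a = (aa == ord(GAP)) | (aa == ord(MISSING))
    nodata_b = (bb == ord(GAP)) | (bb == ord(MISSING))
    if gap_policy == EXCLUDE_GAPS:
        comparable = ~nodata_a & ~nodata_b
    else:
        comparable = ~(nodata_a & nodata_b)
    n = int(comparable.sum())
    if n == 0:
        return None
    matches = int(((aa == bb) & ~nodata_a & ~nodata_b).sum())
    return matches / n


def locus_conservation(
    og: OrthogroupAlignment,
    gap_policy: str = EXCLUDE_GAPS,
    statistic: str = "mean",
) -> float:
    """Accumulated-conservation proxy for a locus's evolutionary rate.

    The mean of :func:`pairwise_identity` over all unordered pairs of
    non-empty rows, in ``[0, 1]``; 1 means perfectly conserved
    (slowest-evolving).  ``statistic="sum"`` returns the raw
    accumulated sum over pairs instead of the mean.

    Raises :class:`UndefinedScoreError` when fewer than two rows carry
    residues, or no pair shares a comparable position.
    """
    if statistic not in ("mean", "sum"):
        raise UsageError(f"unknown statistic {statistic!r}")
    taxa = og.non_empty_taxa()
    if len(taxa) < 2:
        raise UndefinedScoreError(
            f"locus {og.id!r}: conservation undefined with "
            f"{len(taxa)} non-empty rows"
        )
    values = [
        pid
        for t1, t2 in combinations(taxa, 2)
        if (pid := pairwise_identity(og.rows[t1], og.rows[t2], gap_policy))
        is not None
    ]
    if not values:
        raise UndefinedScoreError(
            f"locus {og.id!r}: no comparable residue pairs"
        )
    total = float(sum(values))
    return total if statistic == "sum" else total / len(values)


@dataclass
class RateTable:
    """Per-locus conservation scores and the slow-to-fast ranking.

    ``ranking`` lists locus ids from most conserved (slowest-evolving)
    to least conserved (fastest-evolving); ties are broken by locus id
    so the order is deterministic.  ``excluded`` lists loci whose
    conservation is undefined (< 2 usable rows).
    """

    scores: dict[str, float]
    ranking: list[str]
    excluded: list[str]

    @classmethod
    def from_set(cls, s: OrthogroupSet, gap_policy: str = EXCLUDE_GAPS) -> "RateTable":
        scores: dict[str, float] = {}
        excluded: list[str] = []
        for og in s:
            try:
                scores[og.id] = locus_conservation(og, gap_policy)
            except UndefinedScoreError:
                excluded.append(og.id)
        if excluded:
            log.warning(
                "%d loci excluded from rate ranking (undefined conservation): %s",
                len(excluded), ", ".join(excluded[:5]),
            )
        ranking = sorted(scores, key=lambda lid: (-scores[lid], lid))
        return cls(scores, ranking, excluded)


def trim_rate_tails(
    s: OrthogroupSet,
    q_low: float = 0.2,
    q_high: float = 0.2,
    gap_policy: str = EXCLUDE_GAPS,
) -> OrthogroupSet:
    """Discard the slowest and fastest evolutionary-rate tails.

    Loci are ranked by :func:`locus_conservation`; ``floor(q_low * N)``
    loci are discarded from the low-rate end (most conserved, slowest)
    and ``floor(q_high * N)`` from the high-rate end (least conserved,
    fastest), where ``N`` counts the rankable loci.  Loci with
    undefined conservation are dropped with a warning.  The retained
    middle keeps the set's original (lexicographic) order.
    """
    if q_low < 0 or q_high < 0 or q_low + q_high >= 1:
        raise UsageError("require 0 <= q_low + q_high < 1")
    table = RateTable.from_set(s, gap_policy)
    n = len(table.ranking)
    n_slow = math.floor(q_low * n)
    n_fast = math.floor(q_high * n)
    kept = set(table.ranking[n_slow : n - n_fast])
    return s.replace_loci(og for og in s if og.id in kept)
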