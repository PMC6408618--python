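"""Dayhoff six-state recoding of amino-acid matrices.

Collapsing the 20 amino acids into the six Dayhoff exchange classes
(AGPST / FWY / C / HKR / ILMV / EDNQ) reduces compositional
heterogeneity and saturation effects in deep phylogenetic inference.
Recoded matrices use the digit characters ``0``–``5`` so they are
directly consumable by multi-state inference programs.

Gaps pass through unchanged.  Ambiguity letters (B, Z, J, X, U, O) and
stops become ``?`` by default; an optional strict mode resolves an
ambiguity to a class when every expansion falls in the same class
(e.g. B = D/N, both in class 5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    AMINO20,
    ALPHABETS,
    CANONICAL_AA,
    DAYHOFF6,
    GAP,
    MISSING,
    AlphabetError,
    OrthogroupAlignment,
    UsageError,
)

#: Expansions of resolvable IUPAC ambiguity letters.
AMBIGUITY_EXPANSIONS = {"B": "DN", "Z": "EQ", "J": "IL"}


@dataclass(frozen=True)
class RecodingScheme:
    """A named partition of the 20 amino acids into state classes."""

    name: str
    classes: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        covered: set[str] = set()
        for symbol, members in self.classes.items():
            overlap = covered & members
            if overlap:
                raise UsageError(
                    f"scheme {self.name!r}: classes overlap on {sorted(overlap)}"
                )
            covered |= members

    def class_of(self, residue: str) -> str | None:
        for symbol, members in self.classes.items():
            if residue in members:
                return symbol
        return None


DAYHOFF6_SCHEME = RecodingScheme(
    "dayhoff6",
    {
        "0": frozenset("AGPST"),
        "1": frozenset("FWY"),
        "2": frozenset("C"),
        "3": frozenset("HKR"),
        "4": frozenset("ILMV"),
        "5": frozenset("EDNQ"),
    },
)


def recode_residue(
    r: str,
    scheme: RecodingScheme = DAYHOFF6_SCHEME,
    resolve_ambiguities: bool = False,
) -> str:
    """Recode a single amino-acid symbol into its class symbol.

    Canonical letters map to their class; ``-`` passes through;
    everything else legal in the amino-acid alphabet (ambiguity
    letters, ``?``, ``*``) maps to ``?`` unless *resolve_ambiguities*
    is set and every expansion of the letter falls in one class.
    """
    if r not in ALPHABETS[AMINO20]:
        raise AlphabetError(f"character {r!r} not in alphabet {AMINO20!r}")
    if r == GAP:
        return GAP
    symbol = scheme.class_of(r)
    if symbol is not None:
        return symbol
    if resolve_ambiguities and r in AMBIGUITY_EXPANSIONS:
        symbols = {scheme.class_of(x) for x in AMBIGUITY_EXPANSIONS[r]}
        if len(symbols) == 1 and None not in symbols:
            return symbols.pop()
    return MISSING


def _translation_table(scheme: RecodingScheme, resolve_ambiguities: bool) -> dict[int, str]:
    return {
        ord(c): recode_residue(c, scheme, resolve_ambiguities)
        for c in sorted(ALPHABETS[AMINO20])
    }


def recode_alignment(
    og: OrthogroupAlignment,
    scheme: RecodingScheme = DAYHOFF6_SCHEME,
    resolve_ambiguities: bool = False,
) -> OrthogroupAlignment:
    """Recode a whole alignment; dimensions, taxa and gaps preserved."""
    if og.alphabet != AMINO20:
        raise UsageError(
            f"locus {og.id!r}: can only recode {AMINO20!r} alignments, "
            f"got {og.alphabet!r}"
        )
    table = _translation_table(scheme, resolve_ambiguities)
    rows: dict[str, str] = {}
    for taxon, seq in og.rows.items():
        bad = sorted(set(seq) - set(ALPHABETS[AMINO20]))
        if bad:
            raise AlphabetError(
                f"locus {og.id!r}, taxon {taxon!r}: illegal characters {bad}"
            )
        rows[taxon] = seq.translate(table)
    return OrthogroupAlignment(og.id, rows, DAYHOFF6, og.length)
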