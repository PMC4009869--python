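"""Simple indel coding: score alignment gaps as binary characters.

Each distinct gap span — a maximal run of ``-`` with a particular (start,
end) — observed in any taxon becomes one presence/absence character:

* ``1``  the taxon has exactly that span;
* ``?``  the taxon has no nucleotide anywhere in the span's columns for
  another reason: a strictly longer gap enclosing the span, a terminal
  region treated as missing data, or explicit ``?`` cells.  A taxon whose
  longer deletion covers a shorter one carries no evidence about whether
  the shorter event also happened on its lineage;
* ``0``  otherwise (the taxon has sequence in at least one of the columns).

Terminal runs of ``-`` usually reflect incomplete sequencing rather than
deletion, so by default (``terminal_policy="missing"``) they are not coded
as characters and render the affected cells missing; ``terminal_policy=
"code"`` scores them like internal gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .io_formats import NUCLEOTIDE_PRESENT, Alignment

MISSING_STATE = np.int8(-1)


class CodingError(ValueError):
    pass


@dataclass(frozen=True)
class GapSpan:
    """A maximal gap run in one row; 0-based half-open columns."""

    taxon: Optional[str]
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CodingError(f"invalid span [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


class CharacterDescriptor(NamedTuple):
    locus: Optional[str]
    start: int
    end: int
    length: int


class GapCharacterMatrix:
    """Taxa x binary gap characters; cell states 0/1/missing(-1)."""

    def __init__(self, taxa: list[str], characters: list[CharacterDescriptor], states: np.ndarray):
        states = np.asarray(states, dtype=np.int8)
        if states.shape != (len(taxa), len(characters)):
            raise CodingError(
                f"states shape {states.shape} != ({len(taxa)}, {len(characters)})"
            )
        if len(set(taxa)) != len(taxa):
            raise CodingError("duplicate taxon labels")
        if not np.isin(states, [-1, 0, 1]).all():
            raise CodingError("states must be 0, 1 or -1 (missing)")
        self.taxa = list(taxa)
        self.characters = list(characters)
        self.states = states

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.characters], dtype=int)

    def subset(self, indices) -> "GapCharacterMatrix":
        indices = np.asarray(indices, dtype=int)
        return GapCharacterMatrix(
            list(self.taxa),
            [self.characters[i] for i in indices],
            self.states[:, indices],
        )

    def validate_coding(self) -> None:
        """Check the coding invariants (each character gapped in >=1 taxon,
        no duplicate descriptors)."""
        if self.n_characters and not ((self.states == 1).sum(axis=0) >= 1).all():
            raise CodingError("character with no taxon in state 1")
        keys = [(c.locus, c.start, c.end) for c in self.characters]
        if len(set(keys)) != len(keys):
            raise CodingError("duplicate (locus, start, end) characters")

    def character_table(self) -> pd.DataFrame:
        ones = (self.states == 1).sum(axis=0)
        zeros = (self.states == 0).sum(axis=0)
        miss = (self.states == MISSING_STATE).sum(axis=0)
        info = _informative_mask(self.states)
        return pd.DataFrame(
            {
                "locus": [c.locus for c in self.characters],
                "start": [c.start for c in self.characters],
                "end": [c.end for c in self.characters],
                "length": [c.length for c in self.characters],
                "n1": ones,
                "n0": zeros,
                "nmissing": miss,
                "informative": info,
            }
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GapCharacterMatrix)
            and self.taxa == other.taxa
            and self.characters == other.characters
            and np.array_equal(self.states, other.states)
        )


def find_gap_spans(
    row: str, terminal_policy: str = "missing", taxon: Optional[str] = None
) -> tuple[list[GapSpan], list[tuple[int, int]]]:
    """Locate maximal ``-`` runs in one aligned row.

    Returns ``(coded_spans, terminal_regions)``.  Under
    ``terminal_policy="missing"`` the leading/trailing stretches of ``-``
    and ``?`` (when they contain a gap symbol) are reported as terminal
    regions instead of coded spans.
    """
    if terminal_policy not in ("code", "missing"):
        raise CodingError(f"unknown terminal_policy {terminal_policy!r}")
    n = len(row)
    terminal: list[tuple[int, int]] = []
    lo, hi = 0, n
    if terminal_policy == "missing":
        while lo < n and row[lo] in "-?":
            lo += 1
        while hi > lo and row[hi - 1] in "-?":
            hi -= 1
        if lo > 0 and "-" in row[:lo]:
            terminal.append((0, lo))
        if hi < n and "-" in row[hi:]:
            terminal.append((hi, n))
    spans: list[GapSpan] = []
    i = lo
    while i < hi:
        if row[i] == "-":
            j = i
            while j < hi and row[j] == "-":
                j += 1
            spans.append(GapSpan(taxon, i, j))
            i = j
        else:
            i += 1
    return spans, terminal


def simple_indel_coding(
    alignment: Alignment, terminal_policy: str = "missing"
) -> GapCharacterMatrix:
    """Code every distinct gap span as one binary character.

    State 1 = the taxon shows exactly that span; missing = the taxon has no
    nucleotide in the span's columns for any other reason (enclosing gap,
    terminal region, explicit ``?``); 0 = otherwise.
    """
    span_sets: dict[str, set[tuple[int, int]]] = {}
    observed: set[tuple[int, int]] = set()
    for taxon, seq in zip(alignment.taxa, alignment.sequences):
        spans, _ = find_gap_spans(seq, terminal_policy, taxon)
        keys = {(s.start, s.end) for s in spans}
        span_sets[taxon] = keys
        observed |= keys

    descriptors = sorted(
        (
            CharacterDescriptor(
                alignment.locus_of_column(start), start, end, end - start
            )
            for start, end in observed
        ),
        key=lambda c: (c.locus or "", c.start, c.end),
    )

    states = np.zeros((alignment.n_taxa, len(descriptors)), dtype=np.int8)
    for i, (taxon, seq) in enumerate(zip(alignment.taxa, alignment.sequences)):
        mine = span_sets[taxon]
        for j, char in enumerate(descriptors):
            if (char.start, char.end) in mine:
                states[i, j] = 1
            elif not any(
                c in NUCLEOTIDE_PRESENT for c in seq[char.start : char.end]
            ):
                states[i, j] = MISSING_STATE
    matrix = GapCharacterMatrix(list(alignment.taxa), descriptors, states)
    matrix.validate_coding()
    return matrix


def filter_by_indel_length(
    matrix: GapCharacterMatrix, min_length: int = 1
) -> GapCharacterMatrix:
    """Keep only characters whose gap spans >= ``min_length`` alignment
    columns; ``min_length=1`` is the identity."""
    if min_length < 1:
        raise CodingError("min_length must be >= 1")
    keep = np.nonzero(matrix.lengths >= min_length)[0]
    return matrix.subset(keep)


def _informative_mask(states: np.ndarray) -> np.ndarray:
    ones = (states == 1).sum(axis=0)
    zeros = (states == 0).sum(axis=0)
    return (ones >= 2) & (zeros >= 2)


def informative_counts(matrix: GapCharacterMatrix) -> dict[str, int]:
    """Character tallies: total, variable (both states present) and
    parsimony-informative (both states in >= 2 taxa each)."""
    ones = (matrix.states == 1).sum(axis=0)
    zeros = (matrix.states == 0).sum(axis=0)
    variable = (ones >= 1) & (zeros >= 1)
    informative = (ones >= 2) & (zeros >= 2)
    return {
        "total": int(matrix.n_characters),
        "variable": int(variable.sum()),
        "parsimony_informative": int(informative.sum()),
    }


def informative_indices(matrix: GapCharacterMatrix) -> np.ndarray:
    return np.nonzero(_informative_mask(matrix.states))[0]
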