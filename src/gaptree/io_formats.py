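"""Alignment, character-matrix and tree I/O in standard formats.

Conventions used throughout the package:

* columns are 0-based and intervals half-open ``[start, end)``;
* ``-`` is a gap (absence of sequence), ``?`` is missing data;
* ``N`` and IUPAC ambiguity codes count as *nucleotide present* for gap
  scoring — ambiguity is uncertainty about a residue that exists, a gap is
  the absence of one;
* partition files use 1-based inclusive ranges (``locus = 12-340``), the
  common convention of phylogenetics configuration files, and are converted
  on read.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import dendropy
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .trees import Tree, parse_newick  # noqa: F401  (re-exported)

if TYPE_CHECKING:  # pragma: no cover
    from .gap_coding import GapCharacterMatrix

logger = logging.getLogger(__name__)

NUCLEOTIDE_PRESENT = set("ACGTUNRYSWKMBDHV")
GAP = "-"
MISSING = "?"


class FormatError(ValueError):
    """Input does not parse in the named dialect."""


class AlignmentShapeError(FormatError):
    """Rows of an alignment differ in length."""


@dataclass
class Alignment:
    """Taxa-by-columns matrix of nucleotide symbols, gap and missing.

    ``partition_map`` maps locus name -> half-open column interval.
    """

    taxa: list[str]
    sequences: list[str]
    partition_map: Optional[dict[str, tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise AlignmentShapeError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise FormatError("duplicate taxon labels")
        if any(not t for t in self.taxa):
            raise FormatError("empty taxon label")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"ragged alignment rows: lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]
        if self.partition_map:
            self._check_partitions()

    def _check_partitions(self) -> None:
        n = self.n_columns
        seen: list[tuple[int, int]] = []
        for name, (start, end) in self.partition_map.items():
            if not (0 <= start < end <= n):
                raise FormatError(f"partition {name!r} interval [{start},{end}) outside alignment")
            for s, e in seen:
                if start < e and s < end:
                    raise FormatError(f"partition {name!r} overlaps another interval")
            seen.append((start, end))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def locus_of_column(self, col: int) -> Optional[str]:
        if not self.partition_map:
            return None
        for name, (s, e) in self.partition_map.items():
            if s <= col < e:
                return name
        return None

    def subset_columns(self, columns: list[int]) -> "Alignment":
        return Alignment(
            list(self.taxa),
            ["".join(seq[c] for c in columns) for seq in self.sequences],
        )


_BIOPYTHON_FORMAT = {"fasta": "fasta", "nexus": "nexus", "phylip": "phylip-relaxed"}


def read_alignment(path, format: str = "fasta") -> Alignment:
    """Read a multiple sequence alignment (``fasta``, ``nexus`` or relaxed
    ``phylip``); gap ``-`` preserved verbatim, case normalised to upper."""
    if format not in _BIOPYTHON_FORMAT:
        raise FormatError(f"unknown alignment format {format!r}")
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if format == "fasta":
        # AlignIO is strict about equal lengths but reports ragged rows as a
        # generic ValueError; read records first for a clearer error
        records = list(SeqIO.parse(io.StringIO(text), "fasta"))
        if not records:
            raise FormatError(f"{path}: no FASTA records")
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"{path}: ragged rows, lengths {sorted(lengths)}")
        taxa = [r.id for r in records]
        seqs = [str(r.seq) for r in records]
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                msa = AlignIO.read(io.StringIO(text), _BIOPYTHON_FORMAT[format])
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
        taxa = [r.id for r in msa]
        seqs = [str(r.seq) for r in msa]
    return Alignment(taxa, seqs)


def write_alignment(alignment: Alignment, path, format: str = "fasta") -> None:
    if format not in _BIOPYTHON_FORMAT:
        raise FormatError(f"unknown alignment format {format!r}")
    records = []
    for taxon, seq in zip(alignment.taxa, alignment.sequences):
        rec = SeqRecord(Seq(seq), id=taxon, description="")
        rec.annotations["molecule_type"] = "DNA"
        records.append(rec)
    msa = MultipleSeqAlignment(records)
    with open(path, "w") as handle:
        AlignIO.write(msa, handle, _BIOPYTHON_FORMAT[format])


def read_partition_file(path) -> dict[str, tuple[int, int]]:
    """Parse ``name = start-end`` lines (1-based inclusive) into half-open
    0-based intervals."""
    out: dict[str, tuple[int, int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            name, rng = (part.strip() for part in line.split("="))
            lo, hi = (int(x) for x in rng.split("-"))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: cannot parse {raw!r}") from exc
        if not (1 <= lo <= hi):
            raise FormatError(f"{path}:{lineno}: bad range {lo}-{hi}")
        out[name] = (lo - 1, hi)
    return out


# ---------------------------------------------------------------------------
# binary gap-character matrices


def ry_encode(matrix: "GapCharacterMatrix") -> Alignment:
    """Recode a binary matrix as purine/pyrimidine symbols (0→R, 1→Y,
    missing→?) so it can be written and analysed as DNA-format data."""
    code = {0: "R", 1: "Y", -1: "?"}
    seqs = ["".join(code[int(s)] for s in row) for row in matrix.states]
    return Alignment(list(matrix.taxa), seqs)


def ry_decode(alignment: Alignment) -> "GapCharacterMatrix":
    """Inverse of :func:`ry_encode` (R→0, Y→1, ?→missing)."""
    from .gap_coding import CharacterDescriptor, GapCharacterMatrix
    import numpy as np

    decode = {"R": 0, "Y": 1, "?": -1}
    try:
        states = np.array(
            [[decode[c] for c in seq] for seq in alignment.sequences], dtype=np.int8
        )
    except KeyError as exc:
        raise FormatError(f"symbol {exc} is not an RY/missing code") from exc
    if states.size == 0:
        states = states.reshape(len(alignment.taxa), 0)
    chars = [
        CharacterDescriptor(None, j, j + 1, 1) for j in range(alignment.n_columns)
    ]
    return GapCharacterMatrix(list(alignment.taxa), chars, states)


def write_character_matrix(matrix: "GapCharacterMatrix", path, dialect: str = "nexus_standard") -> None:
    """Write a binary character matrix: NEXUS ``datatype=standard`` with
    symbols ``01`` and missing ``?``, or RY-recoded FASTA."""
    if dialect == "ry_fasta":
        write_alignment(ry_encode(matrix), path, "fasta")
        return
    if dialect != "nexus_standard":
        raise FormatError(f"unknown character-matrix dialect {dialect!r}")
    code = {0: "0", 1: "1", -1: "?"}
    width = max((len(t) for t in matrix.taxa), default=1) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        '    FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=? GAP=-;',
        "    MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.states):
        cells = "".join(code[int(s)] for s in row)
        lines.append(f"    {_nexus_label(taxon):<{width}}{cells}")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))


def read_character_matrix(path) -> "GapCharacterMatrix":
    """Read a NEXUS ``datatype=standard`` 01 matrix."""
    from .gap_coding import CharacterDescriptor, GapCharacterMatrix
    import numpy as np

    try:
        dmat = dendropy.StandardCharacterMatrix.get(
            path=str(path), schema="nexus", preserve_underscores=True
        )
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    taxa = [t.label for t in dmat.taxon_namespace]
    rows = []
    for taxon in dmat.taxon_namespace:
        symbols = [str(c) for c in dmat[taxon]]
        rows.append([-1 if s in "?-" else int(s) for s in symbols])
    states = np.array(rows, dtype=np.int8)
    if states.size == 0:
        states = states.reshape(len(taxa), 0)
    chars = [CharacterDescriptor(None, j, j + 1, 1) for j in range(states.shape[1])]
    return GapCharacterMatrix(taxa, chars, states)


def _nexus_label(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`<>^-"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_tree(path) -> Tree:
    return parse_newick(Path(path).read_text())


def write_tree(tree: Tree, path, **kwargs) -> None:
    Path(path).write_text(tree.newick(**kwargs) + "\n")
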