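"""Amino-acid alphabet contract, FASTA input, and distance-matrix I/O.

The residue ordering fixed here (alphabetical one-letter codes by
default) defines the index ``i`` used by every downstream block of the
feature vector.  All pairwise distances are invariant to the ordering as
long as it is applied uniformly, so the choice is a reproducibility
convention, not a modelling decision.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Symmetry tolerance when validating a fully populated matrix.
SYMMETRY_TOL = 1e-9


class FastaParseError(ValueError):
    """Structurally malformed FASTA input."""


class SequenceValidationError(ValueError):
    """A sequence violates the alphabet contract."""


class MatrixFormatError(ValueError):
    """A distance-matrix file violates its declared format."""


class NonstandardPolicy(str, enum.Enum):
    """What to do with residues outside the 20-letter alphabet."""

    REJECT = "reject"
    STRIP = "strip"


@dataclass(frozen=True)
class AlphabetConfig:
    """Fixed residue ordering plus the non-standard-residue policy.

    ``residue_order[i]`` is the residue with (0-based) index ``i`` used
    everywhere downstream: transition-matrix rows/columns, content
    ratios, and position ratios all follow this ordering.
    """

    residue_order: str = STANDARD_RESIDUES
    nonstandard_policy: NonstandardPolicy = NonstandardPolicy.REJECT

    def __post_init__(self) -> None:
        order = self.residue_order
        if len(order) != 20 or len(set(order)) != 20:
            raise ValueError("residue_order must contain exactly 20 distinct letters")
        if not set(order) <= set(STANDARD_RESIDUES):
            bad = sorted(set(order) - set(STANDARD_RESIDUES))
            raise ValueError(f"residue_order contains non-standard letters: {bad}")

    @property
    def size(self) -> int:
        return len(self.residue_order)

    def index(self, residue: str) -> int:
        """0-based index of ``residue`` in the alphabet ordering."""
        i = self.residue_order.find(residue)
        if i < 0:
            raise SequenceValidationError(f"residue {residue!r} is not in the alphabet")
        return i

    def indices(self, residues: str) -> np.ndarray:
        """Vectorised residue-to-index lookup for a whole sequence."""
        lut = np.full(128, -1, dtype=np.int64)
        for i, r in enumerate(self.residue_order):
            lut[ord(r)] = i
        codes = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
        idx = lut[codes]
        if (idx < 0).any():
            pos = int(np.argmax(idx < 0))
            raise SequenceValidationError(
                f"residue {residues[pos]!r} at position {pos + 1} is not in the alphabet"
            )
        return idx


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence ``S = S_1 ... S_N``."""

    label: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise SequenceValidationError(
                f"sequence {self.label!r} has length {len(self.residues)}; "
                "at least 2 residues are required (a transition pair must exist)"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @classmethod
    def from_record(
        cls, label: str, raw: str, alphabet: AlphabetConfig
    ) -> "ProteinSequence":
        """Build a sequence from raw record text, applying the alphabet policy."""
        residues = "".join(raw.split()).upper()
        members = set(alphabet.residue_order)
        if alphabet.nonstandard_policy is NonstandardPolicy.STRIP:
            kept = "".join(r for r in residues if r in members)
            removed = len(residues) - len(kept)
            if removed:
                logger.warning(
                    "record %r: stripped %d non-standard character(s)", label, removed
                )
            residues = kept
        else:
            for pos, r in enumerate(residues, start=1):
                if r not in members:
                    raise SequenceValidationError(
                        f"record {label!r}: non-standard residue {r!r} at position {pos}"
                    )
        if len(residues) < 2:
            raise SequenceValidationError(
                f"record {label!r}: fewer than 2 valid residues remain"
            )
        return cls(label=label, residues=residues)


def read_fasta(
    path: str | Path, alphabet: AlphabetConfig | None = None
) -> list[ProteinSequence]:
    """Read and validate protein sequences from a FASTA file.

    Under ``nonstandard_policy=strip``, characters outside the alphabet
    (ambiguity codes, gaps) are removed with a logged per-record count;
    under ``reject`` (the default) they raise
    :class:`SequenceValidationError` naming the record and position.
    """
    alphabet = alphabet or AlphabetConfig()
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected '>' header, got {line.strip()[:30]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: no FASTA records found")
    with path.open() as handle:
        records = [
            ProteinSequence.from_record(title.split()[0] if title else "", seq, alphabet)
            for title, seq in SimpleFastaParser(handle)
        ]
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60
) -> None:
    """Write sequences as FASTA, wrapping residue lines at ``width``."""
    with Path(path).open("w") as handle:
        for seq in seqs:
            handle.write(f">{seq.label}\n")
            for start in range(0, seq.length, width):
                handle.write(seq.residues[start : start + width] + "\n")


@dataclass(frozen=True)
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        k = len(self.labels)
        if k == 0:
            raise MatrixFormatError("empty distance matrix")
        if len(set(self.labels)) != k:
            raise MatrixFormatError("duplicate labels in distance matrix")
        if values.shape != (k, k):
            raise MatrixFormatError(
                f"matrix shape {values.shape} does not match {k} labels"
            )
        if not np.isfinite(values).all():
            raise MatrixFormatError("distance matrix contains non-finite values")
        if (values < 0).any():
            raise MatrixFormatError("distance matrix contains negative values")
        if np.abs(np.diagonal(values)).max() > 0:
            raise MatrixFormatError("distance matrix diagonal must be zero")
        if np.abs(values - values.T).max() > SYMMETRY_TOL:
            raise MatrixFormatError(
                f"distance matrix asymmetric beyond tolerance {SYMMETRY_TOL}"
            )

    @property
    def size(self) -> int:
        return len(self.labels)

    def reindex(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return the matrix with rows/columns reordered to ``labels``."""
        if set(labels) != set(self.labels) or len(labels) != self.size:
            raise ValueError("reindex labels must be a permutation of matrix labels")
        pos = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(pos, pos)])

    def upper_triangle(self) -> np.ndarray:
        """Strictly upper-triangular entries in row-major order."""
        iu = np.triu_indices(self.size, k=1)
        return self.values[iu]


def _format_cell(x: float, digits: int | None) -> str:
    if digits is None:
        return repr(float(x))
    return f"{x:.{digits}f}"


def write_distance_matrix(
    m: DistanceMatrix,
    path: str | Path,
    format: str = "csv",
    digits: int | None = None,
) -> None:
    """Write a distance matrix as CSV or square PHYLIP.

    Cells are written with full double precision unless ``digits`` is
    given, which controls display rounding only.
    """
    path = Path(path)
    if format == "csv":
        with path.open("w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow([""] + list(m.labels))
            for label, row in zip(m.labels, m.values):
                writer.writerow([label] + [_format_cell(x, digits) for x in row])
    elif format == "phylip":
        width = max(10, max(len(l) for l in m.labels) + 1)
        with path.open("w") as handle:
            handle.write(f"{m.size}\n")
            for label, row in zip(m.labels, m.values):
                cells = " ".join(_format_cell(x, digits) for x in row)
                handle.write(f"{label:<{width}} {cells}\n")
    else:
        raise ValueError(f"unknown distance-matrix format {format!r}")


def _mirror(labels: list[str], grid: np.ndarray, source: str) -> DistanceMatrix:
    """Fill missing (NaN) cells from the transpose and validate symmetry.

    Published tables are often printed upper-triangular with the final
    (all-implied) row omitted; this completes them to full symmetry.
    """
    k = len(labels)
    both = ~np.isnan(grid) & ~np.isnan(grid.T)
    if both.any() and np.nanmax(np.abs(np.where(both, grid - grid.T, 0.0))) > SYMMETRY_TOL:
        raise MatrixFormatError(f"{source}: asymmetry beyond tolerance {SYMMETRY_TOL}")
    filled = np.where(np.isnan(grid), grid.T, grid)
    np.fill_diagonal(filled, np.where(np.isnan(np.diagonal(filled)), 0.0, np.diagonal(filled)))
    if np.isnan(filled).any():
        i, j = np.argwhere(np.isnan(filled))[0]
        raise MatrixFormatError(
            f"{source}: cell ({labels[i]}, {labels[j]}) missing from both triangles"
        )
    return DistanceMatrix(tuple(labels), filled)


def read_distance_matrix(path: str | Path, format: str = "csv") -> DistanceMatrix:
    """Read a labelled square distance matrix from CSV or PHYLIP.

    Upper-triangular input (missing lower-triangle cells, trailing rows
    omitted) is mirrored to full symmetry.
    """
    path = Path(path)
    if format == "csv":
        with path.open(newline="") as handle:
            rows = [r for r in csv.reader(handle) if any(c.strip() for c in r)]
        if not rows:
            raise MatrixFormatError(f"{path}: empty file")
        labels = [c.strip() for c in rows[0][1:]]
        k = len(labels)
        if k == 0:
            raise MatrixFormatError(f"{path}: no labels in header")
        if len(rows) - 1 > k:
            raise MatrixFormatError(f"{path}: more data rows than labels (not square)")
        grid = np.full((k, k), np.nan)
        for row in rows[1:]:
            label = row[0].strip()
            if label not in labels:
                raise MatrixFormatError(f"{path}: unknown row label {label!r}")
            i = labels.index(label)
            cells = row[1:]
            if len(cells) > k:
                raise MatrixFormatError(
                    f"{path}: row {label!r} has {len(cells)} cells for {k} labels"
                )
            for j, cell in enumerate(cells):
                if cell.strip():
                    grid[i, j] = float(cell)
        return _mirror(labels, grid, str(path))
    if format == "phylip":
        with path.open() as handle:
            lines = [l.rstrip("\n") for l in handle if l.strip()]
        if not lines:
            raise MatrixFormatError(f"{path}: empty file")
        try:
            k = int(lines[0].split()[0])
        except ValueError as exc:
            raise MatrixFormatError(f"{path}: bad PHYLIP count line") from exc
        body = lines[1:]
        if len(body) != k:
            raise MatrixFormatError(f"{path}: expected {k} rows, found {len(body)}")
        labels, grid = [], np.full((k, k), np.nan)
        for i, line in enumerate(body):
            parts = line.split()
            labels.append(parts[0])
            cells = parts[1:]
            if len(cells) > k:
                raise MatrixFormatError(f"{path}: row {parts[0]!r} is not square")
            for j, cell in enumerate(cells):
                grid[i, j] = float(cell)
        if len(set(labels)) != k:
            raise MatrixFormatError(f"{path}: duplicate labels")
        return _mirror(labels, grid, str(path))
    raise ValueError(f"unknown distance-matrix format {format!r}")
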