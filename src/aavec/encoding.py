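"""Encoding of a protein sequence into a 440-D feature vector.

The vector concatenates three blocks, in fixed order:

* ``P`` (400-D): empirical transition probabilities among the 20 amino
  acids in row-major ``(i, j)`` order.  Row ``i`` is divided by the
  number of occurrences of residue ``i`` — minus one when residue ``i``
  is the final residue of the sequence, since the final occurrence
  starts no pair.  This endpoint correction makes every defined row sum
  to exactly 1; rows whose denominator is zero are all zeros.
* ``C`` (20-D): content ratios, the fraction of positions occupied by
  each residue.
* ``D`` (20-D): position ratios, the sum of the 1-based positions of
  each residue divided by ``N(N+1)/2``.

The weighted column sums ``sum_i C_i * P_{i,j}`` admit an exact closed
form in terms of ``C_j``, ``N`` and the transition row of the final
residue; :func:`verify_delta_identity` executes that identity as an
internal consistency check on the encoder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .alphabet_io import AlphabetConfig, ProteinSequence

#: Valid block names, in concatenation order.
BLOCK_ORDER = ("P", "C", "D")

_BLOCK_SIZES = {"P": 400, "C": 20, "D": 20}


@dataclass(frozen=True)
class CountsSummary:
    """Exact integer tallies from which all three blocks derive.

    Attributes
    ----------
    occurrence_counts : (20,) int array
        Number of occurrences of each residue.
    pair_counts : (20, 20) int array
        Number of occurrences of each ordered adjacent residue pair.
    position_sums : (20,) int array
        Sum of the 1-based positions at which each residue occurs.
    first_residue_index, last_residue_index : int
        0-based alphabet indices of the first and last residues.
    length : int
        Sequence length ``N``.
    """

    occurrence_counts: np.ndarray = field(repr=False)
    pair_counts: np.ndarray = field(repr=False)
    position_sums: np.ndarray = field(repr=False)
    first_residue_index: int
    last_residue_index: int
    length: int


def tally(seq: ProteinSequence, alphabet: AlphabetConfig | None = None) -> CountsSummary:
    """Count residue occurrences, adjacent ordered pairs, and position sums.

    All arithmetic is exact integer arithmetic; division to reals
    happens once, at probability construction.
    """
    alphabet = alphabet or AlphabetConfig()
    idx = alphabet.indices(seq.residues)
    k = alphabet.size
    occurrence = np.bincount(idx, minlength=k).astype(np.int64)
    pair_flat = np.bincount(idx[:-1] * k + idx[1:], minlength=k * k)
    positions = np.arange(1, seq.length + 1, dtype=np.int64)
    position_sums = np.bincount(idx, weights=positions, minlength=k).astype(np.int64)
    return CountsSummary(
        occurrence_counts=occurrence,
        pair_counts=pair_flat.reshape(k, k).astype(np.int64),
        position_sums=position_sums,
        first_residue_index=int(idx[0]),
        last_residue_index=int(idx[-1]),
        length=seq.length,
    )


def transition_probabilities(counts: CountsSummary) -> np.ndarray:
    """Flattened 400-D transition-probability block.

    Row ``i`` is ``pair_counts[i] / occurrence_counts[i]``, with the
    denominator reduced by one for the final residue's row.  Rows with a
    zero denominator (absent residue, or a residue occurring exactly
    once at the end) are all zeros.
    """
    denom = counts.occurrence_counts.astype(float).copy()
    denom[counts.last_residue_index] -= 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        probs = counts.pair_counts / denom[:, None]
    probs[denom == 0.0] = 0.0
    return probs.reshape(-1)


def content_ratios(counts: CountsSummary) -> np.ndarray:
    """20-D content-ratio block: occurrence counts over ``N``."""
    return counts.occurrence_counts / counts.length


def position_ratios(counts: CountsSummary) -> np.ndarray:
    """20-D position-ratio block: position sums over ``N(N+1)/2``."""
    n = counts.length
    return 2.0 * counts.position_sums / (n * (n + 1))


@dataclass(frozen=True)
class FeatureVector:
    """Concatenation of selected blocks, with provenance for checks."""

    values: np.ndarray = field(repr=False)
    blocks: tuple[str, ...]
    source_length: int
    first_residue_index: int
    last_residue_index: int
    alphabet: AlphabetConfig

    def __post_init__(self) -> None:
        expected = sum(_BLOCK_SIZES[b] for b in self.blocks)
        if self.values.shape != (expected,):
            raise ValueError(
                f"feature vector has shape {self.values.shape}, expected ({expected},)"
            )

    @property
    def dimension(self) -> int:
        return self.values.size

    def block(self, name: str) -> np.ndarray:
        """The sub-vector for one block (``P`` reshaped to 20x20)."""
        if name not in self.blocks:
            raise KeyError(f"block {name!r} was not encoded (have {self.blocks})")
        start = 0
        for b in self.blocks:
            size = _BLOCK_SIZES[b]
            if b == name:
                part = self.values[start : start + size]
                return part.reshape(20, 20) if name == "P" else part
            start += size
        raise AssertionError("unreachable")


def _normalize_blocks(blocks: Iterable[str]) -> tuple[str, ...]:
    chosen = set(blocks)
    if not chosen:
        raise ValueError("at least one block must be selected")
    unknown = chosen - set(BLOCK_ORDER)
    if unknown:
        raise ValueError(f"unknown block name(s): {sorted(unknown)}")
    return tuple(b for b in BLOCK_ORDER if b in chosen)


def encode(
    seq: ProteinSequence,
    alphabet: AlphabetConfig | None = None,
    blocks: Iterable[str] = BLOCK_ORDER,
) -> FeatureVector:
    """Encode a sequence into the feature vector of the selected blocks.

    ``blocks`` defaults to all three (the full 440-D vector); subsets
    such as ``{"C"}``, ``{"D"}`` or ``{"C", "D"}`` support ablation
    analyses.  The relative P, C, D order is always preserved.
    """
    alphabet = alphabet or AlphabetConfig()
    chosen = _normalize_blocks(blocks)
    counts = tally(seq, alphabet)
    parts = {
        "P": transition_probabilities,
        "C": content_ratios,
        "D": position_ratios,
    }
    values = np.concatenate([parts[b](counts) for b in chosen])
    return FeatureVector(
        values=values,
        blocks=chosen,
        source_length=counts.length,
        first_residue_index=counts.first_residue_index,
        last_residue_index=counts.last_residue_index,
        alphabet=alphabet,
    )


def delta(v: FeatureVector, j: int) -> float:
    """Content-weighted column sum ``sum_i C_i * P_{i,j}`` (0-based ``j``)."""
    if not {"P", "C"} <= set(v.blocks):
        raise ValueError("delta requires a vector encoded with both P and C blocks")
    if not 0 <= j < 20:
        raise ValueError(f"column index {j} out of range 0..19")
    return float(v.block("C") @ v.block("P")[:, j])


def delta_closed_form(v: FeatureVector, j: int) -> float:
    """Closed form for :func:`delta` from ``C_j``, ``N`` and the last row.

    With ``u``/``v`` the first/last residue indices and ``N`` the length:
    ``C_j + P_{v,j}/N``, minus ``1/N`` when ``j == u``.  When the last
    residue occurs only once its transition row is zero, so the formula
    reduces to ``C_j`` (minus ``1/N`` when ``j == u``).
    """
    if not {"P", "C"} <= set(v.blocks):
        raise ValueError("delta requires a vector encoded with both P and C blocks")
    if not 0 <= j < 20:
        raise ValueError(f"column index {j} out of range 0..19")
    n = v.source_length
    base = float(v.block("C")[j]) + float(v.block("P")[v.last_residue_index, j]) / n
    if j == v.first_residue_index:
        base -= 1.0 / n
    return base


def verify_delta_identity(
    seq: ProteinSequence, alphabet: AlphabetConfig | None = None
) -> np.ndarray:
    """Residuals ``|delta(j) - closed_form(j)|`` for all 20 columns.

    A correct encoder keeps every residual at rounding-error level
    (<= 1e-12); anything larger indicates an encoding bug.
    """
    v = encode(seq, alphabet)
    return np.array(
        [abs(delta(v, j) - delta_closed_form(v, j)) for j in range(20)]
    )
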