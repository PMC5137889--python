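"""Pairwise distances between feature vectors and matrix agreement scoring."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .alphabet_io import AlphabetConfig, DistanceMatrix, ProteinSequence
from .encoding import BLOCK_ORDER, FeatureVector, encode


@dataclass(frozen=True)
class MetricSpec:
    """Distance metric on feature vectors.

    ``euclidean`` is the root-sum-of-squares over coordinates.
    ``hamming`` counts coordinates whose absolute difference exceeds
    ``hamming_tolerance`` (default 0, i.e. exact inequality); the
    tolerance is ignored by the euclidean metric.
    """

    name: str = "euclidean"
    hamming_tolerance: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("euclidean", "hamming"):
            raise ValueError(f"unknown metric {self.name!r}")
        if self.hamming_tolerance < 0:
            raise ValueError("hamming_tolerance must be non-negative")


def vector_distance(a: FeatureVector, b: FeatureVector, metric: MetricSpec | None = None) -> float:
    """Distance between two feature vectors under ``metric``.

    Both vectors must have been encoded with the same block selection
    and alphabet ordering.
    """
    metric = metric or MetricSpec()
    if a.blocks != b.blocks or a.alphabet != b.alphabet:
        raise ValueError("feature vectors use different block selections or alphabets")
    if a.values.shape != b.values.shape:
        raise ValueError("feature vector dimension mismatch")
    diff = a.values - b.values
    if metric.name == "euclidean":
        return float(np.sqrt(np.sum(diff * diff)))
    return float(np.count_nonzero(np.abs(diff) > metric.hamming_tolerance))


def pairwise_matrix(
    seqs: Sequence[ProteinSequence],
    metric: MetricSpec | None = None,
    blocks: Iterable[str] = BLOCK_ORDER,
    alphabet: AlphabetConfig | None = None,
) -> DistanceMatrix:
    """Pairwise distance matrix over sequences, in input label order."""
    metric = metric or MetricSpec()
    if len(seqs) < 2:
        raise ValueError("at least 2 sequences are required")
    labels = [s.label for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    vectors = np.vstack([encode(s, alphabet, blocks).values for s in seqs])
    if metric.name == "euclidean":
        condensed = pdist(vectors, metric="euclidean")
    else:
        diffs = np.abs(vectors[:, None, :] - vectors[None, :, :])
        counts = np.count_nonzero(diffs > metric.hamming_tolerance, axis=2)
        condensed = squareform(counts.astype(float), checks=False)
    return DistanceMatrix(tuple(labels), squareform(condensed))


def matrix_correlation(m1: DistanceMatrix, m2: DistanceMatrix) -> tuple[float, int]:
    """Pearson correlation between two distance matrices.

    Matrices are aligned by label name (not position) and the
    correlation is computed over the strictly-upper-triangular entries
    only, so diagonal zeros and the duplicated symmetric half never
    contribute.  Returns ``(r, number_of_pairs)``.
    """
    if set(m1.labels) != set(m2.labels) or m1.size != m2.size:
        raise ValueError("distance matrices have different label sets")
    x = m1.upper_triangle()
    y = m2.reindex(m1.labels).upper_triangle()
    if x.size < 3:
        raise ValueError("need at least 3 sequence pairs for a correlation")
    r = pearsonr(x, y).statistic
    return float(r), int(x.size)
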