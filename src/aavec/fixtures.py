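"""Synthetic protein-sequence generators for tests and benchmarks.

Sequences are sampled either i.i.d. from a target residue composition or
from a first-order Markov chain with a given row-stochastic transition
matrix.  A single integer seed makes every draw reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet_io import AlphabetConfig, ProteinSequence

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SequenceModel:
    """Sampling model for one family of synthetic sequences.

    ``composition`` gives the target residue frequencies (and the
    initial-state distribution when ``transition_bias`` is set).
    ``transition_bias``, when provided, is a 20x20 row-stochastic matrix
    defining a first-order chain.
    """

    length: int
    composition: Sequence[float]
    transition_bias: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be at least 2")
        comp = np.asarray(self.composition, dtype=float)
        if comp.shape != (20,) or (comp < 0).any():
            raise ValueError("composition must be 20 non-negative reals")
        if abs(comp.sum() - 1.0) > _SUM_TOL:
            raise ValueError("composition must sum to 1")
        object.__setattr__(self, "composition", comp)
        if self.transition_bias is not None:
            t = np.asarray(self.transition_bias, dtype=float)
            if t.shape != (20, 20) or (t < 0).any():
                raise ValueError("transition_bias must be a 20x20 non-negative matrix")
            if np.abs(t.sum(axis=1) - 1.0).max() > _SUM_TOL:
                raise ValueError("transition_bias rows must each sum to 1")
            object.__setattr__(self, "transition_bias", t)


def generate(
    model: SequenceModel,
    alphabet: AlphabetConfig | None = None,
    label: str | None = None,
) -> ProteinSequence:
    """Sample one sequence from ``model``; deterministic for a fixed seed."""
    alphabet = alphabet or AlphabetConfig()
    rng = np.random.default_rng(model.seed)
    if model.transition_bias is None:
        idx = rng.choice(20, size=model.length, p=model.composition)
    else:
        idx = np.empty(model.length, dtype=np.int64)
        idx[0] = rng.choice(20, p=model.composition)
        # cumulative-row inverse sampling keeps the loop cheap
        cum = np.cumsum(model.transition_bias, axis=1)
        cum[:, -1] = 1.0
        draws = rng.random(model.length - 1)
        for pos in range(1, model.length):
            idx[pos] = np.searchsorted(cum[idx[pos - 1]], draws[pos - 1], side="right")
    residues = "".join(alphabet.residue_order[i] for i in idx)
    return ProteinSequence(label=label or f"sim_seed{model.seed}", residues=residues)


def generate_families(
    n_per_family: int,
    models: Sequence[SequenceModel],
    alphabet: AlphabetConfig | None = None,
) -> list[ProteinSequence]:
    """Sample ``n_per_family`` labelled sequences from each family model.

    Family ``f``, member ``m`` gets label ``fam{f}_seq{m}`` and seed
    ``model.seed + m`` so members are distinct but reproducible.
    """
    if len(models) < 2:
        raise ValueError("at least 2 family models are required")
    out: list[ProteinSequence] = []
    for f, model in enumerate(models):
        for m in range(n_per_family):
            member = SequenceModel(
                length=model.length,
                composition=model.composition,
                transition_bias=model.transition_bias,
                seed=model.seed + m,
            )
            out.append(generate(member, alphabet, label=f"fam{f}_seq{m}"))
    return out


def random_composition(rng: np.random.Generator, concentration: float = 5.0) -> np.ndarray:
    """Random residue composition drawn from a symmetric Dirichlet."""
    return rng.dirichlet(np.full(20, concentration))


def random_transition_matrix(
    rng: np.random.Generator, concentration: float = 5.0
) -> np.ndarray:
    """Random row-stochastic 20x20 matrix with Dirichlet rows."""
    return rng.dirichlet(np.full(20, concentration), size=20)


def random_sequence(
    rng: np.random.Generator,
    length: int,
    alphabet: AlphabetConfig | None = None,
    label: str = "random",
) -> ProteinSequence:
    """Uniform random sequence of ``length`` residues (test helper)."""
    alphabet = alphabet or AlphabetConfig()
    idx = rng.integers(0, 20, size=length)
    return ProteinSequence(label=label, residues="".join(alphabet.residue_order[i] for i in idx))
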