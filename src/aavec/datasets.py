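"""Bundled reference data for the 9-species ND5 benchmark.

Two published pairwise distance matrices over the ND5 proteins of nine
mammals (human, gorilla, pigmy and common chimpanzee, fin and blue
whale, rat, mouse, opossum) are shipped as CSV: one produced by the
feature-vector method implemented here, one by the alignment-based
ClustalW aligner.  Both are stored exactly as published —
upper-triangular with the final all-implied row omitted — and completed
to full symmetry on load.

The ND5 protein sequences themselves are not redistributed; they can be
fetched from NCBI under the accessions listed in the README and passed
to :func:`aavec.read_fasta`.
"""

from __future__ import annotations

from importlib import resources

from .alphabet_io import DistanceMatrix, read_distance_matrix

ND5_SPECIES = (
    "Human",
    "Gorilla",
    "P.chim",
    "C.chim",
    "F.whale",
    "B.whale",
    "Rat",
    "Mouse",
    "Opossum",
)

#: NCBI protein accessions of the nine ND5 sequences, by species label.
ND5_ACCESSIONS = {
    "Human": "AP_000649",
    "Gorilla": "NP_008222",
    "P.chim": "NP_008209",
    "C.chim": "NP_008196",
    "F.whale": "NP_006899",
    "B.whale": "NP_007066",
    "Rat": "NP_004902",
    "Mouse": "NP_904338",
    "Opossum": "NP_007105",
}


def load_nd5_fasta(path) -> list:
    """Read a user-supplied FASTA of the nine ND5 proteins.

    Records are matched to species by NCBI accession (version suffixes
    ignored) or by species label, and returned in the canonical
    :data:`ND5_SPECIES` order with species labels.
    """
    from .alphabet_io import ProteinSequence, read_fasta

    seqs = read_fasta(path)
    by_species = {}
    acc_to_species = {v: k for k, v in ND5_ACCESSIONS.items()}
    for seq in seqs:
        key = seq.label.split(".")[0]
        species = acc_to_species.get(key) or (seq.label if seq.label in ND5_SPECIES else None)
        if species is None:
            raise ValueError(
                f"record {seq.label!r} matches no ND5 accession or species label"
            )
        by_species[species] = seq
    missing = [s for s in ND5_SPECIES if s not in by_species]
    if missing:
        raise ValueError(f"ND5 FASTA is missing species: {missing}")
    return [
        ProteinSequence(label=s, residues=by_species[s].residues) for s in ND5_SPECIES
    ]


def _load(name: str) -> DistanceMatrix:
    ref = resources.files("aavec") / "data" / name
    with resources.as_file(ref) as path:
        return read_distance_matrix(path, format="csv")


def nd5_feature_distances() -> DistanceMatrix:
    """Published 9x9 ND5 distance matrix from the 440-D feature vectors."""
    return _load("nd5_feature_distances.csv")


def nd5_clustalw_distances() -> DistanceMatrix:
    """Published 9x9 ND5 distance matrix from ClustalW alignments."""
    return _load("nd5_clustalw_distances.csv")
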