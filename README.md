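# aavec

Alignment-free protein sequence comparison via amino-acid
transition-probability feature vectors.

Each protein sequence is encoded into a 440-dimensional vector made of
three blocks:

- **P** (400-D) — empirical transition probabilities between ordered
  pairs of the 20 amino acids. The row of the sequence's final residue
  is divided by its occurrence count minus one (the final occurrence
  starts no pair), which makes every defined row sum to exactly 1. Rows
  whose denominator is zero (absent residue, or a residue occurring only
  once at the very end) are all zeros.
- **C** (20-D) — content ratios: the fraction of positions occupied by
  each residue.
- **D** (20-D) — position ratios: the sum of each residue's 1-based
  positions divided by `N(N+1)/2`.

Sequences are compared by the Euclidean (or Hamming) distance between
their vectors. Whole distance matrices can be scored against a reference
matrix (e.g. one derived from alignments) by the Pearson correlation of
their strictly-upper-triangular entries, aligned by label.

The encoder carries an executable self-check: the content-weighted
column sums `Σᵢ Cᵢ·P_{i,j}` have an exact closed form in terms of `C_j`,
`N` and the final residue's transition row, and
`aavec.verify_delta_identity` verifies it to 1e-12 for any sequence.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis) for the tally
identities, row-stochasticity, and the closed-form identity, plus an
acceptance suite (`tests/test_acceptance.py`). Tests that need the ND5
benchmark sequences (see below) skip cleanly when the data is absent.

## CLI

```sh
aavec encode proteins.fasta -o vectors.csv --blocks PCD
aavec distmat proteins.fasta -o dist.csv --metric euclidean --format csv
aavec correlate dist.csv reference.csv
aavec simulate synthetic.fasta --n 10 --length 300 --families 2 --seed 1
```

- `--blocks` selects any subset of `PCD` for ablation analyses (e.g.
  `--blocks CD` for the 40-D content+position encoding).
- `distmat` writes CSV or square PHYLIP (`--format phylip`); cells are
  full double precision unless `--digits` is given.
- `correlate` reads two labelled distance matrices (upper-triangular
  input is mirrored automatically) and prints the Pearson r and the
  number of pairs used.
- Every run logs version, alphabet order, metric, block selection, and
  input checksums to stderr; outputs are written atomically.

## ND5 benchmark data

Two published 9×9 reference distance matrices over mammalian ND5
proteins are bundled (`aavec.datasets`): one from this feature-vector
method and one from ClustalW alignments. Their upper-triangle Pearson
correlation is 0.962 over 36 species pairs.

The ND5 protein sequences themselves are not redistributed. To run the
sequence-level benchmarks, fetch these NCBI protein records and save
them (FASTA) as `data/nd5.fasta`:

| Species            | Accession |
| ------------------ | --------- |
| Human              | AP_000649 |
| Gorilla            | NP_008222 |
| Pigmy chimpanzee   | NP_008209 |
| Common chimpanzee  | NP_008196 |
| Fin whale          | NP_006899 |
| Blue whale         | NP_007066 |
| Rat                | NP_004902 |
| Mouse              | NP_904338 |
| Opossum            | NP_007105 |

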