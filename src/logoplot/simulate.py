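"""Synthetic alignments and matrices with known ground truth.

Every downstream module is testable without external data: a
:class:`MotifModel` holds a generating PWM from which alignments are
drawn column-independently, and :func:`make_random_matrix` produces
type-correct random matrices of any semantic type.  All randomness flows
through one explicitly seeded ``numpy`` generator — no global state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import Alignment
from .matrix import (
    Background,
    PositionCharacterMatrix,
    probability_to_information,
    probability_to_weight,
    validate_matrix,
)

DEFAULT_ALPHABET = "ACGT"


@dataclass
class MotifModel:
    """A generating PWM plus sampling parameters.

    ``matrix`` must be a probability matrix; each simulated sequence
    draws its character at column ``i`` independently from row ``i``.
    """

    matrix: PositionCharacterMatrix
    n_sequences: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix.matrix_type != "probability":
            raise ValueError("MotifModel requires a probability matrix")
        validate_matrix(self.matrix)
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")

    @property
    def alphabet(self) -> list[str]:
        return self.matrix.characters


def simulate_alignment(model: MotifModel) -> Alignment:
    """Draw ``model.n_sequences`` sequences from the PWM.

    Columns are independent; deterministic given (model, seed).
    """
    rng = np.random.default_rng(model.seed)
    chars = np.array(model.alphabet)
    probs = model.matrix.values
    # renormalize defensively: validate() allows 1e-8 slack
    probs = probs / probs.sum(axis=1, keepdims=True)
    columns = [
        rng.choice(len(chars), size=model.n_sequences, p=row) for row in probs
    ]
    codes = np.stack(columns, axis=1)  # (n_sequences, length)
    records = [
        (f"seq{k}", "".join(chars[codes[k]])) for k in range(model.n_sequences)
    ]
    return Alignment(records)


def make_random_matrix(
    matrix_type: str = "probability",
    n_positions: int = 8,
    alphabet: str | list[str] = DEFAULT_ALPHABET,
    seed: int = 0,
) -> PositionCharacterMatrix:
    """A type-correct random matrix, deterministic given ``seed``.

    counts: integers in [0, 20]; probability: Dirichlet(1,...,1) rows
    (strictly positive); weight: log-odds of such rows against a uniform
    background; information: heights of such rows; user: standard
    normals.
    """
    rng = np.random.default_rng(seed)
    chars = list(alphabet)
    n_chars = len(chars)
    if matrix_type == "counts":
        values = rng.integers(0, 21, size=(n_positions, n_chars)).astype(float)
    elif matrix_type in ("probability", "weight", "information"):
        values = rng.dirichlet(np.ones(n_chars), size=n_positions)
        # Dirichlet can emit exact zeros at float precision; nudge away
        values = np.clip(values, 1e-12, None)
        values = values / values.sum(axis=1, keepdims=True)
    elif matrix_type == "user":
        values = rng.normal(size=(n_positions, n_chars))
    else:
        raise ValueError(f"unknown matrix_type {matrix_type!r}")

    table = PositionCharacterMatrix.from_values(
        values,
        chars,
        matrix_type="probability" if matrix_type in ("weight", "information") else matrix_type,
    )
    if matrix_type == "weight":
        table = probability_to_weight(table, Background.uniform(chars))
    elif matrix_type == "information":
        table = probability_to_information(table, Background.uniform(chars))
    return table


def make_random_alignment(
    n_sequences: int = 20,
    length: int = 10,
    alphabet: str | list[str] = DEFAULT_ALPHABET,
    gap_fraction: float = 0.0,
    seed: int = 0,
) -> Alignment:
    """A random ungapped-or-gapped alignment for tally tests.

    ``gap_fraction`` of positions (independently per cell) are replaced
    by '-'.
    """
    rng = np.random.default_rng(seed)
    chars = np.array(list(alphabet))
    codes = rng.integers(0, len(chars), size=(n_sequences, length))
    seqs = ["".join(chars[row]) for row in codes]
    if gap_fraction > 0:
        mask = rng.random(size=(n_sequences, length)) < gap_fraction
        seqs = [
            "".join("-" if mask[i, j] else s[j] for j in range(length))
            for i, s in enumerate(seqs)
        ]
    return Alignment([(f"seq{i}", s) for i, s in enumerate(seqs)])
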