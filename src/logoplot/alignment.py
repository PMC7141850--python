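"""Alignments, single sequences and saliency tracks as matrix sources.

A sequence logo summarising a multiple-sequence alignment starts from a
counts matrix: ``n[i,c]`` = number of sequences carrying character ``c``
at column ``i``.  This module reads FASTA alignments (via Biopython),
tallies them, and also builds the two single-sequence matrix flavours:
one-hot matrices (for wild-type overlays) and masked saliency matrices
(one externally supplied importance score per position, e.g. a neural
network attribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlphabetError, FastaFormatError, RaggedAlignmentError
from .matrix import (
    GAP_CHARS,
    Background,
    PositionCharacterMatrix,
    transform_matrix,
)

PathOrStream = Union[str, Path, IO[str]]

DNA_LETTERS = frozenset("ACGT")
RNA_LETTERS = frozenset("ACGU")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class Alignment:
    """Equal-length sequences with identifiers."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.records:
            raise FastaFormatError("alignment contains no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            by_len: dict[int, list[str]] = {}
            for ident, seq in self.records:
                by_len.setdefault(len(seq), []).append(ident)
            raise RaggedAlignmentError(
                f"sequences have unequal lengths {sorted(by_len)}; "
                f"records by length: {by_len}"
            )
        if lengths == {0}:
            raise FastaFormatError("alignment sequences are empty")
        for ident, _ in self.records:
            if not ident:
                raise FastaFormatError("empty sequence identifier")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    @property
    def identifiers(self) -> list[str]:
        return [ident for ident, _ in self.records]


@dataclass
class SaliencyTrack:
    """A single sequence plus one importance score per character."""

    sequence: str
    scores: Sequence[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = [float(s) for s in self.scores]
        if len(self.scores) != len(self.sequence):
            raise FastaFormatError(
                f"saliency track has {len(self.sequence)} characters but "
                f"{len(self.scores)} scores"
            )
        if not all(np.isfinite(self.scores)):
            raise FastaFormatError("saliency scores must all be finite")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: PathOrStream) -> Alignment:
    """Read an aligned FASTA file (or open text stream).

    Sequence lines are concatenated, surrounding whitespace stripped and
    case preserved.  Records must all share one length.
    """
    if hasattr(source, "read"):
        handle, close = source, False
    else:
        handle, close = open(source), True
    try:
        records = [(rec.id, str(rec.seq).strip()) for rec in SeqIO.parse(handle, "fasta")]
    finally:
        if close:
            handle.close()
    if not records:
        raise FastaFormatError("no FASTA records found (missing '>' header?)")
    return Alignment(records)


def write_fasta(aln: Alignment, target: PathOrStream) -> None:
    """Write an alignment as FASTA (one line per sequence)."""
    records = [
        SeqRecord(Seq(seq), id=ident, description="") for ident, seq in aln.records
    ]
    if hasattr(target, "write"):
        SeqIO.write(records, target, "fasta-2line")
    else:
        with open(target, "w") as handle:
            SeqIO.write(records, handle, "fasta-2line")


# ---------------------------------------------------------------------------
# matrices from sequence data


def alignment_to_matrix(
    aln: Alignment,
    characters: Sequence[str] | None = None,
    to_type: str = "counts",
    pseudocount: float = 1.0,
    background: Background | None = None,
    weights: Sequence[float] | None = None,
    start_position: int = 0,
    strict: bool = False,
    case_sensitive: bool = False,
) -> PositionCharacterMatrix:
    """Tally an alignment into a counts matrix, optionally transformed.

    Characters are uppercased before tallying (unless ``case_sensitive``).
    Gap characters (``-``, ``.``, ``*``) and anything outside the chosen
    alphabet are excluded from the tally, so column totals may differ
    across positions; with ``strict=True`` such characters raise
    :class:`AlphabetError` instead.  The default alphabet is the sorted
    set of observed non-gap characters; a user-supplied ``characters``
    order wins.

    ``weights`` gives one non-negative weight per record (default:
    uniform 1), letting callers weight sequences e.g. by usage counts.
    ``to_type != 'counts'`` forwards through
    :func:`~logoplot.matrix.transform_matrix`.
    """
    seqs = aln.sequences
    if not case_sensitive:
        seqs = [s.upper() for s in seqs]
    if weights is None:
        w = np.ones(len(seqs))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(seqs),):
            raise ValueError(
                f"weights must have one entry per record ({len(seqs)}), "
                f"got shape {w.shape}"
            )
        if (w < 0).any():
            raise ValueError("sequence weights must be >= 0")

    if characters is None:
        observed = set("".join(seqs)) - GAP_CHARS
        alphabet = sorted(observed)
    else:
        alphabet = [str(c) for c in characters]
        if not case_sensitive:
            alphabet = [c.upper() for c in alphabet]
    if not alphabet:
        raise AlphabetError("effective alphabet is empty (all gaps?)")

    char_index = {c: k for k, c in enumerate(alphabet)}
    counts = np.zeros((aln.length, len(alphabet)))
    for seq, wt in zip(seqs, w):
        for i, ch in enumerate(seq):
            k = char_index.get(ch)
            if k is None:
                if strict and ch not in GAP_CHARS:
                    raise AlphabetError(
                        f"character {ch!r} at column {i} is outside the "
                        f"alphabet {alphabet}"
                    )
                continue
            counts[i, k] += wt

    positions = range(start_position, start_position + aln.length)
    table = PositionCharacterMatrix.from_values(
        counts, alphabet, positions, matrix_type="counts"
    )
    if to_type == "counts":
        return table
    return transform_matrix(
        table, to_type, background=background, pseudocount=pseudocount
    )


def sequence_to_matrix(
    seq: str,
    characters: Sequence[str] | None = None,
    start_position: int = 0,
) -> PositionCharacterMatrix:
    """One-hot matrix for a single sequence (matrix_type ``user``).

    Cell (i, c) is 1 where the sequence carries character ``c`` at
    position ``i``, else 0.  Useful for wild-type overlays.
    """
    seq = seq.upper()
    if characters is None:
        alphabet = sorted(set(seq))
    else:
        alphabet = [str(c).upper() for c in characters]
    char_index = {c: k for k, c in enumerate(alphabet)}
    onehot = np.zeros((len(seq), len(alphabet)))
    for i, ch in enumerate(seq):
        k = char_index.get(ch)
        if k is None:
            raise AlphabetError(
                f"character {ch!r} at position {i} is outside the alphabet "
                f"{alphabet}"
            )
        onehot[i, k] = 1.0
    positions = range(start_position, start_position + len(seq))
    return PositionCharacterMatrix.from_values(
        onehot, alphabet, positions, matrix_type="user"
    )


def saliency_to_matrix(
    track: SaliencyTrack,
    characters: Sequence[str] | None = None,
    start_position: int = 0,
) -> PositionCharacterMatrix:
    """Masked matrix: cell (i, c) = score[i] if sequence[i] == c else 0.

    Each row has at most one nonzero cell, so the rendered logo shows the
    sequence itself with character heights equal to the (possibly signed)
    importance scores.
    """
    seq = track.sequence.upper()
    if characters is None:
        alphabet = sorted(set(seq))
    else:
        alphabet = [str(c).upper() for c in characters]
    char_index = {c: k for k, c in enumerate(alphabet)}
    masked = np.zeros((len(seq), len(alphabet)))
    for i, (ch, score) in enumerate(zip(seq, track.scores)):
        k = char_index.get(ch)
        if k is None:
            raise AlphabetError(
                f"character {ch!r} at position {i} is outside the alphabet "
                f"{alphabet}"
            )
        masked[i, k] = score
    positions = range(start_position, start_position + len(seq))
    return PositionCharacterMatrix.from_values(
        masked, alphabet, positions, matrix_type="user"
    )


def infer_alphabet(characters) -> str:
    """Classify a character set as dna / rna / protein / custom.

    Only used to pick a default color scheme; ambiguity resolves in the
    order dna, rna, protein.
    """
    chars = {str(c).upper() for c in characters}
    if not chars:
        raise AlphabetError("cannot infer alphabet from an empty character set")
    if chars <= DNA_LETTERS:
        return "dna"
    if chars <= RNA_LETTERS and "U" in chars:
        return "rna"
    if chars <= PROTEIN_LETTERS:
        return "protein"
    return "custom"
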