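"""Reading and writing the matrix TSV dialect and saliency tracks.

Matrix files are plain tab-separated text: the first column is headed
``pos`` and holds integer position labels; every other column is headed by
a single character; lines starting with ``#`` are comments.  The semantic
matrix type is *not* stored in the file — the reader takes it as a
parameter.  Values are written with 12 significant digits, so
write → read → write is byte-stable.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Union

import pandas as pd

from .alignment import SaliencyTrack
from .errors import FastaFormatError, MatrixValidationError
from .matrix import PositionCharacterMatrix

PathOrStream = Union[str, Path, IO[str]]


def _as_text_stream(source: PathOrStream, mode: str = "r"):
    """(stream, needs_close) for a path or an already-open text stream."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


def read_matrix_tsv(
    source: PathOrStream, matrix_type: str = "user"
) -> PositionCharacterMatrix:
    """Read a position-by-character matrix from tab-separated text.

    ``matrix_type`` declares the semantics of the values; the usual
    validation (including probability row renormalization within 1e-4)
    runs on the result.
    """
    stream, close = _as_text_stream(source)
    try:
        try:
            df = pd.read_csv(stream, sep="\t", comment="#", dtype={0: int})
        except Exception as exc:  # pandas raises several parse error types
            raise MatrixValidationError(f"could not parse matrix TSV: {exc}") from exc
    finally:
        if close:
            stream.close()
    if df.shape[1] < 2 or df.columns[0] != "pos":
        raise MatrixValidationError(
            "matrix TSV must start with a 'pos' column followed by one "
            "column per character"
        )
    df = df.set_index("pos")
    df.index.name = None
    return PositionCharacterMatrix(df, matrix_type=matrix_type)


def write_matrix_tsv(table: PositionCharacterMatrix, target: PathOrStream) -> None:
    """Write a matrix in the TSV dialect (12 significant digits)."""
    stream, close = _as_text_stream(target, "w")
    try:
        stream.write("pos\t" + "\t".join(table.characters) + "\n")
        for pos, row in zip(table.positions, table.values):
            cells = "\t".join(f"{v:.12g}" for v in row)
            stream.write(f"{pos}\t{cells}\n")
    finally:
        if close:
            stream.close()


def matrix_to_tsv_string(table: PositionCharacterMatrix) -> str:
    buf = _io.StringIO()
    write_matrix_tsv(table, buf)
    return buf.getvalue()


def read_saliency_tsv(source: PathOrStream) -> SaliencyTrack:
    """Read a saliency track from two-column TSV (character, score).

    ``#`` comments and blank lines are ignored; row order is sequence
    order.
    """
    stream, close = _as_text_stream(source)
    try:
        chars: list[str] = []
        scores: list[float] = []
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FastaFormatError(
                    f"saliency TSV line {lineno}: expected 2 tab-separated "
                    f"fields, got {len(fields)}"
                )
            char, score = fields
            if len(char) != 1:
                raise FastaFormatError(
                    f"saliency TSV line {lineno}: first field must be a "
                    f"single character, got {char!r}"
                )
            try:
                scores.append(float(score))
            except ValueError as exc:
                raise FastaFormatError(
                    f"saliency TSV line {lineno}: bad score {score!r}"
                ) from exc
            chars.append(char)
    finally:
        if close:
            stream.close()
    if not chars:
        raise FastaFormatError("saliency TSV contains no data rows")
    return SaliencyTrack("".join(chars), scores)


def write_saliency_tsv(track: SaliencyTrack, target: PathOrStream) -> None:
    stream, close = _as_text_stream(target, "w")
    try:
        for char, score in zip(track.sequence, track.scores):
            stream.write(f"{char}\t{score:.12g}\n")
    finally:
        if close:
            stream.close()
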