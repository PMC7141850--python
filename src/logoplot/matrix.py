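"""Position-by-character matrices and the transform algebra among them.

The central data structure is :class:`PositionCharacterMatrix`: a labelled
numeric table in which rows are integer sequence positions, columns are
single characters (the alphabet) and values are character heights.  Every
logo in this package is drawn from such a matrix.  A matrix carries a
semantic ``matrix_type``:

``counts``
    Non-negative tallies of characters per alignment column.
``probability``
    Each row is a probability distribution over the alphabet (a PWM).
``weight``
    Log-odds: ``w[i,c] = log2(p[i,c] / bg[c])`` against a background.
``information``
    Heights ``h[i,c] = p[i,c] * I_i`` where ``I_i`` is the position's
    information content in bits (Kullback-Leibler divergence of the
    position distribution from the background; for a uniform background
    this equals the classic ``log2(C) - H_i`` form).
``user``
    Arbitrary signed values (binding energies, enrichment scores,
    saliency scores, ...); no invariant beyond finiteness.

Transformations route through ``probability`` as the hub type:
counts → probability → {weight, information}, and weight → probability →
information.  :func:`transform_matrix` dispatches among them.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegeneratePositionError,
    DispatchError,
    MatrixValidationError,
    NormalizationError,
    SemanticTypeError,
    TransformRangeError,
    ZeroProbabilityError,
)

MATRIX_TYPES = ("counts", "probability", "weight", "information", "user")

#: Row-sum slack accepted on *input* probability matrices (text files are
#: rounded); rows within this of 1 are silently renormalized.
ROW_SUM_INPUT_TOL = 1e-4
#: Row-sum tolerance guaranteed on *output* probability matrices.
ROW_SUM_OUTPUT_TOL = 1e-10

GAP_CHARS = frozenset("-.*")


class PositionCharacterMatrix:
    """A positions-by-characters table with a declared semantic type.

    Parameters
    ----------
    data :
        A ``pandas.DataFrame`` (index = integer position labels, columns =
        single characters) or anything ``DataFrame`` accepts.
    matrix_type :
        One of ``counts | probability | weight | information | user``.
    validate :
        Check the invariants of ``matrix_type`` on construction.

    Position labels are arbitrary integers (so genomic coordinates can be
    used) but must be strictly increasing; layout uses their rank order,
    the labels themselves are cosmetic.
    """

    def __init__(self, data, matrix_type: str = "user", validate: bool = True):
        if matrix_type not in MATRIX_TYPES:
            raise MatrixValidationError(
                f"unknown matrix_type {matrix_type!r}; expected one of {MATRIX_TYPES}"
            )
        df = pd.DataFrame(data).copy()
        df = df.astype(float)
        self._df = df
        self.matrix_type = matrix_type
        if validate:
            validate_matrix(self)

    # -- container protocol -------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        """The underlying DataFrame (positions × characters)."""
        return self._df

    @property
    def positions(self) -> list[int]:
        return [int(p) for p in self._df.index]

    @property
    def characters(self) -> list[str]:
        return [str(c) for c in self._df.columns]

    @property
    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._df.shape

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PositionCharacterMatrix)
            and self.matrix_type == other.matrix_type
            and self._df.equals(other._df)
        )

    def __repr__(self) -> str:
        n, c = self.shape
        return (
            f"<PositionCharacterMatrix {self.matrix_type!r} "
            f"{n} positions x {c} characters>"
        )

    def copy(self) -> "PositionCharacterMatrix":
        return PositionCharacterMatrix(self._df, self.matrix_type, validate=False)

    def row(self, position: int) -> pd.Series:
        return self._df.loc[position]

    @classmethod
    def from_values(
        cls,
        values,
        characters: Sequence[str],
        positions: Sequence[int] | None = None,
        matrix_type: str = "user",
    ) -> "PositionCharacterMatrix":
        """Build a matrix from an array-like of shape (n_positions, n_chars)."""
        arr = np.asarray(values, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(1, -1)
        if positions is None:
            positions = range(arr.shape[0])
        df = pd.DataFrame(arr, index=list(positions), columns=list(characters))
        return cls(df, matrix_type=matrix_type)


class Background:
    """Per-character background probabilities used by weight and
    information transforms.

    All entries must be strictly positive and sum to 1 (within 1e-8).
    """

    def __init__(self, probabilities: Mapping[str, float] | pd.Series):
        series = pd.Series(probabilities, dtype=float)
        if (series <= 0).any():
            bad = series.index[series <= 0].tolist()
            raise MatrixValidationError(
                f"background probabilities must be > 0; offending characters: {bad}"
            )
        total = float(series.sum())
        if abs(total - 1.0) > 1e-8:
            if abs(total - 1.0) <= ROW_SUM_INPUT_TOL:
                series = series / total
            else:
                raise NormalizationError(
                    f"background probabilities sum to {total:.6g}, not 1"
                )
        self.probabilities = series

    @classmethod
    def uniform(cls, characters: Iterable[str]) -> "Background":
        chars = list(characters)
        return cls(pd.Series(1.0 / len(chars), index=chars))

    def reindex(self, characters: Sequence[str]) -> pd.Series:
        """Background vector over ``characters``; error if any is missing."""
        missing = [c for c in characters if c not in self.probabilities.index]
        if missing:
            raise MatrixValidationError(
                f"background defines no probability for characters {missing}"
            )
        return self.probabilities.reindex(characters)

    def __repr__(self) -> str:
        return f"<Background over {list(self.probabilities.index)}>"


# ---------------------------------------------------------------------------
# validation


def validate_matrix(table: PositionCharacterMatrix) -> PositionCharacterMatrix:
    """Check (and where allowed, repair) the invariants of ``table``.

    * all cells finite;
    * unique position and character labels;
    * ``counts``: all values >= 0;
    * ``probability``: values in [0, 1]; rows within ``ROW_SUM_INPUT_TOL``
      of summing to 1 are renormalized in place, rows further off raise
      :class:`NormalizationError`.

    Returns the (possibly renormalized) table.
    """
    df = table.df
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise MatrixValidationError("matrix needs at least 1 position and 1 character")

    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise MatrixValidationError(f"duplicate character labels: {dups}")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise MatrixValidationError(f"duplicate position labels: {dups}")
    for c in df.columns:
        s = str(c)
        if len(s) != 1 or not s.isprintable():
            raise MatrixValidationError(
                f"character labels must be single printable characters, got {c!r}"
            )
    pos = np.asarray(df.index)
    if len(pos) > 1 and not np.all(np.diff(pos) > 0):
        raise MatrixValidationError("position labels must be strictly increasing")

    arr = df.to_numpy()
    if not np.all(np.isfinite(arr)):
        i, j = np.argwhere(~np.isfinite(arr))[0]
        raise MatrixValidationError(
            f"non-finite value at position {df.index[i]}, character {df.columns[j]!r}"
        )

    mt = table.matrix_type
    if mt == "counts":
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise MatrixValidationError(
                f"counts must be >= 0; negative value at position "
                f"{df.index[i]}, character {df.columns[j]!r}"
            )
    elif mt == "probability":
        if (arr < 0).any() or (arr > 1).any():
            bad = (arr < 0) | (arr > 1)
            i, j = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"probabilities must lie in [0, 1]; offending cell at position "
                f"{df.index[i]}, character {df.columns[j]!r}"
            )
        sums = arr.sum(axis=1)
        off = np.abs(sums - 1.0)
        if (off > ROW_SUM_INPUT_TOL).any():
            i = int(np.argmax(off))
            raise NormalizationError(
                f"probability row at position {df.index[i]} sums to "
                f"{sums[i]:.6g}, more than {ROW_SUM_INPUT_TOL} from 1"
            )
        if (off > 0).any():
            table._df = df.div(sums, axis=0)
    elif mt == "information":
        # heights may only be negative under a non-uniform background;
        # finiteness (checked above) is the sole hard invariant here
        pass
    return table


# ---------------------------------------------------------------------------
# transforms


def _require_type(table: PositionCharacterMatrix, expected: str, op: str) -> None:
    if table.matrix_type != expected:
        raise SemanticTypeError(
            f"{op} expects a {expected!r} matrix, got {table.matrix_type!r}"
        )


def counts_to_probability(
    counts: PositionCharacterMatrix, pseudocount: float = 1.0
) -> PositionCharacterMatrix:
    """Laplace-smoothed column frequencies.

    ``p[i,c] = (n[i,c] + pseudocount) / sum_c' (n[i,c'] + pseudocount)``.

    A pseudocount of 0 with an all-zero row raises
    :class:`DegeneratePositionError` (no distribution is defined there).
    """
    _require_type(counts, "counts", "counts_to_probability")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    df = counts.df + pseudocount
    sums = df.sum(axis=1)
    if (sums <= 0).any():
        bad = df.index[sums <= 0].tolist()
        raise DegeneratePositionError(
            f"all-zero counts with pseudocount 0 at positions {bad}; "
            "supply a pseudocount > 0"
        )
    prob = df.div(sums, axis=0)
    return PositionCharacterMatrix(prob, "probability", validate=False)


def probability_to_weight(
    prob: PositionCharacterMatrix, background: Background | None = None
) -> PositionCharacterMatrix:
    """Log-odds weights ``w[i,c] = log2(p[i,c] / bg[c])``.

    Zero probabilities are an error (their log-odds is -inf, which cannot
    be stacked in a logo); apply a pseudocount upstream instead.
    """
    _require_type(prob, "probability", "probability_to_weight")
    validate_matrix(prob)
    bg = _background_vector(prob, background)
    arr = prob.values
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ZeroProbabilityError(
            f"zero probability at position {prob.df.index[i]}, character "
            f"{prob.df.columns[j]!r}: log-odds would be -inf; rebuild the "
            "probability matrix with a pseudocount > 0"
        )
    w = np.log2(arr / bg.to_numpy()[None, :])
    out = pd.DataFrame(w, index=prob.df.index, columns=prob.df.columns)
    return PositionCharacterMatrix(out, "weight", validate=False)


def weight_to_probability(
    weight: PositionCharacterMatrix, background: Background | None = None
) -> PositionCharacterMatrix:
    """Invert :func:`probability_to_weight`: ``p[i,c] ∝ bg[c] * 2**w[i,c]``.

    Exact inverse up to a per-position additive constant in the weights
    (the per-row normalization absorbs it).
    """
    _require_type(weight, "weight", "weight_to_probability")
    bg = _background_vector(weight, background)
    arr = weight.values
    if (np.abs(arr) > 1000).any():
        i, j = np.argwhere(np.abs(arr) > 1000)[0]
        raise TransformRangeError(
            f"|weight| > 1000 at position {weight.df.index[i]}, character "
            f"{weight.df.columns[j]!r}: 2**w overflows"
        )
    unnorm = bg.to_numpy()[None, :] * np.exp2(arr)
    prob = unnorm / unnorm.sum(axis=1, keepdims=True)
    out = pd.DataFrame(prob, index=weight.df.index, columns=weight.df.columns)
    return PositionCharacterMatrix(out, "probability", validate=False)


def probability_to_information(
    prob: PositionCharacterMatrix,
    background: Background | None = None,
    n_sequences: int | None = None,
) -> PositionCharacterMatrix:
    """Information logo heights ``h[i,c] = p[i,c] * I_i``.

    ``I_i = sum_c p[i,c] * log2(p[i,c] / bg[c])`` with the convention
    ``0 * log2(0/bg) = 0``: the Kullback-Leibler divergence of the
    position distribution from the background, in bits.  With a uniform
    background this reduces to the familiar ``log2(C) - H_i``.

    ``n_sequences`` optionally applies the small-sample correction
    ``e(n) = (C - 1) / (2 ln 2 * n)``, subtracted from each ``I_i`` and
    floored at 0.  Off by default: logos built from arbitrary matrices
    have no sample size.
    """
    _require_type(prob, "probability", "probability_to_information")
    validate_matrix(prob)
    bg = _background_vector(prob, background)
    p = prob.values
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / bg.to_numpy()[None, :])
    terms = np.where(p == 0, 0.0, terms)
    info = terms.sum(axis=1)
    if n_sequences is not None:
        if n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        c = prob.shape[1]
        info = np.maximum(info - (c - 1) / (2.0 * math.log(2.0) * n_sequences), 0.0)
    heights = p * info[:, None]
    out = pd.DataFrame(heights, index=prob.df.index, columns=prob.df.columns)
    return PositionCharacterMatrix(out, "information", validate=False)


def center_matrix(table: PositionCharacterMatrix) -> PositionCharacterMatrix:
    """Subtract each row's mean, making every row mean-zero.

    Used for energy/enrichment logos so the stack straddles the baseline.
    Only meaningful for ``weight`` and ``user`` matrices; centering a
    counts or probability matrix would destroy its invariants.
    """
    if table.matrix_type not in ("weight", "user"):
        raise SemanticTypeError(
            f"center_matrix applies to weight or user matrices, not "
            f"{table.matrix_type!r}"
        )
    df = table.df.sub(table.df.mean(axis=1), axis=0)
    return PositionCharacterMatrix(df, table.matrix_type, validate=False)


_SUPPORTED = {
    ("counts", "counts"),
    ("counts", "probability"),
    ("counts", "weight"),
    ("counts", "information"),
    ("probability", "probability"),
    ("probability", "weight"),
    ("probability", "information"),
    ("weight", "weight"),
    ("weight", "probability"),
    ("weight", "information"),
}


def transform_matrix(
    table: PositionCharacterMatrix,
    to_type: str,
    background: Background | None = None,
    pseudocount: float | None = None,
    center: bool = False,
    from_type: str | None = None,
    n_sequences: int | None = None,
) -> PositionCharacterMatrix:
    """Convert ``table`` to ``to_type``, routing through probability.

    ``from_type``, if given, must match ``table.matrix_type`` (a guard for
    callers reading matrices from files, where the type is declared rather
    than stored).  ``pseudocount`` defaults to 1.0 when the source is a
    counts matrix and is ignored otherwise.  ``center`` applies
    :func:`center_matrix` last, and only for weight output.
    """
    if from_type is not None and from_type != table.matrix_type:
        raise DispatchError(
            f"declared from_type {from_type!r} does not match the matrix's "
            f"type {table.matrix_type!r}"
        )
    src = table.matrix_type
    pair = (src, to_type)
    if pair not in _SUPPORTED:
        supported = sorted(f"{a}->{b}" for a, b in _SUPPORTED if a != b)
        raise DispatchError(
            f"conversion {src} -> {to_type} is not supported; supported: "
            + ", ".join(supported)
        )
    if center and to_type != "weight":
        raise SemanticTypeError("center=True is only valid for weight output")

    if src == to_type:
        return validate_matrix(table.copy())

    # hub: get a probability matrix
    if src == "counts":
        pc = 1.0 if pseudocount is None else pseudocount
        prob = counts_to_probability(table, pseudocount=pc)
    elif src == "probability":
        prob = table
    elif src == "weight":
        prob = weight_to_probability(table, background)

    if to_type == "probability":
        out = prob if prob is not table else validate_matrix(table.copy())
    elif to_type == "weight":
        out = probability_to_weight(prob, background)
        if center:
            out = center_matrix(out)
    elif to_type == "information":
        out = probability_to_information(prob, background, n_sequences=n_sequences)
    return out


def _background_vector(
    table: PositionCharacterMatrix, background: Background | None
) -> pd.Series:
    if background is None:
        background = Background.uniform(table.characters)
    return background.reindex(table.characters)
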