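"""Stack layout: from per-position values to glyph rectangles.

Positive values stack upward from the baseline (y = 0), negative values
stack downward; a value of zero produces no glyph.  The stack order,
padding, flipping and shading rules live in :class:`LogoStyle`; the
geometry itself is computed by :func:`layout_position` and collected per
matrix into a :class:`LogoLayout`, which tests and callers can inspect
without touching any drawing backend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .colors import get_color_scheme, shade_color
from .errors import LayoutError
from .glyphs import DEFAULT_FONT, RGBA, GlyphSpec

STACK_ORDERS = ("big_on_top", "small_on_top", "fixed")


@dataclass
class LogoStyle:
    """Styling knobs for a whole logo.

    stack_order
        ``big_on_top`` (default): within a stack, glyphs are ordered by
        ascending magnitude from the baseline, so the largest-magnitude
        glyph sits farthest from the axis; ties break alphabetically.
        ``small_on_top`` is the exact reverse; ``fixed`` keeps alphabet
        order regardless of values.
    flip_below
        Draw below-baseline glyphs upside down.  ``None`` (default)
        means: on when the matrix contains negative values, off
        otherwise.
    fade_probabilities
        Map each glyph's opacity to its probability value (identity,
        alpha = p).  Only valid for probability matrices.
    shade_below
        Multiply the RGB of below-baseline glyphs by (1 - shade_below).
    vpad
        Fraction of each glyph's slot height shaved symmetrically off
        its top and bottom (vpad/2 each end).
    width
        Glyph width as a fraction of the unit position slot; the glyph
        is centered on the integer position.
    vsep
        Absolute vertical gap carved at interior stack boundaries
        (vsep/2 from each neighbour); stack ends at the baseline and the
        outer extremity are untouched.
    color_scheme
        Scheme name or explicit char→color mapping; ``None`` picks a
        default from the inferred alphabet (classic for DNA/RNA,
        chemistry for protein, gray otherwise).
    highlights
        List of ``(start_pos, end_pos, color, alpha)`` ranges drawn as
        rectangles behind the glyphs.
    """

    stack_order: str = "big_on_top"
    flip_below: bool | None = None
    fade_probabilities: bool = False
    shade_below: float = 0.0
    vpad: float = 0.0
    vsep: float = 0.0
    width: float = 0.96
    color_scheme: object = None
    font_name: str = DEFAULT_FONT
    highlights: list = field(default_factory=list)
    baseline_width: float = 0.5
    edge_width: float = 0.0

    def __post_init__(self) -> None:
        if self.stack_order not in STACK_ORDERS:
            raise LayoutError(
                f"stack_order must be one of {STACK_ORDERS}, got "
                f"{self.stack_order!r}"
            )
        if not (0.0 <= self.shade_below <= 1.0):
            raise LayoutError("shade_below must lie in [0, 1]")
        if not (0.0 <= self.vpad < 1.0):
            raise LayoutError("vpad must lie in [0, 1)")
        if not (0.0 < self.width <= 1.0):
            raise LayoutError("width must lie in (0, 1]")
        if self.vsep < 0:
            raise LayoutError("vsep must be >= 0")


@dataclass
class HighlightSpec:
    """A rectangle behind the glyphs spanning an inclusive position range."""

    start_pos: int
    end_pos: int
    color: RGBA
    alpha: float = 1.0

    @property
    def xmin(self) -> float:
        return self.start_pos - 0.5

    @property
    def xmax(self) -> float:
        return self.end_pos + 0.5


def _ordered_items(
    items: list[tuple[str, float]], stack_order: str, fixed_order: Sequence[str]
) -> list[tuple[str, float]]:
    """Order stack entries from the baseline outward."""
    if stack_order == "fixed":
        rank = {c: k for k, c in enumerate(fixed_order)}
        return sorted(items, key=lambda cv: rank[cv[0]])
    ascending = sorted(items, key=lambda cv: (abs(cv[1]), cv[0]))
    if stack_order == "big_on_top":
        return ascending
    return ascending[::-1]


def layout_position(
    values: Mapping[str, float],
    position: int,
    style: LogoStyle | None = None,
    colors: Mapping[str, RGBA] | None = None,
    alphas: Mapping[str, float] | None = None,
) -> list[GlyphSpec]:
    """Stack one position's values into glyph rectangles.

    Positive values fill ``[0, sum of positives]`` cumulatively in stack
    order; negatives fill ``[-sum of |negatives|, 0]`` downward with the
    same ordering rule mirrored.  vsep carves a fixed gap at interior
    stack boundaries; vpad then shaves ``vpad * span / 2`` off both ends
    of each glyph.  Glyphs whose interval collapses under the shrinking
    are dropped.  Below-baseline glyphs are flipped (per
    ``style.flip_below``) and shaded by ``style.shade_below``.
    """
    style = style or LogoStyle()
    for c, v in values.items():
        if not math.isfinite(v):
            raise LayoutError(
                f"non-finite value {v!r} for character {c!r} at position {position}"
            )
    if colors is None:
        colors = get_color_scheme(
            style.color_scheme if style.color_scheme is not None else "gray",
            list(values),
        )
    alphas = alphas or {}
    fixed_order = list(values)

    positives = [(c, v) for c, v in values.items() if v > 0]
    negatives = [(c, v) for c, v in values.items() if v < 0]
    flip_below = True if style.flip_below is None else style.flip_below

    glyphs: list[GlyphSpec] = []

    def emit(items, sign: int) -> None:
        ordered = _ordered_items(items, style.stack_order, fixed_order)
        edge = 0.0
        n = len(ordered)
        for k, (c, v) in enumerate(ordered):
            span = abs(v)
            lo, hi = (edge, edge + span) if sign > 0 else (-edge - span, -edge)
            edge += span
            # interior boundaries: the baseline-side end of every glyph
            # but the first, the outer end of every glyph but the last
            inner_base = k > 0
            inner_outer = k < n - 1
            shave = style.vpad * span / 2.0
            if sign > 0:
                lo += shave + (style.vsep / 2.0 if inner_base else 0.0)
                hi -= shave + (style.vsep / 2.0 if inner_outer else 0.0)
            else:
                hi -= shave + (style.vsep / 2.0 if inner_base else 0.0)
                lo += shave + (style.vsep / 2.0 if inner_outer else 0.0)
            if hi <= lo:
                continue
            color = colors.get(c, (0.5, 0.5, 0.5, 1.0))
            alpha = alphas.get(c)
            if alpha is not None:
                r, g, b, a = color
                color = (r, g, b, a * min(max(alpha, 0.0), 1.0))
            flip = False
            if sign < 0:
                flip = flip_below
                color = shade_color(color, style.shade_below)
            glyphs.append(
                GlyphSpec(
                    character=c,
                    x_center=float(position),
                    floor=lo,
                    ceiling=hi,
                    width=style.width,
                    color=color,
                    flip=flip,
                    font_name=style.font_name,
                    edge_width=style.edge_width,
                )
            )

    emit(positives, +1)
    emit(negatives, -1)
    return glyphs


@dataclass
class LogoLayout:
    """The laid-out logo: glyph specs, decorations and axis extents.

    ``glyphs`` maps ``(position, character)`` to its :class:`GlyphSpec`.
    ``patches`` holds the matplotlib artists when the layout has been
    drawn (empty for pure-geometry layouts) and is excluded from
    equality; :meth:`snapshot` gives a plain-tuple form for exact
    comparisons.
    """

    glyphs: dict[tuple[int, str], GlyphSpec] = field(default_factory=dict)
    highlights: list[HighlightSpec] = field(default_factory=list)
    position_labels: tuple = ()
    xlim: tuple[float, float] = (0.0, 1.0)
    ylim: tuple[float, float] = (0.0, 1.0)
    baseline_width: float = 0.5
    patches: dict = field(default_factory=dict, compare=False, repr=False)
    ax: object = field(default=None, compare=False, repr=False)

    def glyphs_at(self, position: int) -> list[GlyphSpec]:
        return [g for (p, _), g in self.glyphs.items() if p == position]

    @property
    def positions(self) -> list[int]:
        return sorted({p for p, _ in self.glyphs})

    def snapshot(self) -> tuple:
        """Hashable, order-independent full description of the layout."""
        glyph_part = tuple(
            (
                p,
                c,
                g.x_center,
                g.floor,
                g.ceiling,
                g.width,
                g.color,
                g.flip,
                g.font_name,
                g.edge_width,
            )
            for (p, c), g in sorted(self.glyphs.items())
        )
        hl_part = tuple(
            (h.start_pos, h.end_pos, h.color, h.alpha) for h in self.highlights
        )
        return (glyph_part, hl_part, self.xlim, self.ylim, self.baseline_width)
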