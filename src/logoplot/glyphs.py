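"""Vector glyph geometry: character outlines and box-to-box affine maps.

A glyph is one character drawn as a scalable vector outline, stretched
anisotropically so its tight bounding box lands exactly on a target
rectangle.  Outlines come from matplotlib's text-path machinery;
matplotlib bundles the DejaVu fonts, so the default font ("DejaVu Sans")
gives identical geometry on every machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from matplotlib.font_manager import FontProperties
from matplotlib.path import Path as MplPath
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D, Bbox

from .errors import GlyphError, LayoutError

DEFAULT_FONT = "DejaVu Sans"

RGBA = tuple[float, float, float, float]


@dataclass
class GlyphSpec:
    """One character's geometry and style within a logo.

    The glyph occupies the axis-aligned rectangle
    ``[x_center - width/2, x_center + width/2] x [floor, ceiling]``.
    """

    character: str
    x_center: float
    floor: float
    ceiling: float
    width: float
    color: RGBA = (0.0, 0.0, 0.0, 1.0)
    flip: bool = False
    font_name: str = DEFAULT_FONT
    edge_width: float = 0.0
    edge_color: RGBA = (0.0, 0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.ceiling > self.floor):
            raise LayoutError(
                f"glyph {self.character!r}: ceiling ({self.ceiling}) must "
                f"exceed floor ({self.floor})"
            )
        if not (self.width > 0):
            raise LayoutError(f"glyph {self.character!r}: width must be > 0")
        if not (0.0 <= self.color[3] <= 1.0):
            raise LayoutError(f"glyph {self.character!r}: alpha outside [0, 1]")

    @property
    def target_bbox(self) -> Bbox:
        return Bbox.from_extents(
            self.x_center - self.width / 2.0,
            self.floor,
            self.x_center + self.width / 2.0,
            self.ceiling,
        )

    @property
    def height(self) -> float:
        return self.ceiling - self.floor

    def with_style(self, **overrides) -> "GlyphSpec":
        """Copy with style fields replaced; geometry fields are rejected."""
        allowed = {"color", "flip", "font_name", "edge_width", "edge_color"}
        bad = set(overrides) - allowed
        if bad:
            raise ValueError(f"not style fields: {sorted(bad)}")
        return replace(self, **overrides)


@lru_cache(maxsize=512)
def _raw_char_path(character: str, font_name: str) -> MplPath:
    prop = FontProperties(family=[font_name, DEFAULT_FONT])
    return TextPath((0, 0), character, size=1, prop=prop)


def char_path(character: str, font_name: str = DEFAULT_FONT) -> MplPath:
    """The vector outline of ``character`` in font units.

    Raises :class:`GlyphError` for characters with no drawable outline
    (whitespace and the like).
    """
    if len(character) != 1:
        raise GlyphError(f"expected a single character, got {character!r}")
    try:
        path = _raw_char_path(character, font_name)
    except Exception as exc:  # matplotlib chokes on glyphless characters
        raise GlyphError(
            f"character {character!r} has no drawable outline in font "
            f"{font_name!r}: {exc}"
        ) from exc
    bbox = path.get_extents()
    if bbox.width <= 0 or bbox.height <= 0:
        raise GlyphError(
            f"character {character!r} has a degenerate outline "
            f"(width={bbox.width}, height={bbox.height}) in font {font_name!r}"
        )
    return path


def compute_glyph_transform(
    native_bbox: Bbox | tuple[float, float, float, float],
    target_bbox: Bbox | tuple[float, float, float, float],
    flip: bool = False,
) -> Affine2D:
    """Affine map sending ``native_bbox`` exactly onto ``target_bbox``.

    Independent x and y scaling plus translation; with ``flip``, an
    additional y-negation about the target box's center (the outline is
    drawn upside down but still fills the same rectangle).
    """
    native = Bbox.from_extents(*native_bbox) if not isinstance(native_bbox, Bbox) else native_bbox
    target = Bbox.from_extents(*target_bbox) if not isinstance(target_bbox, Bbox) else target_bbox
    if native.width <= 0 or native.height <= 0:
        raise GlyphError(
            f"degenerate native bounding box (w={native.width}, h={native.height})"
        )
    if target.width <= 0 or target.height <= 0:
        raise GlyphError(
            f"degenerate target bounding box (w={target.width}, h={target.height})"
        )
    t = Affine2D()
    t.translate(-native.x0, -native.y0)
    t.scale(target.width / native.width, target.height / native.height)
    t.translate(target.x0, target.y0)
    if flip:
        cy = 0.5 * (target.y0 + target.y1)
        t += Affine2D().translate(0, -cy).scale(1, -1).translate(0, cy)
    return t


def glyph_path(spec: GlyphSpec) -> MplPath:
    """The fully transformed outline of a glyph, in data coordinates."""
    raw = char_path(spec.character, spec.font_name)
    transform = compute_glyph_transform(
        raw.get_extents(), spec.target_bbox, flip=spec.flip
    )
    return transform.transform_path(raw)
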