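"""Built-in glyph color schemes.

A scheme maps each alphabet character to an RGBA tuple.  Characters a
scheme does not cover fall back to a neutral gray, so any scheme is total
over any alphabet.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from matplotlib.colors import to_rgba

from .errors import ColorSchemeError

#: Fallback for characters a scheme does not define.
NEUTRAL_GRAY = (0.5, 0.5, 0.5, 1.0)

# classic nucleotide colors: A green, C blue, G orange, T/U red
_CLASSIC = {
    "A": "#008000",
    "C": "#0000cc",
    "G": "#ffa500",
    "T": "#cc0000",
    "U": "#cc0000",
}

# amino acids grouped by side-chain chemistry
_CHEMISTRY = {
    # polar (green)
    **{c: "#109648" for c in "GSTYC"},
    # neutral amides (purple)
    **{c: "#8f1d9c" for c in "QN"},
    # basic (blue)
    **{c: "#255c99" for c in "KRH"},
    # acidic (red)
    **{c: "#d62839" for c in "DE"},
    # hydrophobic (black)
    **{c: "#221f20" for c in "AVLIPWFM"},
}

# Kyte-Doolittle-style three-way hydrophobicity grouping
_HYDROPHOBICITY = {
    # hydrophilic (blue)
    **{c: "#1f77b4" for c in "RKDENQ"},
    # neutral (green)
    **{c: "#2ca02c" for c in "SGHTAP"},
    # hydrophobic (black)
    **{c: "#221f20" for c in "YVMCLFIW"},
}

_GRAY = "#404040"


def _build(mapping: Mapping[str, str], alphabet: Sequence[str]):
    return {
        c: to_rgba(mapping[c]) if c in mapping else NEUTRAL_GRAY for c in alphabet
    }


SCHEME_NAMES = ("classic", "gray", "chemistry", "hydrophobicity")


def get_color_scheme(
    scheme: str | Mapping[str, object], alphabet: Sequence[str]
) -> dict[str, tuple[float, float, float, float]]:
    """Resolve a scheme name or explicit char→color mapping over ``alphabet``.

    Returns a total map character → RGBA.  Explicit mappings may use any
    matplotlib color specification; characters missing from an explicit
    map get :data:`NEUTRAL_GRAY`.
    """
    alphabet = [str(c) for c in alphabet]
    if isinstance(scheme, Mapping):
        return {
            c: to_rgba(scheme[c]) if c in scheme else NEUTRAL_GRAY for c in alphabet
        }
    if scheme == "classic":
        return _build(_CLASSIC, alphabet)
    if scheme == "gray":
        return {c: to_rgba(_GRAY) for c in alphabet}
    if scheme == "chemistry":
        return _build(_CHEMISTRY, alphabet)
    if scheme == "hydrophobicity":
        return _build(_HYDROPHOBICITY, alphabet)
    raise ColorSchemeError(
        f"unknown color scheme {scheme!r}; available: {', '.join(SCHEME_NAMES)} "
        "or an explicit character->color mapping"
    )


def default_scheme_for(alphabet_kind: str) -> str:
    """Default scheme name given an inferred alphabet kind."""
    if alphabet_kind in ("dna", "rna"):
        return "classic"
    if alphabet_kind == "protein":
        return "chemistry"
    return "gray"


def shade_color(rgba, shade: float):
    """Darken an RGBA color: multiply RGB by (1 - shade), keep alpha."""
    r, g, b, a = rgba
    f = 1.0 - shade
    return (r * f, g * f, b * f, a)
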