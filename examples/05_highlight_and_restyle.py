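"""Highlighting a subsequence and restyling a single glyph.

Highlights mark functional elements behind the stack; per-glyph
restyling (e.g. coloring the wild-type character orange) customizes a
rendered logo without recomputing its geometry.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from logoplot import (
    highlight_interval,
    make_random_matrix,
    render_logo,
    style_single_glyph,
)

info = make_random_matrix("information", n_positions=10, seed=11)
fig, ax = plt.subplots(figsize=(6, 2.5))
layout = render_logo(info, ax=ax)

h = highlight_interval(layout, 2, 4, color="gold", alpha=0.3)
print(f"highlight covers x in [{h.xmin}, {h.xmax}] "
      "(closed position interval 2..4)")

pos, char = next(iter(sorted(layout.glyphs)))
before = layout.glyphs[(pos, char)]
style_single_glyph(layout, pos, char, color="orange")
after = layout.glyphs[(pos, char)]
print(f"restyled glyph {char!r} at position {pos}: color {after.color}, "
      f"geometry unchanged: {(before.floor, before.ceiling) == (after.floor, after.ceiling)}")
fig.savefig("highlighted_logo.svg")
print("-> highlighted_logo.svg")
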