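"""Energy-style logo: signed values stacked above and below the baseline.

Binding-energy or enrichment matrices hold signed contributions; after
per-position mean-centering, favourable characters rise above zero and
unfavourable ones hang below, drawn flipped and darkened.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from logoplot import LogoStyle, center_matrix, make_random_matrix, render_logo

energy = make_random_matrix("user", n_positions=10, seed=7)
energy = center_matrix(energy)
print("row means after centering:",
      " ".join(f"{m:+.1e}" for m in energy.values.mean(axis=1)))
# all zero: each position's stack is balanced around the baseline

style = LogoStyle(flip_below=True, shade_below=0.3, color_scheme="classic")
fig, ax = plt.subplots(figsize=(6, 2.5))
layout = render_logo(energy, style, ax=ax)
below = sum(1 for g in layout.glyphs.values() if g.ceiling <= 0)
print(f"{len(layout.glyphs)} glyphs, {below} below the baseline (flipped)")
fig.savefig("energy_logo.svg")
print("-> energy_logo.svg")
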