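"""Probability logo with value-specific transparency.

In a faded probability logo each glyph's opacity equals its probability:
near-certain characters are solid, rare ones fade out.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from logoplot import LogoStyle, make_random_matrix, render_logo

prob = make_random_matrix("probability", n_positions=8, seed=3)
style = LogoStyle(fade_probabilities=True, stack_order="big_on_top")

fig, ax = plt.subplots(figsize=(5, 2.5))
layout = render_logo(prob, style, ax=ax)
g = layout.glyphs[(0, "A")]
print(f"position 0, character A: p = {prob.df.loc[0, 'A']:.3f}, "
      f"glyph alpha = {g.color[3]:.3f}")
# alpha equals the probability (identity fade)
fig.savefig("faded_probability_logo.svg")
print("-> faded_probability_logo.svg")
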