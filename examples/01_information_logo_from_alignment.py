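"""Information logo from a multiple-sequence alignment.

Simulates a small DNA motif alignment, tallies it into a counts matrix,
converts to information heights (bits) and renders the logo.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from logoplot import (
    MotifModel,
    alignment_to_matrix,
    make_random_matrix,
    render_logo,
    simulate_alignment,
)

# a random 8-position PWM and 200 sequences drawn from it
pwm = make_random_matrix("probability", n_positions=8, seed=42)
alignment = simulate_alignment(MotifModel(pwm, n_sequences=200, seed=1))
print(f"alignment: {alignment.n_sequences} sequences x {alignment.length} columns")

info = alignment_to_matrix(alignment, to_type="information", pseudocount=1.0)
per_position = info.values.sum(axis=1)
print("information per position (bits):",
      " ".join(f"{b:.3f}" for b in per_position))
# each number is that column's deviation from a uniform background, in
# bits; 0 = uninformative, 2 = perfectly conserved DNA position

fig, ax = plt.subplots(figsize=(5, 2.5))
layout = render_logo(info, ax=ax)
ax.set_ylabel("bits")
fig.savefig("information_logo.svg")
print(f"drew {len(layout.glyphs)} glyphs -> information_logo.svg")
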