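"""Masked (saliency) logo: one character per position, height = score.

Importance scores — e.g. neural-network attributions along a genomic
window — attach to the observed sequence; the resulting matrix has at
most one nonzero cell per row.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from logoplot import SaliencyTrack, render_logo, saliency_to_matrix

rng = np.random.default_rng(5)
sequence = "ACGTGGTACCAT"
scores = rng.normal(scale=0.5, size=len(sequence))
track = SaliencyTrack(sequence, scores)

masked = saliency_to_matrix(track, "ACGT")
print("score sum:", f"{scores.sum():.4f}",
      "| matrix cell sum:", f"{masked.values.sum():.4f}")
print("max nonzero cells per row:", int((masked.values != 0).sum(axis=1).max()))
# the matrix conserves the scores exactly, one cell per position

fig, ax = plt.subplots(figsize=(6, 2.0))
render_logo(masked, ax=ax)
fig.savefig("saliency_logo.svg")
print("-> saliency_logo.svg")
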