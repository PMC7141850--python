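# logoplot

Publication-quality sequence logos in Python, rendered as matplotlib
vector graphics.

Sequence logos stack characters at integer positions, with each
character's height encoding a quantitative property — column statistics
of a multiple-sequence alignment, log-odds scores, binding-energy
contributions, neural-network importance scores. `logoplot` is for
computational biologists who want such logos as first-class matplotlib
objects: drawn into any `Axes`, styled programmatically, and dropped
into multi-panel figures.

## The model

Everything is a **position-by-character matrix**: rows are positions,
columns are alphabet characters, values are heights. Matrices carry a
semantic type connected by a small algebra (probability is the hub):

- **counts → probability** (Laplace smoothing with pseudocount λ):
  `p_ic = (n_ic + λ) / Σ_c' (n_ic' + λ)`
- **probability ↔ weight** (log-odds against a background `b`):
  `w_ic = log2(p_ic / b_c)`, inverted by `p_ic ∝ b_c · 2^{w_ic}`
- **probability → information** (heights in bits):
  `I_i = Σ_c p_ic · log2(p_ic / b_c)` and `h_ic = p_ic · I_i`,
  which for a uniform background is the classic `log2 C − H_i` form;
  an optional small-sample correction `e(n) = (C−1)/(2 ln2 · n)` can be
  subtracted from `I_i` (floored at 0).
- **user** matrices hold arbitrary signed values (energies, enrichments,
  saliency scores) and render with stacks above and below the baseline.

Rendering converts each matrix cell into a glyph: the character's font
outline, anisotropically stretched so its bounding box lands exactly on
its slot in the stack. Styling covers color schemes (classic DNA/RNA,
protein chemistry/hydrophobicity, grayscale, custom maps), fonts,
vertical padding, probability-proportional transparency, highlighting of
position ranges, flipping/shading of below-baseline glyphs, and
per-glyph overrides.

## Worked example

```python
from logoplot import (MotifModel, alignment_to_matrix, make_random_matrix,
                      render_logo, simulate_alignment)

pwm = make_random_matrix("probability", n_positions=8, seed=42)
alignment = simulate_alignment(MotifModel(pwm, n_sequences=200, seed=1))
info = alignment_to_matrix(alignment, to_type="information", pseudocount=1.0)
print(" ".join(f"{b:.3f}" for b in info.values.sum(axis=1)))
layout = render_logo(info)
```

prints

```
0.198 0.408 0.661 0.434 0.323 0.275 0.311 0.322
```

— the information content of each alignment column in bits: 0 would be
an uninformative (background-like) column, 2 a perfectly conserved DNA
position. The returned `layout` lists every drawn glyph's rectangle and
style, so figures are scriptable and testable. The `examples/` directory
holds one short script per capability (information logos, signed energy
logos, faded probability logos, masked saliency logos, highlighting and
per-glyph restyling).

## Command line

```bash
logoplot --input alignment.fa --kind fasta --to-type information --output logo.svg
logoplot --input energy.tsv --from-type user --center --output logo.pdf
logoplot --input scores.tsv --kind saliency --output logo.png
```

Inputs are FASTA alignments, tab-separated matrices (`pos` column plus
one column per character) or two-column saliency tracks; output is
SVG/PDF/PNG. SVG output is byte-deterministic for fixed inputs and
flags.

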