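# Methods

## The matrix model

A logo is drawn from a position-by-character matrix: ordered integer
position labels (strictly increasing, arbitrary start so genomic
coordinates can serve as labels; layout uses rank order, labels are
cosmetic), an ordered alphabet of single printable characters, and one
finite real value per cell. The declared `matrix_type` fixes the
invariants enforced at validation:

- `counts`: all values ≥ 0 (zero columns are legal);
- `probability`: values in [0, 1], rows summing to 1 — rows within
  1e-4 of 1 are silently renormalized (absorbing text-file rounding),
  rows further off are an error; internally produced probability rows
  are exact to 1e-10;
- `information`: finite heights (non-negativity holds for uniform
  backgrounds but not in general, so it is not enforced);
- `weight`, `user`: finiteness only.

## Transform algebra

Probability is the hub type: counts → probability → {weight,
information} and weight → probability → information. The individual
steps:

- **Counts → probability.** Laplace smoothing,
  `p_ic = (n_ic + λ) / Σ(n_ic' + λ)`. The default pseudocount is
  λ = 1 when converting alignment counts (the conventional default);
  an all-zero row with λ = 0 is a hard error rather than NaN.
- **Probability → weight.** `w_ic = log2(p_ic / b_c)`. A zero
  probability raises an error directing the caller to a pseudocount:
  −∞ cells cannot be stacked or rendered, so there is no silent −∞
  path.
- **Weight → probability.** `p_ic ∝ b_c · 2^{w_ic}`, normalized per
  row; exact inverse of the forward map up to a per-position additive
  constant, which the normalization absorbs. |w| > 1000 is rejected
  before exponentiation overflows.
- **Probability → information.** Per-position
  `I_i = Σ_c p_ic log2(p_ic / b_c)` with `0·log 0 ≡ 0`, heights
  `h_ic = p_ic · I_i`. This Kullback–Leibler form was chosen because it
  covers non-uniform backgrounds with one formula and reduces exactly
  to `log2 C − H_i` when the background is uniform. The small-sample
  correction `e(n) = (C−1)/(2 ln2 · n)` is available through the
  `n_sequences` argument (subtracted from `I_i`, floored at 0) and off
  by default: logos built from arbitrary matrices carry no sample size,
  so applying it silently would be wrong more often than right.
- **Centering.** Row-mean subtraction, restricted to `weight` and
  `user` matrices (it would corrupt counts or probabilities); used for
  energy/enrichment logos so stacks straddle the baseline. Idempotent
  and invariant under per-row constant shifts.

The default background is uniform over the matrix's alphabet; any
strictly positive distribution summing to 1 (within 1e-8) may be
supplied. Post-condition tolerances are 1e-10 (row sums, round trips)
internally versus 1e-4 on input acceptance.

## Sequence inputs

Alignments are read with Biopython and must be rectangular; ragged
input names the offending records. Tallying uppercases by default
(`case_sensitive` disables), excludes the gap/stop characters `-`, `.`,
`*` and anything outside the chosen alphabet (matching common logo
practice; `strict=True` turns non-gap out-of-alphabet characters into
errors, gaps never error). Column totals may therefore differ across
positions. The default alphabet is the sorted set of observed non-gap
characters; a user-supplied order wins. Sequences are uniformly
weighted; a per-record weight vector is exposed for e.g. usage-weighted
probability logos. Alphabet classification (dna / rna / protein /
custom) only selects a default color scheme and resolves ambiguous sets
in that order — `{A,C,G,T,N}` classifies as protein since N is
asparagine.

Single sequences become one-hot `user` matrices; saliency tracks become
masked `user` matrices with exactly one potentially nonzero cell per
row (cell = that position's score), so cell sums equal score sums by
construction.

## Glyph geometry

Character outlines come from matplotlib's text-path machinery.
Matplotlib bundles the DejaVu fonts, so the default "DejaVu Sans"
yields identical outlines on every machine; unknown font names fall
back to it. A glyph is placed by the affine map (independent x/y
scaling plus translation, plus y-negation about the target box center
when flipped) that sends the outline's tight bounding box exactly onto
its target rectangle; corner mapping is exact to well below the 1e-6
relative tolerance asserted in tests. Characters without a drawable
outline (spaces) are an error.

Stacking: positive values fill `[0, Σ positives]` cumulatively, negative
values mirror downward. The default `big_on_top` order sorts by
ascending magnitude from the baseline (largest glyph farthest from the
axis, the dominant convention in published logos), ties alphabetical;
`small_on_top` is its exact reverse; `fixed` keeps alphabet order.
Padding semantics: `vsep` carves an absolute gap of `vsep/2` from each
side of interior stack boundaries only (baseline and outer ends are
untouched, so unpadded stack extents equal the value sums exactly);
`vpad` then shaves `vpad·span/2` off both ends of each glyph's slot.
Glyphs whose interval collapses to nothing under this shrinking are
dropped rather than drawn with inverted extent. Zero values produce no
glyph. Position `i` owns the x-interval `[i−0.5, i+0.5]`; glyphs
default to 0.96 of that slot, centered.

Below-baseline glyphs flip by default only when the matrix contains
negative values (`flip_below=None` means auto) and can be darkened by
`shade_below` (RGB × (1−shade)). Probability fading maps opacity to the
probability identically (alpha = p, clipped); a rescaled variant was
considered and rejected as less interpretable — alpha 1 means certainty.

## Rendering

`render_logo` draws onto a caller-supplied Axes (or a fresh one),
touching nothing else in the figure, so logos compose into multi-panel
layouts. Z-order is highlights < baseline < glyphs. Axis extents:
x spans first−0.5 to last+0.5; y spans the full stack range with a 5%
margin. Highlights are closed position intervals. The returned
`LogoLayout` records every glyph rectangle, color and flag plus the
decorations, and `snapshot()` gives an exactly comparable tuple —
geometry tests run on layouts, never on pixels. Per-glyph restyling
swaps style fields (color, alpha, flip, font, edge) while geometry is
frozen.

SVG/PDF/PNG export goes through matplotlib. The CLI pins the SVG hash
salt and strips the embedded timestamp, making SVG output
byte-deterministic for fixed input and flags.

## Synthetic data

The generator draws alignment columns independently from a stated PWM
(no phylogenetic correlation, no indel process, no column coupling), so
parameter-recovery tests measure pure multinomial sampling error:
passing them shows the tally/transform chain is unbiased, not that real
alignments are this clean. Random matrices are type-correct by
construction — probability rows are Dirichlet(1,…,1) clipped away from
exact zeros and renormalized, counts are integers in [0, 20], signed
matrices standard normal. A single explicitly seeded numpy generator
drives everything; no global random state.

Problem sizes in the test suite and acceptance script — 1000 random
matrices for round-trip checks, 200 alignments of up to 50×30 for the
tally oracle, 10,000 sequences for PWM recovery, 1000 style/matrix
draws for geometry — were chosen so the whole suite runs in seconds
while leaving the statistical bounds (e.g. max cell error < 0.02 at
n = 10,000, about five binomial standard errors) comfortably slack.

## Known limitations

- No motif scanning, p-values, or MEME/TRANSFAC/JASPAR parsers; inputs
  are the TSV dialect, FASTA and saliency TSV.
- Inputs must be pre-aligned; there is no MSA construction.
- Glyphs are font characters only; no arbitrary images, animation or
  HTML output.
- PNG output is rasterized by matplotlib and not guaranteed
  byte-deterministic across library versions; determinism guarantees
  apply to SVG.
- Energy-matrix sign conventions are the caller's: `user` matrices
  render values as given.
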