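# Methods

## Problem setting

Post-operative CT of tibial fractures is read twice: once to delineate
bone (segmentation), once to grade the reduction (imaging score). The
package automates the first step with a seeded graph cut whose seeds are
derived from a histogram threshold instead of manual painting, and
mechanises the second as an explicit, testable scoring function.

All computation is 2-D, on single-channel 8-bit slices or top-view
projections (`L = 256` gray levels by default; inputs with intensities at
or above `L` are rejected rather than clipped so the histogram
probabilities stay exact). Pixels are indexed row-major from the top-left.

## Histogram thresholding

For a histogram `p_i = n_i / n`, a threshold `t` splits the levels into
`C0 = {0..t}` (background) and `C1 = {t+1..L-1}` (foreground; bone is the
bright phase in CT, invertible via a flag). Class probabilities, means,
variances and entropies are the usual per-class moments of the normalised
distributions.

Two selectors are provided because the choice between them is a genuine
degree of freedom of the method; both are exposed in the API and CLI:

- **Maximum entropy**: maximise `f(t) = H0 + H1`.
- **Minimum classification error**: minimise
  `J(t) = 1 + w0 log(s0²/w0²) + w1 log(s1²/w1²)`, the standard
  two-Gaussian minimum-error criterion. The additive constant is kept for
  transparency; it never moves the argmin.

Numerical conventions, fixed globally:

- natural logarithms everywhere (the base rescales objectives, never
  changes `t*`);
- `0 · log 0 ≡ 0` in entropies;
- candidate thresholds range over `{min nonzero level … max nonzero
  level − 1}` so both classes are always non-empty; a histogram with mass
  on fewer than two levels raises an explicit no-valid-threshold error;
- empty-class statistics are NaN, never silently zero;
- ties in the arg-extremum break to the smallest `t` (deterministic
  output; note that a histogram with a zero-count gap between its modes
  makes every threshold inside the gap an exact tie — they all induce the
  same segmentation — so `t*` is then the gap's left edge);
- class moments are accumulated in exact integer arithmetic (counts,
  `Σ i·n_i`, `Σ i²·n_i`), so a point-mass class has variance exactly
  zero and is excluded from `J(t)` reliably; zero-variance candidates are
  excluded rather than floored to avoid spurious minima. Exactness holds
  for any image below ~10⁷ pixels, far beyond a CT slice.

## Seed generation and the graph cut

Markers derive from the selected threshold with an uncertainty band of
half-width `seed_band` (default 10 gray levels): intensity
`> t* + band` → foreground seed, `≤ t* − band` → background seed, the
rest unlabeled. If either seed class is empty the band halves repeatedly
(finally 0) until both are populated; a single-level image is reported as
ill-posed. The band exists so that pixels near the threshold — exactly
the ones thresholding misclassifies under noise — are decided by the cut
rather than the histogram.

The cut minimises the standard two-terminal energy

    E(labels) = λ Σ_p R_p(label_p) + Σ_{(p,q)∈N} B(p,q) [label_p ≠ label_q]

- `R_p(FG) = −log P_fg(I_p)` with `P_fg` the foreground-seed intensity
  histogram smoothed by a pseudocount (default 1) over all `L` levels, so
  region costs are always finite; `R_p(BG)` analogously.
- `B(p,q) = exp(−(I_p−I_q)²/(2σ²)) / dist(p,q)`, `dist = 1` for
   4-neighbours and `√2` for diagonals; connectivity defaults to 8.
- `σ` defaults to the median absolute 4-neighbour intensity difference of
  the image (robust, data-driven; floored at 1 for constant images).
- `λ = 1` by default; `λ = 0` with `seed_band = 0` reduces the pipeline
  exactly to plain thresholding (every pixel is then a hard seed).

Seeds are hard constraints. Their terminal capacity is `1 +` the pixel's
total incident boundary weight — large enough that flipping a seed can
never pay, while keeping capacities small (this matters below).

Two min-cut backends produce the same cut:

- a bundled augmenting-path (Dinic) solver with exact float capacities,
  used by the enumeration oracle tests;
- `scipy.sparse.csgraph.maximum_flow` for speed. scipy needs integer
  capacities, so floats are scaled (up to 2²⁰) and rounded; the scale is
  capped so the **total** quantised capacity stays below 2³¹, because
  scipy's solver overflows silently beyond int32 range — this was
  observed directly, as returned flows that still admitted augmenting
  paths. The foreground is the source side of the residual graph.

## Evaluation

`Dice(M, N) = 2|M∩N| / (|M|+|N|)` over foreground pixel sets: 1 iff the
sets coincide, 0 iff disjoint. Two empty masks are an undefined 0/0 and
raise, rather than picking an arbitrary convention. Artifact counts make
the qualitative "holes and isolated points" comparison quantitative:
holes are 4-connected background components not touching the border,
isolated points are 8-connected foreground components below `min_size`
(default 5 px) — the dual-connectivity pairing that avoids topological
paradoxes. Timing is a monotonic wall clock, reported but never asserted:
it varies across machines, results do not.

## Imaging score

Three displacement categories score {6, 4, 2, 0} points each
(total 18): collapse bands `0 / (0,5] / (5,10] / >10` mm, broadening
`0 / (0,5) / [5,10] / >10` mm, angulation `0 / (0,10) / [10,20] / >20`
degrees. The printed tables leave some boundary values ambiguous (the
collapse 4-point band is printed as a bare "5 mm", and nothing covers
5–6 mm); the closures above assign every real measurement to a band,
sending boundary values to the lower-scoring band (conservative) except
collapse 5 mm, which stays in its printed band. Grades: 18 excellent,
12–17 good, 6–11 common, 0–5 bad.

Damage area and comminution add {6, 4, 2, 0} each (total 30): damage
confined to the intercondylar eminence — or absent, which the table has
no explicit row for and which is treated as the best band — scores 6,
1–2 / 3 / 4 damaged articular areas score 4 / 2 / 0. Only the four
weight-bearing areas count; eminence involvement alone never lowers the
damage points (the alternative reading, counting it as a fifth area, is
not supported by the 4-area maximum). Fragments: 0 / 1 / 2 / ≥3 →
6 / 4 / 2 / 0, where 0 fragments means the fracture line passes only
through the eminence and is therefore inconsistent with recorded
articular damage (validated). Total grades: 28–30 excellent, 20–27 good,
10–19 common, 0–9 bad. All sub-scores are even, so odd totals such as 19
are unreachable in practice; the grade map still covers them.

The five-area division of a plateau top view uses centroid-anchored
axis-aligned lines: a central vertical band of half-width
`eminence_halfwidth_frac × image width` (default 0.15) is the eminence,
the rest splits at the centroid column (lateral drawn left / medial
right) and centroid row (anterior up / posterior down). A radiologist
places these lines on anatomy; that placement is not recoverable from a
binary mask, so the geometry is parameterised and documented rather than
inferred. Fragment counting from images is likewise out of scope —
`fragment_count` is an input read off the reconstruction.

## Phantoms

The generator realises the same model the minimum-error selector assumes:
each phase Gaussian in intensity. Defaults — 96×96 canvas, bone mean 200,
soft tissue mean 60, both SD 5 — give a 28 SD mode separation, i.e. the
high-contrast regime of bone CT. Shapes: disk, annulus, ellipse,
rectangle; fracture lines are carved through the bone, take background
intensity and are excluded from the truth mask. Optional global Gaussian
noise or salt-and-pepper corruption (for the hole-suppression
comparison). One `numpy` Generator per case, seeded from the spec;
intensities clip to [0, 255] and round half-to-even, so cases are
bit-reproducible across platforms. Plateau phantoms route a compact
damage stroke through the interior of each requested region, taking the
region geometry from the scoring module's own division, so the
damaged-region ground truth is exact by construction.

What the phantoms do **not** emulate: anatomical bone texture, partial
volume effects, beam hardening and scanner artifacts, or 3-D context.
Passing the end-to-end suites therefore demonstrates correctness of the
algorithms under their own model assumptions, not clinical accuracy on
patient CT.

## Problem sizes and test design

Unit and property suites run on histograms up to 256 levels and images
up to 128×128; the enumeration oracle for the cut runs on images up to
3×4 pixels (all `2^free` labelings enumerated); end-to-end recovery uses
20 seeded 64×64 phantoms and asserts Dice ≥ 0.95 per seed. The
hole-suppression claim is tested as a paired comparison over 20
salt-and-pepper phantoms: strictly fewer enclosed holes in total for the
cut than for thresholding at the same `t*`, and no worse on ≥ 95% of
cases. These sizes keep the whole suite under a minute while leaving the
statistics stable across seeds.

## Known limitations

- 2-D only; no DICOM/NIfTI, no 3-D graphs, no multiplanar context.
- Binary labels only; no multi-label cuts or GrabCut-style iterative
  region re-estimation.
- The scipy backend quantises capacities; cut values agree with the exact
  bundled solver to the quantisation step (the labeling has always been
  identical in testing, but exact ties could in principle resolve
  differently between backends).
- The scoring tables' band closures at fractional boundaries are a
  documented design choice where the printed tables are ambiguous.
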