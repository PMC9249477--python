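# tibiacut

Seeded graph-cut segmentation of bone CT slices with **automatically
generated threshold markers**, Dice-based evaluation, and the
tibial-plateau fracture **imaging score** used to grade reduction quality
after surgery.

Classic interactive graph cuts require a user to paint foreground and
background seeds on every slice. For high-contrast bone CT that manual
step can be replaced by a histogram threshold: pixels well above the
threshold seed the bone phase, pixels well below seed the soft-tissue
phase, and only the uncertain band in between is left to the cut. This
package implements that pipeline for radiologists' workflows and for
method development on synthetic phantoms:

- **Thresholding** — two selectors on the gray-level histogram
  `p_i = n_i / n`:
  - *maximum entropy*: `t* = argmax_t [H0(t) + H1(t)]`, the Shannon
    entropies of the two normalised classes `C0 = {0..t}`,
    `C1 = {t+1..L-1}`;
  - *minimum error*: `t* = argmin_t [1 + w0 log(s0²/w0²) + w1 log(s1²/w1²)]`,
    the two-Gaussian minimum-classification-error criterion with class
    probabilities `w`, means `m` and variances `s²`.
- **Graph cut** — the two-terminal energy
  `E = λ Σ_p R_p(label_p) + Σ_{(p,q)} B(p,q) [label_p ≠ label_q]` with
  region costs from smoothed seed-intensity histograms and the
  contrast-sensitive boundary term
  `B(p,q) = exp(−(I_p−I_q)²/2σ²)/dist(p,q)`, solved as a minimum s–t cut
  (bundled Dinic solver, or scipy's max-flow for speed).
- **Evaluation** — Dice similarity coefficient
  `Dice(M, N) = 2|M∩N| / (|M|+|N|)`, wall-clock timing, and counts of
  the holes / isolated specks that pure thresholding leaves in noisy CT.
- **Scoring** — the Rasmussen-style 18-point displacement score
  (collapse, broadening, angulation), the five-area division of the
  plateau top view (intercondylar eminence + four weight-bearing
  quadrants), damage-area and comminution points, the 30-point total and
  its excellent/good/common/bad grades.
- **Phantoms** — deterministic synthetic CT-like slices and plateau top
  views with exact ground truth, so everything above is testable without
  patient data.

## Worked example

```python
import tibiacut as tc

# a synthetic CT-like slice: bright disk (mean 200) on dark background
# (mean 60), both SD 5, plus a known ground-truth mask
case = tc.generate_slice(tc.PhantomSpec(rng_seed=3))

res = tc.segment_auto(case.image, method="max_entropy")
print("t*:", res.report.t_star)
print("dice:", round(tc.dice(case.truth_mask, res.mask), 5))
```

prints

```
t*: 68
dice: 0.99985
```

The selected threshold `t* = 68` sits just above the soft-tissue mode;
seeds are generated from the ±10 gray-level band around it, and the cut
recovers the disk almost perfectly (Dice 0.99985 against the generator's
ground truth; Dice 1 would be pixel-identical masks).

The same pipeline from the shell:

```sh
tibiacut phantom --seed 3 --out-dir case/
tibiacut segment case/image.png out.png --method max-entropy --report report.json
tibiacut evaluate case/truth.png out.png
tibiacut score --measurements measurements.json --out score.json
```

where `measurements.json` holds a clinical record such as

```json
{"collapse_mm": 0, "broadening_mm": 0, "angulation_deg": 0,
 "damaged_regions": ["intercondylar"], "fragment_count": 0}
```

(that perfect record scores 30/30, grade *excellent*).

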