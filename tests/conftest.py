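"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities with plain Python
loops (or exhaustive enumeration) so they share no code path with the
vectorised implementations they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from tibiacut.image import GrayHistogram


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def hist_from_probs(probs) -> GrayHistogram:
    """Build a GrayHistogram from exact rational probabilities via counts."""
    probs = np.asarray(probs, dtype=np.float64)
    scale = 10_000
    counts = np.rint(probs * scale).astype(np.int64)
    assert counts.sum() == scale, "probabilities must be multiples of 1e-4"
    return GrayHistogram(counts=counts, probabilities=counts / scale, total=scale)


def hist_from_counts(counts) -> GrayHistogram:
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    return GrayHistogram(counts=counts, probabilities=counts / total, total=total)


# ---------------------------------------------------------------------------
# loop-based oracles for class statistics and both threshold objectives.
# Class moments use exact rational arithmetic so degenerate cases (point-
# mass classes, exact zero variance) are detected without float noise.


def oracle_class_stats(counts, t):
    """Direct summation of class probability, mean, variance, entropy.

    ``w0/w1/m0/m1/s0sq/s1sq`` come back as Fractions (or None when the
    class is empty); entropies are floats.
    """
    from fractions import Fraction

    counts = [int(c) for c in counts]
    n = sum(counts)
    L = len(counts)
    p = [Fraction(c, n) for c in counts]
    w0 = sum(p[: t + 1], Fraction(0))
    w1 = sum(p[t + 1 :], Fraction(0))
    out = {"w0": w0, "w1": w1, "m0": None, "m1": None,
           "s0sq": None, "s1sq": None, "H0": None, "H1": None}
    if w0 > 0:
        m0 = sum((i * p[i] for i in range(t + 1)), Fraction(0)) / w0
        out["m0"] = m0
        out["s0sq"] = sum((p[i] * (i - m0) ** 2 for i in range(t + 1)), Fraction(0)) / w0
        out["H0"] = -sum(
            float(p[i] / w0) * math.log(p[i] / w0) for i in range(t + 1) if p[i] > 0
        )
    if w1 > 0:
        m1 = sum((i * p[i] for i in range(t + 1, L)), Fraction(0)) / w1
        out["m1"] = m1
        out["s1sq"] = (
            sum((p[i] * (i - m1) ** 2 for i in range(t + 1, L)), Fraction(0)) / w1
        )
        out["H1"] = -sum(
            float(p[i] / w1) * math.log(p[i] / w1) for i in range(t + 1, L) if p[i] > 0
        )
    return out


def oracle_entropy_objective(counts, t):
    st = oracle_class_stats(counts, t)
    if st["w0"] == 0 or st["w1"] == 0:
        return None
    return st["H0"] + st["H1"]


def oracle_min_error_objective(counts, t):
    st = oracle_class_stats(counts, t)
    if st["w0"] == 0 or st["w1"] == 0:
        return None
    if st["s0sq"] == 0 or st["s1sq"] == 0:
        return None
    return (
        1.0
        + float(st["w0"]) * math.log(float(st["s0sq"]) / float(st["w0"]) ** 2)
        + float(st["w1"]) * math.log(float(st["s1sq"]) / float(st["w1"]) ** 2)
    )


def oracle_scan(counts, objective, minimize=False):
    """Exhaustive scan over every t in 0..L-2; smallest-t tie break."""
    best_t, best_v = None, None
    for t in range(len(counts) - 1):
        v = objective(counts, t)
        if v is None:
            continue
        if best_v is None or (v < best_v if minimize else v > best_v):
            best_t, best_v = t, v
    return best_t, best_v


# ---------------------------------------------------------------------------
# brute-force seeded graph-cut energy oracle


def oracle_energy(pixels, labels, seed_labels, lam, sigma, connectivity, pseudocount, L):
    """Energy of a labeling, everything recomputed with explicit loops."""
    h, w = pixels.shape
    # seed intensity models
    probs = {}
    for which, tag in ((1, "fg"), (2, "bg")):
        vals = [pixels[r, c] for r in range(h) for c in range(w)
                if seed_labels[r, c] == which]
        counts = [0] * L
        for v in vals:
            counts[v] += 1
        denom = len(vals) + pseudocount * L
        probs[tag] = [(counts[i] + pseudocount) / denom for i in range(L)]
    region = 0.0
    for r in range(h):
        for c in range(w):
            tag = "fg" if labels[r, c] else "bg"
            region += -math.log(probs[tag][pixels[r, c]])
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if connectivity == 8:
        offsets += [(1, 1, math.sqrt(2)), (1, -1, math.sqrt(2))]
    boundary = 0.0
    for r in range(h):
        for c in range(w):
            for dr, dc, dist in offsets:
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and labels[r, c] != labels[r2, c2]:
                    d = float(pixels[r, c]) - float(pixels[r2, c2])
                    boundary += math.exp(-d * d / (2 * sigma * sigma)) / dist
    return lam * region + boundary


def oracle_min_energy(pixels, seed_labels, lam, sigma, connectivity, pseudocount, L):
    """Exhaustive enumeration over all labelings consistent with the seeds."""
    h, w = pixels.shape
    free = [(r, c) for r in range(h) for c in range(w) if seed_labels[r, c] == 0]
    base = np.zeros((h, w), dtype=bool)
    base[seed_labels == 1] = True
    best = math.inf
    for bits in itertools.product([False, True], repeat=len(free)):
        lab = base.copy()
        for (r, c), b in zip(free, bits):
            lab[r, c] = b
        e = oracle_energy(pixels, lab, seed_labels, lam, sigma, connectivity,
                          pseudocount, L)
        best = min(best, e)
    return best


# ---------------------------------------------------------------------------
# flood-fill oracle for artifact counts


def oracle_artifact_counts(fg, min_size):
    """Hole and isolated-point counts via BFS flood fill."""
    h, w = fg.shape

    def components(mask, neighbors):
        seen = np.zeros_like(mask, dtype=bool)
        comps = []
        for r in range(h):
            for c in range(w):
                if mask[r, c] and not seen[r, c]:
                    stack, comp = [(r, c)], []
                    seen[r, c] = True
                    while stack:
                        y, x = stack.pop()
                        comp.append((y, x))
                        for dy, dx in neighbors:
                            y2, x2 = y + dy, x + dx
                            if 0 <= y2 < h and 0 <= x2 < w and mask[y2, x2] and not seen[y2, x2]:
                                seen[y2, x2] = True
                                stack.append((y2, x2))
                    comps.append(comp)
        return comps

    four = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    eight = four + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    holes = sum(
        1
        for comp in components(~fg, four)
        if all(0 < y < h - 1 and 0 < x < w - 1 for y, x in comp)
    )
    isolated = sum(1 for comp in components(fg, eight) if len(comp) < min_size)
    return holes, isolated
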