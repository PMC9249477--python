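"""Seeded graph-cut segmentation with automatic threshold markers.

The classic interactive graph-cut formulation labels each pixel foreground
(FG) or background (BG) by solving a minimum s-t cut whose terminal links
encode region likelihood and whose neighbour links penalise label changes
across similar intensities:

``E(labels) = lambda * sum_p R_p(label_p)
            + sum_{(p,q) in N} B(p,q) * [label_p != label_q]``

with ``R_p(FG) = -log P_fg(I_p)`` from a smoothed intensity histogram of
the FG seed pixels (``R_p(BG)`` analogously) and the contrast term
``B(p,q) = exp(-(I_p - I_q)^2 / (2 sigma^2)) / dist(p, q)``.

Instead of user-drawn seeds, markers are generated automatically from a
histogram threshold ``t*``: intensities above ``t* + seed_band`` become FG
seeds, intensities at or below ``t* - seed_band`` become BG seeds, and the
uncertainty band in between stays unlabeled for the cut to decide.  Bone
is the bright phase in CT, so foreground is the above-threshold class
(invertible with ``invert=True`` for bright-background data).

Seeds are enforced as hard constraints through effectively infinite
terminal capacities; the output therefore never flips a seed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import IllPosedSeedsError, ValidationError
from .image import GrayImage, compute_histogram
from .maxflow import DinicSolver, scipy_min_cut
from .thresholding import ThresholdScan, max_entropy_threshold, min_error_threshold

__all__ = [
    "FOREGROUND_SEED",
    "BACKGROUND_SEED",
    "UNLABELED",
    "SeedMask",
    "SegmentationMask",
    "GraphCutParams",
    "RunReport",
    "SegmentationResult",
    "estimate_sigma",
    "generate_markers",
    "seed_region_costs",
    "labeling_energy",
    "segment",
    "segment_auto",
    "threshold_segment",
]

UNLABELED = 0
FOREGROUND_SEED = 1
BACKGROUND_SEED = 2

Backend = Literal["scipy", "bundled"]


@dataclass(frozen=True)
class SeedMask:
    """Tri-state marker map: FG seed, BG seed or unlabeled, per pixel."""

    labels: np.ndarray  # int8 grid of {UNLABELED, FOREGROUND_SEED, BACKGROUND_SEED}
    band_used: float = 0.0  # seed band half-width after any auto-shrink

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int8)
        if lab.ndim != 2:
            raise ValidationError("seed mask must be a 2-D grid")
        if not np.isin(lab, (UNLABELED, FOREGROUND_SEED, BACKGROUND_SEED)).all():
            raise ValidationError("seed labels must be in {UNLABELED, FG, BG}")
        if not (lab == FOREGROUND_SEED).any() or not (lab == BACKGROUND_SEED).any():
            raise IllPosedSeedsError(
                "seed mask needs at least one foreground and one background seed"
            )
        object.__setattr__(self, "labels", lab)

    @property
    def n_foreground(self) -> int:
        return int((self.labels == FOREGROUND_SEED).sum())

    @property
    def n_background(self) -> int:
        return int((self.labels == BACKGROUND_SEED).sum())


@dataclass(frozen=True)
class SegmentationMask:
    """Binary per-pixel labeling; True = foreground."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=bool)
        if lab.ndim != 2:
            raise ValidationError("segmentation mask must be a 2-D grid")
        object.__setattr__(self, "labels", lab)

    @property
    def n_foreground(self) -> int:
        return int(self.labels.sum())


@dataclass(frozen=True)
class GraphCutParams:
    """Tunable parameters of the seeded cut.

    lam
        Weight of the region (terminal) term; 0 disables it.
    sigma
        Contrast scale of the boundary term in gray levels; ``None`` means
        estimate it from the image as the median absolute 4-neighbour
        intensity difference (falling back to 1.0 on constant images).
    connectivity
        Pixel neighbourhood, 4 or 8; diagonal links are weighted 1/sqrt(2).
    seed_band
        Half-width (gray levels) of the unlabeled uncertainty band around
        the threshold during marker generation.
    hist_smoothing
        Additive pseudocount for the seed intensity histograms; must be
        positive so region costs stay finite.
    """

    lam: float = 1.0
    sigma: float | None = None
    connectivity: int = 8
    seed_band: float = 10.0
    hist_smoothing: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if self.sigma is not None and self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if self.seed_band < 0:
            raise ValidationError("seed_band must be >= 0")
        if self.hist_smoothing <= 0:
            raise ValidationError("hist_smoothing pseudocount must be > 0")


@dataclass(frozen=True)
class RunReport:
    """Provenance record of one automatic segmentation run."""

    method: str
    t_star: int
    objective: float
    seed_band_used: float
    n_fg_seeds: int
    n_bg_seeds: int
    energy: float
    elapsed_s: float
    sigma: float
    lam: float
    connectivity: int


@dataclass(frozen=True)
class SegmentationResult:
    mask: SegmentationMask
    seeds: SeedMask
    scan: ThresholdScan
    report: RunReport


def estimate_sigma(image: GrayImage) -> float:
    """Median absolute 4-neighbour intensity difference, floored at 1.0."""
    px = image.pixels.astype(np.float64)
    diffs = np.concatenate(
        [np.abs(np.diff(px, axis=0)).ravel(), np.abs(np.diff(px, axis=1)).ravel()]
    )
    if diffs.size == 0:
        return 1.0
    med = float(np.median(diffs))
    return med if med > 0 else 1.0


def generate_markers(
    image: GrayImage,
    scan: ThresholdScan | int,
    params: GraphCutParams = GraphCutParams(),
    invert: bool = False,
) -> SeedMask:
    """Turn a selected threshold into an automatic FG/BG seed mask.

    Pixels brighter than ``t* + seed_band`` seed the foreground, pixels at
    or below ``t* - seed_band`` the background; the rest stay unlabeled.
    If either seed class comes out empty the band is halved repeatedly
    (and finally set to 0) until both classes are populated; a single-level
    image, where that never happens, raises :class:`IllPosedSeedsError`.
    """
    t_star = scan.t_star if isinstance(scan, ThresholdScan) else int(scan)
    px = image.pixels
    band = float(params.seed_band)
    while True:
        bright = px > t_star + band
        dark = px <= t_star - band
        fg, bg = (dark, bright) if invert else (bright, dark)
        if fg.any() and bg.any():
            break
        if band == 0.0:
            raise IllPosedSeedsError(
                f"cannot seed both classes at t*={t_star}: image has no "
                "intensity on one side of the threshold"
            )
        band = band / 2.0 if band >= 0.5 else 0.0
    labels = np.full(px.shape, UNLABELED, dtype=np.int8)
    labels[fg] = FOREGROUND_SEED
    labels[bg] = BACKGROUND_SEED
    return SeedMask(labels=labels, band_used=band)


def seed_region_costs(
    image: GrayImage, seeds: SeedMask, params: GraphCutParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-level region costs ``R(FG)``, ``R(BG)`` from seed histograms.

    Each seed class defines a smoothed intensity distribution
    ``P(i) = (count_i + a) / (n_seeds + a L)`` with pseudocount
    ``a = hist_smoothing``; the cost of a level is its negative log
    likelihood.  Returns two length-``L`` arrays indexed by gray level.
    """
    L = image.levels
    a = params.hist_smoothing
    px = image.pixels
    costs = []
    for which in (FOREGROUND_SEED, BACKGROUND_SEED):
        vals = px[seeds.labels == which]
        counts = np.bincount(vals.ravel(), minlength=L).astype(np.float64)
        probs = (counts + a) / (vals.size + a * L)
        costs.append(-np.log(probs))
    return costs[0], costs[1]


def _neighbor_arcs(image: GrayImage, params: GraphCutParams, sigma: float):
    """Undirected n-link arcs (p, q, weight) as flat index arrays."""
    px = image.pixels.astype(np.float64)
    h, w = px.shape
    idx = np.arange(h * w).reshape(h, w)
    offsets = [((0, 1), 1.0), ((1, 0), 1.0)]
    if params.connectivity == 8:
        offsets += [((1, 1), np.sqrt(2.0)), ((1, -1), np.sqrt(2.0))]
    ps, qs, ws = [], [], []
    for (dy, dx), dist in offsets:
        ys = slice(max(0, -dy), h - max(0, dy))
        xs = slice(max(0, -dx), w - max(0, dx))
        ys2 = slice(max(0, dy), h - max(0, -dy))
        xs2 = slice(max(0, dx), w - max(0, -dx))
        p = idx[ys, xs].ravel()
        q = idx[ys2, xs2].ravel()
        d = px.ravel()[p] - px.ravel()[q]
        b = np.exp(-(d**2) / (2.0 * sigma**2)) / dist
        ps.append(p)
        qs.append(q)
        ws.append(b)
    return np.concatenate(ps), np.concatenate(qs), np.concatenate(ws)


def labeling_energy(
    image: GrayImage,
    labels: np.ndarray,
    seeds: SeedMask,
    params: GraphCutParams,
    sigma: float | None = None,
) -> float:
    """Energy of an arbitrary binary labeling under the cut's own model.

    Region costs are rebuilt from ``seeds`` exactly as :func:`segment`
    does, and summed over every pixel (seed pixels contribute the constant
    cost of their forced label).  Used by the enumeration oracle tests and
    recorded in run reports.
    """
    sig = estimate_sigma(image) if sigma is None else sigma
    lab = np.asarray(labels, dtype=bool)
    r_fg, r_bg = seed_region_costs(image, seeds, params)
    flat = image.pixels.ravel()
    region = np.where(lab.ravel(), r_fg[flat], r_bg[flat]).sum()
    p, q, w = _neighbor_arcs(image, params, sig)
    boundary = w[lab.ravel()[p] != lab.ravel()[q]].sum()
    return float(params.lam * region + boundary)


def segment(
    image: GrayImage,
    seeds: SeedMask,
    params: GraphCutParams = GraphCutParams(),
    backend: Backend = "scipy",
) -> SegmentationMask:
    """Minimum-cut binary segmentation honouring the given seeds.

    The labeling minimises the seeded graph-cut energy over the pixel
    graph; FG/BG seeds are hard constraints (infinite-capacity terminal
    links) and are provably preserved in the output.
    """
    if seeds.labels.shape != image.pixels.shape:
        raise ValidationError("seed mask dimensions must match the image")
    sigma = params.sigma if params.sigma is not None else estimate_sigma(image)
    h, w = image.pixels.shape
    n_px = h * w
    source, sink = n_px, n_px + 1

    r_fg, r_bg = seed_region_costs(image, seeds, params)
    flat = image.pixels.ravel()
    seed_flat = seeds.labels.ravel()
    free = seed_flat == UNLABELED
    # pixel on source side => foreground => pays its sink link = lam * R(FG)
    cap_src = np.where(free, params.lam * r_bg[flat], 0.0)
    cap_snk = np.where(free, params.lam * r_fg[flat], 0.0)

    p, q, b = _neighbor_arcs(image, params, sigma)

    # hard constraints: a seed's terminal link exceeds everything the cut
    # could save by flipping it (1 + the pixel's total boundary weight),
    # the usual effectively-infinite capacity that keeps magnitudes small
    incident = np.zeros(n_px)
    np.add.at(incident, p, b)
    np.add.at(incident, q, b)
    k_cap = incident + 1.0
    is_fg = seed_flat == FOREGROUND_SEED
    is_bg = seed_flat == BACKGROUND_SEED
    cap_src[is_fg] = k_cap[is_fg]
    cap_snk[is_bg] = k_cap[is_bg]

    if backend == "bundled":
        solver = DinicSolver(n_px + 2)
        for i in range(n_px):
            if cap_src[i] > 0:
                solver.add_edge(source, i, cap_src[i])
            if cap_snk[i] > 0:
                solver.add_edge(i, sink, cap_snk[i])
        for pi, qi, bi in zip(p, q, b):
            solver.add_edge(int(pi), int(qi), float(bi), float(bi))
        solver.max_flow(source, sink)
        side = solver.source_side(source)
    elif backend == "scipy":
        px_idx = np.arange(n_px)
        rows = np.concatenate([np.full(n_px, source), px_idx, p, q])
        cols = np.concatenate([px_idx, np.full(n_px, sink), q, p])
        caps = np.concatenate([cap_src, cap_snk, b, b])
        _, side = scipy_min_cut(n_px + 2, rows, cols, caps, source, sink)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    fg = side[:n_px].reshape(h, w)
    if (fg[seeds.labels == BACKGROUND_SEED]).any() or (
        ~fg[seeds.labels == FOREGROUND_SEED]
    ).any():
        raise AssertionError("internal error: a hard seed constraint was violated")
    return SegmentationMask(labels=fg)


def segment_auto(
    image: GrayImage,
    method: Literal["max_entropy", "min_error"] = "max_entropy",
    params: GraphCutParams = GraphCutParams(),
    backend: Backend = "scipy",
    invert: bool = False,
) -> SegmentationResult:
    """Fully automatic pipeline: histogram -> threshold -> seeds -> cut.

    Replaces the manual marker-drawing step of interactive graph cuts by
    threshold-derived seeds.  Returns the mask together with the threshold
    scan, the seed mask and a :class:`RunReport` (threshold, seed counts,
    final energy, wall-clock time).
    """
    t0 = time.perf_counter()
    hist = compute_histogram(image)
    selector = {"max_entropy": max_entropy_threshold, "min_error": min_error_threshold}
    try:
        scan = selector[method](hist)
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None
    seeds = generate_markers(image, scan, params, invert=invert)
    mask = segment(image, seeds, params, backend=backend)
    elapsed = time.perf_counter() - t0
    sigma = params.sigma if params.sigma is not None else estimate_sigma(image)
    energy = labeling_energy(image, mask.labels, seeds, params, sigma=sigma)
    report = RunReport(
        method=method,
        t_star=scan.t_star,
        objective=scan.objective_at_star,
        seed_band_used=seeds.band_used,
        n_fg_seeds=seeds.n_foreground,
        n_bg_seeds=seeds.n_background,
        energy=energy,
        elapsed_s=elapsed,
        sigma=sigma,
        lam=params.lam,
        connectivity=params.connectivity,
    )
    return SegmentationResult(mask=mask, seeds=seeds, scan=scan, report=report)


def threshold_segment(image: GrayImage, t: int, invert: bool = False) -> SegmentationMask:
    """Plain thresholding baseline: foreground = intensities above ``t``."""
    fg = image.pixels > t
    return SegmentationMask(labels=~fg if invert else fg)
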