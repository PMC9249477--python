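"""Synthetic CT-like phantoms with exact ground truth.

No public fracture-CT dataset backs this package, so every pipeline stage
is exercised on generated phantoms: a bright bone-like shape (disk,
annulus, ellipse or rectangle) on a dark soft-tissue background, each
phase drawn from its own Gaussian intensity distribution — the same
two-Gaussian model the minimum-error threshold selector assumes — with
optional fracture lines carved through the bone and optional global
Gaussian or salt-and-pepper noise.

Every phantom is fully reproducible from its integer ``rng_seed`` (one
``numpy`` Generator per case, no global state).  Intensities are clipped
to [0, 255] and rounded half-to-even so fixtures are platform-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_footprint

from .errors import ValidationError
from .graphcut import SegmentationMask
from .image import GrayImage, save_gray_image, save_mask
from .scoring import Region, RegionLabelMap, divide_plateau

__all__ = ["PhantomSpec", "PhantomCase", "generate_slice", "generate_plateau", "write_case"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one synthetic slice.

    Defaults model a high-contrast bone CT slice: cortical-bright
    foreground (mean 200) on soft-tissue background (mean 60), both with
    SD 5 gray levels, i.e. a mode separation of 28 SDs.
    """

    width: int = 96
    height: int = 96
    bone_shape: str = "disk"  # disk | annulus | ellipse | rectangle
    shape_params: dict = field(default_factory=dict)
    fg_mean: float = 200.0
    fg_sd: float = 5.0
    bg_mean: float = 60.0
    bg_sd: float = 5.0
    fracture_lines: tuple = ()  # ((r0, c0, r1, c1), width_px) pairs
    noise: str | None = None  # None | gaussian | salt_pepper
    noise_amount: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 4 or self.height < 4:
            raise ValidationError("phantom canvas must be at least 4x4")
        if self.bone_shape not in ("disk", "annulus", "ellipse", "rectangle"):
            raise ValidationError(f"unknown bone_shape {self.bone_shape!r}")
        for mean in (self.fg_mean, self.bg_mean):
            if not 0 <= mean <= 255:
                raise ValidationError("phase means must lie in [0, 255]")
        if self.fg_sd < 0 or self.bg_sd < 0:
            raise ValidationError("phase SDs must be >= 0")
        if self.noise not in (None, "gaussian", "salt_pepper"):
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if self.noise is not None and self.noise_amount < 0:
            raise ValidationError("noise_amount must be >= 0")


@dataclass(frozen=True)
class PhantomCase:
    """A generated phantom with its exact ground truth."""

    image: GrayImage
    truth_mask: SegmentationMask  # bone pixels (fracture gaps excluded)
    damage_mask: SegmentationMask  # fracture-line pixels
    region_truth: frozenset[Region]
    spec: PhantomSpec


def _shape_mask(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    rr, cc = np.mgrid[0:h, 0:w]
    cy = spec.shape_params.get("cy", (h - 1) / 2)
    cx = spec.shape_params.get("cx", (w - 1) / 2)
    if spec.bone_shape == "disk":
        r = spec.shape_params.get("radius", min(h, w) / 3)
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= r**2
    elif spec.bone_shape == "annulus":
        r_out = spec.shape_params.get("radius", min(h, w) / 3)
        r_in = spec.shape_params.get("inner_radius", r_out / 2)
        if r_in >= r_out:
            raise ValidationError("annulus inner radius must be < outer radius")
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        mask = (d2 <= r_out**2) & (d2 > r_in**2)
    elif spec.bone_shape == "ellipse":
        a = spec.shape_params.get("semi_axis_col", w / 2.5)
        b = spec.shape_params.get("semi_axis_row", h / 3)
        mask = ((rr - cy) / b) ** 2 + ((cc - cx) / a) ** 2 <= 1.0
    else:  # rectangle
        rh = spec.shape_params.get("rect_height", h // 2)
        rw = spec.shape_params.get("rect_width", w // 2)
        r0 = int(round(cy - rh / 2))
        c0 = int(round(cx - rw / 2))
        mask = np.zeros((h, w), dtype=bool)
        mask[max(r0, 0) : r0 + rh, max(c0, 0) : c0 + rw] = True
    if not mask.any():
        raise ValidationError("bone shape does not cover any pixel of the canvas")
    if not mask[1:-1, 1:-1].any():
        raise ValidationError("bone shape must fit inside the canvas")
    return mask


def _fracture_mask(spec: PhantomSpec) -> np.ndarray:
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for (r0, c0, r1, c1), width_px in spec.fracture_lines:
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        keep = (rr >= 0) & (rr < spec.height) & (cc >= 0) & (cc < spec.width)
        stroke = np.zeros_like(mask)
        stroke[rr[keep], cc[keep]] = True
        if width_px > 1:
            stroke = dilation(stroke, disk_footprint(int(width_px) // 2))
        mask |= stroke
    return mask


def generate_slice(spec: PhantomSpec) -> PhantomCase:
    """Render a phantom slice with exact bone and fracture ground truth.

    Bone pixels are drawn from ``N(fg_mean, fg_sd)``, everything else
    (background and fracture gaps) from ``N(bg_mean, bg_sd)``; fracture
    pixels are excluded from the truth mask.  Identical specs (including
    the seed) produce bit-identical cases.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shape = _shape_mask(spec)
    fracture = _fracture_mask(spec)
    truth = shape & ~fracture

    img = rng.normal(spec.bg_mean, spec.bg_sd, size=(spec.height, spec.width))
    img[truth] = rng.normal(spec.fg_mean, spec.fg_sd, size=int(truth.sum()))

    if spec.noise == "gaussian" and spec.noise_amount > 0:
        img += rng.normal(0.0, spec.noise_amount, size=img.shape)
    pixels = np.rint(np.clip(img, 0, 255)).astype(np.int64)
    if spec.noise == "salt_pepper" and spec.noise_amount > 0:
        flip = rng.random(img.shape) < spec.noise_amount
        salt = rng.random(img.shape) < 0.5
        pixels[flip & salt] = 255
        pixels[flip & ~salt] = 0

    return PhantomCase(
        image=GrayImage(pixels=pixels, levels=256),
        truth_mask=SegmentationMask(labels=truth),
        damage_mask=SegmentationMask(labels=fracture & shape),
        region_truth=frozenset(),
        spec=spec,
    )


def generate_plateau(
    spec: PhantomSpec, target_regions: frozenset[Region] | set[Region]
) -> PhantomCase:
    """Plateau top-view phantom whose damaged-region ground truth is exact.

    The plateau is an ellipse; short fracture strokes are routed through
    the interior of each requested region (region geometry taken from
    :func:`tibiacut.scoring.divide_plateau` at its default eminence
    fraction), so counting damaged regions on the output reproduces
    ``target_regions`` exactly.
    """
    targets = frozenset(Region(r) for r in target_regions)
    base = replace(spec, bone_shape="ellipse", fracture_lines=())
    shape = _shape_mask(base)
    region_map = divide_plateau(shape, eminence_halfwidth_frac=0.15)

    damage = np.zeros_like(shape)
    for region in targets:
        sel = region_map.region_mask(region)
        if not sel.any():
            raise ValidationError(
                f"cannot route a fracture through {region.value}: region empty "
                "for this plateau geometry"
            )
        rows, cols = np.nonzero(sel)
        # a compact stroke at the region's interior centroid pixel
        k = int(np.argmin((rows - rows.mean()) ** 2 + (cols - cols.mean()) ** 2))
        stroke = np.zeros_like(shape)
        stroke[rows[k], cols[k]] = True
        stroke = dilation(stroke, disk_footprint(2)) & sel
        damage |= stroke

    rng = np.random.default_rng(base.rng_seed)
    img = rng.normal(base.bg_mean, base.bg_sd, size=shape.shape)
    truth = shape & ~damage
    img[truth] = rng.normal(base.fg_mean, base.fg_sd, size=int(truth.sum()))
    pixels = np.rint(np.clip(img, 0, 255)).astype(np.int64)

    achieved = frozenset(
        r for r in RegionLabelMap.REGION_ORDER if (region_map.region_mask(r) & damage).any()
    )
    if achieved != targets:
        raise ValidationError(
            f"fracture routing failed: achieved {sorted(r.value for r in achieved)}, "
            f"wanted {sorted(r.value for r in targets)}"
        )
    return PhantomCase(
        image=GrayImage(pixels=pixels, levels=256),
        truth_mask=SegmentationMask(labels=truth),
        damage_mask=SegmentationMask(labels=damage),
        region_truth=targets,
        spec=base,
    )


def write_case(case: PhantomCase, out_dir: str | Path) -> None:
    """Write image.png, truth.png, damage.png and case.json to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_gray_image(case.image, out / "image.png")
    save_mask(case.truth_mask.labels, out / "truth.png")
    save_mask(case.damage_mask.labels, out / "damage.png")
    meta = {
        "spec": {
            **{k: getattr(case.spec, k) for k in (
                "width", "height", "bone_shape", "fg_mean", "fg_sd",
                "bg_mean", "bg_sd", "noise", "noise_amount", "rng_seed",
            )},
            "shape_params": case.spec.shape_params,
            "fracture_lines": [list(map(list, fl[:1])) + [fl[1]] for fl in case.spec.fracture_lines],
        },
        "region_truth": sorted(r.value for r in case.region_truth),
    }
    (out / "case.json").write_text(json.dumps(meta, indent=2))
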