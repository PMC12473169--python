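"""Synthetic phantoms: analytic surfaces plus a virtual rotational rig.

The validation strategy mirrors a physical phantom study: an object of
known geometry is rotated in 30-degree steps over a half turn and its
diametral profile captured at each stop, yielding six radial sections.
Here the phantom is analytic, so every downstream quantity (area,
volume, centroid) has a closed form to compare against.

Shapes
------
* ``hemisphere(R)`` — every measure has a closed form (area 2 pi R^2,
  volume 2/3 pi R^3, centroid height 3R/8).
* ``gaussian_bumps(...)`` — a sum of Gaussian humps, the "complex
  lesion-like" case with no rotational symmetry.
* ``ellipsoid_cap(a, b, c)`` — upper half-ellipsoid, anisotropic but
  still closed form.

Acquisition noise is additive Gaussian on the heights, driven by a
single seeded generator: identical seeds give bit-identical outputs.
The defaults (six sections, 30-degree step, noiseless heights) are the
canonical acquisition conditions; sample counts emulate digitizing a
profile from a photograph at sub-millimetre resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .errors import HemisurfError
from .imaging import SilhouetteImage
from .io import RadialSection, SectionSet, write_section_set

__all__ = [
    "AnalyticSurface",
    "AcquisitionPlan",
    "hemisphere",
    "gaussian_bumps",
    "ellipsoid_cap",
    "sample_sections",
    "render_silhouette",
    "write_phantom_dataset",
]


@dataclass(frozen=True)
class AnalyticSurface:
    """Closed-form height field z(x, angle) with compact support.

    ``height(x, angle)`` takes the signed in-section coordinate x (mm)
    and the rotation angle (rad) and returns the height (mm, >= 0).
    ``support`` is the radius beyond which the height is (numerically)
    zero.
    """

    kind: str
    height: Callable
    support: float
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.support <= 0:
            raise HemisurfError("support radius must be > 0")


def hemisphere(R: float = 10.0) -> AnalyticSurface:
    """Hemisphere of radius R mm resting on the base plane."""
    if R <= 0:
        raise HemisurfError("radius must be > 0")

    def h(x, angle):
        x = np.asarray(x, dtype=float)
        return np.sqrt(np.maximum(R * R - x * x, 0.0))

    return AnalyticSurface(kind="hemisphere", height=h, support=R, params={"R": R})


_DEFAULT_BUMPS = (
    # (cx_mm, cy_mm, amplitude_mm, sigma_mm): a broad dome with two satellites,
    # roughly the footprint and relief of a small raised lesion
    (0.0, 0.0, 8.0, 4.0),
    (3.0, 2.0, 4.0, 2.0),
    (-4.0, 1.5, 3.0, 2.5),
)


def gaussian_bumps(bumps=_DEFAULT_BUMPS, support: float = None) -> AnalyticSurface:
    """Sum of Gaussian humps; the asymmetric 'complex surface' phantom."""
    bumps = tuple(tuple(map(float, b)) for b in bumps)
    if not bumps:
        raise HemisurfError("need at least one bump")
    if support is None:
        support = max(math.hypot(cx, cy) + 4.0 * s for cx, cy, _, s in bumps)

    def h(x, angle):
        x = np.asarray(x, dtype=float)
        X = x * np.cos(angle)
        Y = x * np.sin(angle)
        z = np.zeros_like(x)
        for cx, cy, a, s in bumps:
            z = z + a * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * s * s))
        return z

    return AnalyticSurface(kind="gaussian-bumps", height=h, support=float(support),
                           params={"bumps": bumps})


def ellipsoid_cap(a: float = 10.0, b: float = 7.0, c: float = 5.0) -> AnalyticSurface:
    """Upper half of an ellipsoid with semi-axes (a, b, c) mm."""
    if min(a, b, c) <= 0:
        raise HemisurfError("semi-axes must be > 0")

    def h(x, angle):
        x = np.asarray(x, dtype=float)
        X = x * np.cos(angle)
        Y = x * np.sin(angle)
        q = 1.0 - (X / a) ** 2 - (Y / b) ** 2
        return c * np.sqrt(np.maximum(q, 0.0))

    return AnalyticSurface(kind="ellipsoid-cap", height=h, support=max(a, b),
                           params={"a": a, "b": b, "c": c})


@dataclass(frozen=True)
class AcquisitionPlan:
    """Virtual rotational acquisition: six 30-degree stops by default."""

    n_sections: int = 6
    angle_step: float = math.pi / 6
    n_samples_per_section: int = 101
    noise_sd: float = 0.0  # mm, additive Gaussian on heights
    seed: int = 0

    def __post_init__(self):
        if self.n_sections < 2:
            raise HemisurfError("need at least 2 sections")
        if self.noise_sd < 0:
            raise HemisurfError("noise_sd must be >= 0")
        if self.n_samples_per_section < 2:
            raise HemisurfError("need at least 2 samples per section")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_sections) * self.angle_step


def sample_sections(surf: AnalyticSurface, plan: AcquisitionPlan = AcquisitionPlan()) -> SectionSet:
    """Sample the phantom at each plan angle; deterministic given the seed."""
    rng = np.random.default_rng(plan.seed)
    xs = np.linspace(-surf.support, surf.support, plan.n_samples_per_section)
    sections = []
    for angle in plan.angles:
        z = np.asarray(surf.height(xs, angle), dtype=float)
        if plan.noise_sd > 0:
            z = z + rng.normal(0.0, plan.noise_sd, size=z.shape)
        sections.append(RadialSection(angle=float(angle), xs=xs.copy(), zs=z))
    return SectionSet(
        sections=tuple(sections),
        meta={"phantom": surf.kind, "noise_sd_mm": plan.noise_sd, "seed": plan.seed},
    )


def render_silhouette(surf: AnalyticSurface, angle: float, px: int = 256,
                      mm_per_px: float = None) -> SilhouetteImage:
    """Binary side-view silhouette of the phantom at one rotation angle.

    The object is dark (0.0) on a light (1.0) background; the base plane
    is the bottom image row and the symmetry axis the horizontal centre
    column.  The column-wise upper envelope of the rendered mask matches
    the analytic profile to within one pixel.
    """
    if px < 8:
        raise HemisurfError("image too small")
    if mm_per_px is None:
        mm_per_px = 2.2 * surf.support / px
    half = (px - 1) / 2.0
    x = (np.arange(px) - half) * mm_per_px
    z = np.asarray(surf.height(x, angle), dtype=float)
    if x.max() < surf.support or z.max() >= px * mm_per_px:
        raise HemisurfError("phantom support exceeds the image frame")
    n_obj = np.round(z / mm_per_px).astype(int)  # object pixels per column
    rows = np.arange(px)[:, None]  # row 0 = top
    mask = rows >= (px - n_obj[None, :])
    pixels = np.where(mask, 0.0, 1.0)
    return SilhouetteImage(pixels=pixels, mm_per_px=mm_per_px, angle=angle,
                           polarity="dark-object")


def write_phantom_dataset(outdir, surf: AnalyticSurface,
                          plan: AcquisitionPlan = AcquisitionPlan(),
                          images: bool = False, px: int = 256) -> Path:
    """Write section CSVs + manifest (and optional silhouette PNGs).

    Returns the manifest path.  Byte-identical for identical arguments.
    """
    outdir = Path(outdir)
    ss = sample_sections(surf, plan)
    manifest = write_section_set(ss, outdir)
    if images:
        import imageio.v3 as iio

        for angle in plan.angles:
            img = render_silhouette(surf, float(angle), px=px)
            deg = math.degrees(angle)
            iio.imwrite(outdir / f"silhouette_{deg:07.2f}deg.png",
                        (img.pixels * 255).astype(np.uint8))
    return manifest
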