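"""Silhouette photographs -> radial section profiles.

A raised lesion (or its physical phantom) is photographed in side view
against a contrasting background at each rotation angle.  Binarizing
the photograph isolates the object; the column-wise upper envelope of
the foreground mask is the diametral height profile z(x) of that
rotation angle, with x measured (signed) from a chosen symmetry axis
and the base plane at the bottom image row.

Thresholding defaults to Otsu's inter-class-variance criterion; the
largest 4-connected foreground component is kept so background specks
do not distort the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label

from .errors import ImagingError
from .io import RadialSection

__all__ = [
    "SilhouetteImage",
    "ProfileExtract",
    "load_silhouette",
    "binarize",
    "extract_profile",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class SilhouetteImage:
    """Grayscale silhouette frame: values in [0, 1], known mm/pixel scale.

    ``polarity`` says whether the object is darker ('dark-object') or
    lighter ('light-object') than the background.
    """

    pixels: np.ndarray
    mm_per_px: float
    angle: float = 0.0
    polarity: str = "dark-object"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ImagingError("pixels must be a 2-D grayscale grid")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ImagingError("pixel values must lie in [0, 1]")
        if self.mm_per_px <= 0:
            raise ImagingError("mm_per_px must be > 0")
        if self.polarity not in ("dark-object", "light-object"):
            raise ImagingError("polarity must be 'dark-object' or 'light-object'")
        object.__setattr__(self, "pixels", px)


@dataclass(frozen=True)
class ProfileExtract:
    section: RadialSection
    threshold_used: float
    n_foreground_px: int


def load_silhouette(path, mm_per_px: float, angle: float = 0.0,
                    polarity: str = "dark-object") -> SilhouetteImage:
    """Read PNG/TIFF; color frames collapse to luminance, values to [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.max() > 1.0:
        arr = arr / 255.0
    arr = np.clip(arr, 0.0, 1.0)
    return SilhouetteImage(pixels=arr, mm_per_px=mm_per_px, angle=angle,
                           polarity=polarity)


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold: maximize the inter-class variance over 256 bins.

    When the two modes are well separated, every cut through the empty
    gap achieves the same (maximal) variance; the *middle* of that
    plateau is returned so the threshold is deterministic and sits
    centrally between the modes rather than at a cluster edge.
    """
    hist, edges = np.histogram(np.asarray(values, dtype=float).ravel(), bins=nbins)
    hist = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise ImagingError("flat image: cannot auto-threshold")
    csum = np.cumsum(hist * centers)[:-1]
    m0 = np.divide(csum, w0, out=np.zeros_like(w0), where=w0 > 0)
    m1 = np.divide(csum[-1] + hist[-1] * centers[-1] - csum, w1,
                   out=np.zeros_like(w1), where=w1 > 0)
    var = np.where(valid, w0 * w1 * (m0 - m1) ** 2, -np.inf)
    best = var.max()
    plateau = np.flatnonzero(var >= best * (1.0 - 1e-12))
    split = plateau[len(plateau) // 2]  # class 0 = bins[: split + 1]
    return float(edges[split + 1])


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = label(mask, connectivity=1)
    n = labels.max()
    if n == 0:
        raise ImagingError("empty foreground after thresholding")
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        # tie: keep the component whose bounding box starts leftmost
        best = sorted(best, key=lambda l: np.where(labels == l)[1].min())
    return labels == best[0]


def binarize(img: SilhouetteImage, threshold=None) -> tuple:
    """Foreground mask after polarity normalization.

    Returns (mask, threshold_used).  ``threshold=None`` selects Otsu's
    threshold on the polarity-normalized image; only the largest
    4-connected component is kept.
    """
    fg = img.pixels if img.polarity == "light-object" else 1.0 - img.pixels
    if threshold is None:
        if fg.min() == fg.max():
            raise ImagingError("flat image: cannot auto-threshold")
        threshold = otsu_threshold(fg)
    else:
        threshold = float(threshold)
        if not (0.0 <= threshold <= 1.0):
            raise ImagingError("threshold must lie in [0, 1]")
    mask = fg > threshold
    if not mask.any():
        raise ImagingError("empty foreground after thresholding")
    return _largest_component(mask), threshold


def extract_profile(img: SilhouetteImage, threshold=None,
                    axis_col=None) -> ProfileExtract:
    """Column-wise upper envelope of the silhouette as a radial section.

    For every image column intersecting the mask, the topmost foreground
    row sets the height z (the base plane is the bottom image row); x is
    the signed column offset from ``axis_col`` (default: the foreground
    centroid column).  Objects touching the top border are rejected as
    clipped.
    """
    mask, thr = binarize(img, threshold=threshold)
    if mask[0, :].any():
        raise ImagingError("object touches the top image border (clipped)")
    h, _ = mask.shape
    cols = np.flatnonzero(mask.any(axis=0))
    if len(cols) < 2:
        raise ImagingError("foreground spans fewer than 2 columns")
    top_rows = np.argmax(mask[:, cols], axis=0)  # first True per column
    z_px = h - top_rows.astype(float)
    if axis_col is None:
        col_weights = mask.sum(axis=0)
        axis_col = float(np.average(np.arange(mask.shape[1]), weights=col_weights))
    xs = (cols - float(axis_col)) * img.mm_per_px
    zs = z_px * img.mm_per_px
    section = RadialSection(angle=img.angle, xs=xs, zs=zs)
    return ProfileExtract(section=section, threshold_used=thr,
                          n_foreground_px=int(mask.sum()))
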