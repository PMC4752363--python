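"""Eggshell colorimetry: segment the egg, take a circular subsample, convert
to CIELAB, split maculated from background pixels and summarise.

The pipeline follows the photographic protocol the package emulates:

1. the image is partitioned into egg and backdrop by an Otsu threshold on a
   grayscale (Rec. 709 luminance) version;
2. a circular subsample containing one third of the egg area is placed at the
   egg centroid with its x coordinate shifted to ``0.88 * centroid_x``,
   moving it toward the broad end and away from the curved rim;
3. subsample pixels are converted to CIELAB and classified as maculated or
   background with 2-means clustering (the darker-centroid cluster is the
   maculation);
4. maculation is reported as the percentage of dark pixels in the subsample,
   and the background color as the mean and SD of L*, a*, b* over the
   non-maculated subsample pixels.

Eggs are assumed to lie long-axis-horizontal with the broad end at lower x;
:func:`canonicalize_pose` rotates/flips axis-aligned inputs into this pose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .color import (
    DegenerateHistogramError,
    linear_rgb_to_lab,
    luminance,
    otsu_threshold_values,
)

__all__ = [
    "EggMask",
    "SubsampleRegion",
    "ColorimetricSummary",
    "segment_egg",
    "canonicalize_pose",
    "select_subsample",
    "classify_maculation",
    "summarize_colorimetrics",
    "analyze_image",
    "load_image",
]

SUBSAMPLE_SHIFT = 0.88  # centroid-x multiplier moving the circle to the broad end
SUBSAMPLE_AREA_FRACTION = 1.0 / 3.0


@dataclass
class EggMask:
    """Binary egg segmentation with its physical pixel scale."""

    mask: np.ndarray  #: (H, W) bool
    pixel_scale: float = 0.1  #: mm per pixel

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def area_mm2(self) -> float:
        return self.n_pixels * self.pixel_scale**2


@dataclass
class SubsampleRegion:
    """Circular subsample clipped to the egg mask."""

    center: tuple[float, float]  #: (x, y), x rightward, origin top-left
    radius: float  #: px
    member_mask: np.ndarray  #: (H, W) bool; subset of the egg mask
    achieved_fraction: float  #: member pixels / egg pixels

    @property
    def n_members(self) -> int:
        return int(self.member_mask.sum())


@dataclass
class ColorimetricSummary:
    L_mean: float
    L_sd: float
    a_mean: float
    a_sd: float
    b_mean: float
    b_sd: float
    maculation_pct: float
    egg_area_mm2: float
    diagnostics: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "L_mean": self.L_mean,
            "L_sd": self.L_sd,
            "a_mean": self.a_mean,
            "a_sd": self.a_sd,
            "b_mean": self.b_mean,
            "b_sd": self.b_sd,
            "maculation_pct": self.maculation_pct,
            "egg_area_mm2": self.egg_area_mm2,
        }


def segment_egg(image: np.ndarray, pixel_scale: float = 0.1) -> EggMask:
    """Segment the egg from the backdrop.

    Otsu's threshold on the luminance; the brighter class is the egg; the
    largest connected component is kept and interior holes (dark spots that
    fell below the threshold) are filled, since the egg is a solid object.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    gray = luminance(image) if image.ndim == 3 else image
    t = otsu_threshold_values(gray)  # raises DegenerateHistogramError
    fg = gray > t
    if not fg.any():
        raise ValueError("foreground empty after thresholding")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    # dark spots fall below the threshold: interior ones are holes, rim ones
    # are notches; closing bridges the notches before the holes are filled
    footprint = morphology.disk(6)
    closed = morphology.closing(mask, footprint)
    mask = ndimage.binary_fill_holes(closed)
    return EggMask(mask=mask, pixel_scale=pixel_scale)


def canonicalize_pose(image: np.ndarray, mask: EggMask) -> tuple[np.ndarray, EggMask]:
    """Rotate/flip into the canonical pose: long axis horizontal, broad end
    at lower x.

    Axis alignment is decided from the coordinate variances of the mask (a
    90-degree rotation is applied when the long axis is vertical); the broad
    end is the half holding more mask pixels relative to the centroid, with a
    0.5% tolerance so symmetric eggs are left untouched.  Only exact
    (90-degree / mirror) transforms are used.
    """
    m = mask.mask
    ys, xs = np.nonzero(m)
    if xs.size == 0:
        raise ValueError("empty egg mask")
    if np.var(ys) > np.var(xs):
        image = np.rot90(image, k=1, axes=(0, 1)).copy()
        m = np.rot90(m, k=1).copy()
        ys, xs = np.nonzero(m)
    cx = xs.mean()
    left = int((xs < cx).sum())
    right = int((xs > cx).sum())
    if right > left * 1.005:
        image = image[:, ::-1].copy()
        m = m[:, ::-1].copy()
    return image, EggMask(mask=m, pixel_scale=mask.pixel_scale)


def select_subsample(mask: EggMask) -> SubsampleRegion:
    """Circular subsample holding one third of the egg area.

    The circle center is the egg centroid with its x coordinate multiplied
    by 0.88; the radius is ``sqrt(area / (3*pi))`` so the circle area equals
    one third of the egg area.  Members are clipped to the egg mask and the
    achieved fraction recorded.
    """
    m = mask.mask
    ys, xs = np.nonzero(m)
    if xs.size == 0:
        raise ValueError("empty egg mask")
    cx, cy = xs.mean(), ys.mean()
    cx_shifted = SUBSAMPLE_SHIFT * cx
    area = xs.size
    radius = np.sqrt(area * SUBSAMPLE_AREA_FRACTION / np.pi)
    yy, xx = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
    circle = (xx - cx_shifted) ** 2 + (yy - cy) ** 2 <= radius**2
    member = circle & m
    achieved = member.sum() / area
    return SubsampleRegion(
        center=(float(cx_shifted), float(cy)),
        radius=float(radius),
        member_mask=member,
        achieved_fraction=float(achieved),
    )


def classify_maculation(
    lab_pixels: np.ndarray,
    k: int = 2,
    seed: int | None = None,
    min_centroid_delta: float = 8.0,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """2-means clustering of CIELAB pixels into maculated vs background.

    Lloyd's algorithm with a deterministic, permutation-invariant
    initialisation: the two centroids start at the means of the bottom and
    top L* deciles.  The cluster with the lower centroid L* is labelled
    maculated (label 1).  If the converged centroids are closer than
    ``min_centroid_delta`` (Euclidean distance in Lab) the pixels are deemed
    a single population and everything is labelled background — a spotless
    egg must not be split in half by noise.  The ``seed`` argument is
    accepted for interface compatibility; the procedure is deterministic.

    Returns
    -------
    (labels, centroids, info)
        ``labels``: int array, 1 = maculated; ``centroids``: (k, 3) in the
        order (background, maculated) when separated; ``info`` carries
        ``separated`` and iteration diagnostics.
    """
    X = np.asarray(lab_pixels, dtype=float).reshape(-1, 3)
    n = X.shape[0]
    if k != 2:
        raise ValueError("only k=2 is supported")
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < k:
        warnings.warn(
            "fewer distinct pixels than clusters; labelling all as background",
            stacklevel=2,
        )
        labels = np.zeros(n, dtype=int)
        c = X.mean(axis=0) if n else np.zeros(3)
        return labels, np.stack([c, c]), {"separated": False, "n_iter": 0}

    L = X[:, 0]
    q10, q90 = np.quantile(L, [0.10, 0.90])
    c_lo = X[L <= q10].mean(axis=0)
    c_hi = X[L >= q90].mean(axis=0)
    centroids = np.stack([c_lo, c_hi])
    labels = np.zeros(n, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d, axis=1)
        new = centroids.copy()
        for j in range(2):
            sel = labels == j
            if sel.any():
                new[j] = X[sel].mean(axis=0)
        shift = np.abs(new - centroids).max()
        centroids = new
        if shift < tol:
            break

    delta = float(np.linalg.norm(centroids[0] - centroids[1]))
    separated = delta >= min_centroid_delta
    if not separated:
        out_labels = np.zeros(n, dtype=int)
        c = X.mean(axis=0)
        out_centroids = np.stack([c, c])
    else:
        dark = int(np.argmin(centroids[:, 0]))
        out_labels = (labels == dark).astype(int)
        out_centroids = np.stack([centroids[1 - dark], centroids[dark]])
    return (
        out_labels,
        out_centroids,
        {"separated": separated, "n_iter": n_iter, "centroid_delta": delta},
    )


def summarize_colorimetrics(
    region: SubsampleRegion,
    labels: np.ndarray,
    lab_pixels: np.ndarray,
    mask: EggMask,
) -> ColorimetricSummary:
    """Summarise a classified subsample.

    Maculation % is the share of maculated pixels among subsample members;
    background L*a*b* means/SDs (population SD) are computed over the
    non-maculated members only; the egg area comes from the full mask.
    """
    labels = np.asarray(labels)
    lab = np.asarray(lab_pixels, dtype=float).reshape(-1, 3)
    if labels.shape[0] != region.n_members or lab.shape[0] != region.n_members:
        raise ValueError("labels/pixels do not cover the subsample members")
    n = region.n_members
    n_mac = int((labels == 1).sum())
    bg = lab[labels == 0]
    if bg.shape[0] == 0:
        raise ValueError("no background pixels in subsample; cannot summarise")
    mean = bg.mean(axis=0)
    sd = bg.std(axis=0)
    return ColorimetricSummary(
        L_mean=float(mean[0]),
        L_sd=float(sd[0]),
        a_mean=float(mean[1]),
        a_sd=float(sd[1]),
        b_mean=float(mean[2]),
        b_sd=float(sd[2]),
        maculation_pct=100.0 * n_mac / n,
        egg_area_mm2=mask.area_mm2,
        diagnostics={
            "subsample_fraction": region.achieved_fraction,
            "n_subsample": n,
            "n_maculated": n_mac,
        },
    )


def analyze_image(
    image: np.ndarray,
    pixel_scale: float = 0.1,
    white_point=None,
    min_centroid_delta: float = 8.0,
) -> ColorimetricSummary:
    """Run the whole colorimetry pipeline on one linear-RGB image."""
    from .color import D65_WHITE

    wp = D65_WHITE if white_point is None else white_point
    mask = segment_egg(image, pixel_scale=pixel_scale)
    image, mask = canonicalize_pose(image, mask)
    region = select_subsample(mask)
    pixels = image[region.member_mask]
    lab = linear_rgb_to_lab(pixels, white_point=wp)
    labels, _, info = classify_maculation(
        lab, min_centroid_delta=min_centroid_delta
    )
    summary = summarize_colorimetrics(region, labels, lab, mask)
    summary.diagnostics.update(info)
    return summary


def load_image(path, assume_srgb: bool = False) -> np.ndarray:
    """Read an 8/16-bit PNG or TIFF as linear RGB floats in [0, 1].

    ``assume_srgb`` applies the sRGB electro-optical transfer function to
    decode gamma-encoded files into linear RGB.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(str(path)))
    if arr.dtype == np.uint8:
        img = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        img = arr.astype(float) / 65535.0
    else:
        img = arr.astype(float)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    if assume_srgb:
        a = 0.055
        img = np.where(
            img <= 0.04045, img / 12.92, ((img + a) / (1 + a)) ** 2.4
        )
    return img
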