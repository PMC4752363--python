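"""Color-space conversions and the Otsu histogram threshold.

Images are handled as *linear* RGB (Rec. 709 / sRGB primaries, no gamma) in
[0, 1].  Conversion to CIELAB goes linear RGB -> CIE XYZ (matrix for the
configured primaries) -> L*a*b* with a configurable reference white (D65 by
default), using the CIE 1976 formulae with the 6/29 linearisation knee.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "D65_WHITE",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "linear_rgb_to_lab",
    "lab_to_linear_rgb",
    "luminance",
    "otsu_threshold",
    "otsu_threshold_values",
    "DegenerateHistogramError",
]

# Rec. 709 / sRGB primaries, D65 white (linear RGB -> XYZ)
_RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_RGB = np.linalg.inv(_RGB_TO_XYZ)

#: XYZ of the D65 reference white, normalised to Y = 1.
D65_WHITE = tuple(_RGB_TO_XYZ @ np.ones(3))

_DELTA = 6.0 / 29.0


class DegenerateHistogramError(ValueError):
    """Raised when a histogram cannot support a two-class threshold."""


def linear_rgb_to_xyz(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    return rgb @ _RGB_TO_XYZ.T


def xyz_to_linear_rgb(xyz: np.ndarray) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ _XYZ_TO_RGB.T


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 709 luminance (the Y row of the RGB->XYZ matrix)."""
    rgb = np.asarray(rgb, dtype=float)
    return rgb @ _RGB_TO_XYZ[1]


def _f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _f_inv(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.where(u > _DELTA, u**3, 3 * _DELTA**2 * (u - 4.0 / 29.0))


def xyz_to_lab(xyz: np.ndarray, white_point=D65_WHITE) -> np.ndarray:
    xyz = np.asarray(xyz, dtype=float)
    wp = np.asarray(white_point, dtype=float)
    fx, fy, fz = (_f(xyz[..., i] / wp[i]) for i in range(3))
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab: np.ndarray, white_point=D65_WHITE) -> np.ndarray:
    lab = np.asarray(lab, dtype=float)
    wp = np.asarray(white_point, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    return np.stack(
        [_f_inv(fx) * wp[0], _f_inv(fy) * wp[1], _f_inv(fz) * wp[2]], axis=-1
    )


def linear_rgb_to_lab(rgb: np.ndarray, white_point=D65_WHITE) -> np.ndarray:
    """Linear RGB in [0, 1] to CIELAB.  Out-of-range input is clipped with a
    warning (sensor noise can push pixels slightly outside the unit cube)."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        warnings.warn(
            "RGB values outside [0, 1] clipped before CIELAB conversion",
            stacklevel=2,
        )
        rgb = np.clip(rgb, 0.0, 1.0)
    return xyz_to_lab(linear_rgb_to_xyz(rgb), white_point=white_point)


def lab_to_linear_rgb(lab: np.ndarray, white_point=D65_WHITE, clip: bool = True) -> np.ndarray:
    rgb = xyz_to_linear_rgb(lab_to_xyz(lab, white_point=white_point))
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb


def otsu_threshold(counts: np.ndarray, bin_edges: np.ndarray | None = None):
    """Otsu's threshold from a histogram.

    Chooses the split maximising the between-class variance
    ``w0 * w1 * (mu0 - mu1)^2`` (equivalently minimising the pooled
    within-class variance); ties are broken by the lowest threshold.

    Parameters
    ----------
    counts
        Histogram counts per bin.
    bin_edges
        Optional edges of length ``len(counts) + 1``.  When given, the
        returned threshold is the boundary value between the two classes
        (right edge of the last bin of the lower class); otherwise the split
        index ``k`` is returned (lower class = bins ``0..k`` inclusive).

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size < 2:
        raise DegenerateHistogramError("histogram must be 1-D with >= 2 bins")
    if np.count_nonzero(counts) < 2:
        raise DegenerateHistogramError(
            "histogram occupies fewer than two bins; no two-class split exists"
        )
    total = counts.sum()
    p = counts / total
    centers = (
        (bin_edges[:-1] + bin_edges[1:]) / 2.0
        if bin_edges is not None
        else np.arange(counts.size, dtype=float)
    )
    w0 = np.cumsum(p)[:-1]
    w1 = 1.0 - w0
    m0 = np.cumsum(p * centers)[:-1]
    mtot = (p * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, m0 / w0, 0.0)
        mu1 = np.where(w1 > 0, (mtot - m0) / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    # lowest threshold among (floating-point) ties
    best = between.max()
    tol = 1e-9 * max(best, 1e-300)
    k = int(np.flatnonzero(between >= best - tol)[0])
    if bin_edges is not None:
        return float(bin_edges[k + 1])
    return k


def otsu_threshold_values(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold of raw values via a ``nbins``-bin histogram."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    if lo == hi:
        raise DegenerateHistogramError("all values identical; threshold undefined")
    counts, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    return otsu_threshold(counts, edges)
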