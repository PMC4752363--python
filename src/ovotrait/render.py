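"""Synthetic egg-image rendering with ground-truth masks.

An egg is drawn as a horizontal ellipse (broad end, by convention, at lower
x) on a near-black background, in linear RGB.  Maculation is laid down as
random dark disks until the ground-truth spot coverage falls within +/-0.02
of the requested fraction; Gaussian pixel noise is added last, so the masks
describe the noise-free rendering exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color import lab_to_linear_rgb

__all__ = ["EggImageBundle", "render_egg_image"]

COVERAGE_TOL = 0.02


@dataclass
class EggImageBundle:
    """A rendered egg image plus its generating ground truth."""

    image: np.ndarray  #: (H, W, 3) linear RGB in [0, 1]
    egg_mask: np.ndarray  #: (H, W) bool, True on the egg
    maculation_mask: np.ndarray  #: (H, W) bool, True on spots (subset of egg)
    params: dict = field(default_factory=dict)

    @property
    def spot_fraction(self) -> float:
        """Achieved ground-truth spot coverage of the egg."""
        egg = int(self.egg_mask.sum())
        return float(self.maculation_mask.sum()) / egg if egg else 0.0


def default_spot_lab(background_lab) -> tuple[float, float, float]:
    """Darker, slightly redder spot color derived from the background."""
    L, a, b = (float(v) for v in background_lab)
    return (max(8.0, L - 28.0), a + 8.0, max(b - 8.0, -20.0))


def render_egg_image(
    background_lab,
    maculation_fraction: float,
    pixel_scale: float = 0.1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = (300, 400),
    noise_sd: float = 0.004,
    spot_lab=None,
    spot_radius_range: tuple[float, float] = (2.0, 4.5),
    vignette_strength: float = 0.0,
    backdrop_rgb: float = 0.005,
    max_disks: int = 40000,
) -> EggImageBundle:
    """Render one synthetic egg photograph.

    Parameters
    ----------
    background_lab
        CIELAB triple of the (non-maculated) shell background color; must
        map into the RGB gamut of the rendering white point.
    maculation_fraction
        Target spot coverage of the egg area, in [0, 1]; fractions above
        0.9 are rejected as unreachable by disk placement.
    pixel_scale
        Physical size of a pixel in mm (stored in the bundle parameters).
    shape
        Canvas (rows, cols); the ellipse spans ~84% x ~76% of it.
    noise_sd
        SD of i.i.d. Gaussian pixel noise in linear RGB, added after the
        ground-truth masks are fixed.
    vignette_strength
        0 disables; v in (0, 1] darkens the egg multiplicatively towards
        its rim by up to ``v``.
    """
    if not 0.0 <= maculation_fraction <= 1.0:
        raise ValueError("maculation_fraction must be in [0, 1]")
    if maculation_fraction > 0.9:
        raise ValueError(
            f"maculation_fraction={maculation_fraction} exceeds the packable "
            "coverage limit (0.9) for random disk placement"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    H, W = shape
    cy, cx = H / 2.0, W / 2.0
    semi_x, semi_y = 0.42 * W, 0.38 * H
    yy, xx = np.mgrid[0:H, 0:W]
    egg = ((xx - cx) / semi_x) ** 2 + ((yy - cy) / semi_y) ** 2 <= 1.0
    n_egg = int(egg.sum())

    spots = np.zeros_like(egg)
    n_spot = 0
    target = maculation_fraction
    if target > 0:
        r_lo, r_hi = spot_radius_range
        for _ in range(max_disks):
            if n_spot / n_egg >= target:
                break
            # rejection-sample a spot center on the egg
            px = rng.uniform(cx - semi_x, cx + semi_x)
            py = rng.uniform(cy - semi_y, cy + semi_y)
            if ((px - cx) / semi_x) ** 2 + ((py - cy) / semi_y) ** 2 > 1.0:
                continue
            r = rng.uniform(r_lo, r_hi)
            x0, x1 = max(0, int(px - r) - 1), min(W, int(px + r) + 2)
            y0, y1 = max(0, int(py - r) - 1), min(H, int(py + r) + 2)
            sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
            disk = (sub_x - px) ** 2 + (sub_y - py) ** 2 <= r * r
            patch = spots[y0:y1, x0:x1]
            new = disk & egg[y0:y1, x0:x1] & ~patch
            n_spot += int(new.sum())
            patch |= new
        achieved = n_spot / n_egg
        if abs(achieved - target) > COVERAGE_TOL:
            raise RuntimeError(
                f"spot coverage {achieved:.3f} not within {COVERAGE_TOL} of "
                f"target {target:.3f} after {max_disks} disks"
            )

    bg_rgb = lab_to_linear_rgb(np.asarray(background_lab, dtype=float))
    if spot_lab is None:
        spot_lab = default_spot_lab(background_lab)
    sp_rgb = lab_to_linear_rgb(np.asarray(spot_lab, dtype=float))

    image = np.full((H, W, 3), backdrop_rgb, dtype=float)
    image[egg] = bg_rgb
    image[spots] = sp_rgb
    if vignette_strength > 0:
        d2 = ((xx - cx) / semi_x) ** 2 + ((yy - cy) / semi_y) ** 2
        factor = 1.0 - vignette_strength * np.clip(d2, 0.0, 1.0)
        image[egg] *= factor[egg][:, None]
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return EggImageBundle(
        image=image,
        egg_mask=egg,
        maculation_mask=spots,
        params={
            "background_lab": tuple(float(v) for v in background_lab),
            "spot_lab": tuple(float(v) for v in spot_lab),
            "maculation_fraction_target": float(maculation_fraction),
            "maculation_fraction_achieved": n_spot / n_egg,
            "pixel_scale": float(pixel_scale),
            "noise_sd": float(noise_sd),
            "shape": (int(H), int(W)),
        },
    )
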