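"""Seeded synthetic phantoms with ultrasound-like structure.

Phantoms are piecewise-smooth: a background level, an optional linear intensity
gradient (emulating depth-dependent gain), elliptical hypo-/hyper-echoic
inclusions (emulating cysts / nodes), and a light Gaussian blur that softens
edges the way a B-mode point-spread function does.  They stand in for natural
or clinical training images wherever a clean reference with measurable edges
is needed, and are bitwise-reproducible from their spec.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .image import GrayImage, Scale

__all__ = ["PhantomSpec", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom image.

    Parameters
    ----------
    height, width
        Image size in pixels.
    n_inclusions
        Number of non-overlapping elliptical inclusions.
    inclusion_contrast_range
        Interval of |contrast| magnitudes (unit scale) drawn per inclusion;
        the hypo/hyper sign is drawn separately with probability 1/2.  Kept
        away from zero by default so every inclusion is detectable.
    background_level
        Base intensity in [0.1, 0.9].
    gradient_amplitude
        Peak-to-trough amplitude of a linear intensity ramp in a random
        direction; 0 disables it.
    blur_radius
        Gaussian sigma in pixels applied at the end; 0 disables it.
    seed
        Seed controlling every random draw of the phantom.
    """

    height: int = 64
    width: int = 64
    n_inclusions: int = 3
    inclusion_contrast_range: tuple[float, float] = (0.15, 0.4)
    background_level: float = 0.5
    gradient_amplitude: float = 0.1
    blur_radius: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom size must be at least 1x1")
        if self.n_inclusions < 0:
            raise ValueError("n_inclusions must be >= 0")
        lo, hi = self.inclusion_contrast_range
        if not (-0.5 <= lo <= hi <= 0.5):
            raise ValueError("inclusion_contrast_range must be an interval within [-0.5, 0.5]")
        if not 0.1 <= self.background_level <= 0.9:
            raise ValueError("background_level must lie in [0.1, 0.9]")
        if self.gradient_amplitude < 0 or self.blur_radius < 0:
            raise ValueError("gradient_amplitude and blur_radius must be >= 0")


def _draw_ellipses(spec: PhantomSpec, rng: np.random.Generator) -> list[tuple]:
    """Rejection-sample non-overlapping ellipse geometries."""
    h, w = spec.height, spec.width
    short = min(h, w)
    a_lo, a_hi = 0.08 * short, 0.18 * short
    if a_lo < 1.5:
        a_lo = 1.5
    if a_hi <= a_lo:
        a_hi = a_lo + 1.0
    if 2 * a_hi > short:
        raise ValueError(f"inclusions of semi-axis up to {a_hi:.1f}px do not fit a {h}x{w} image")
    placed: list[tuple] = []
    attempts = 0
    while len(placed) < spec.n_inclusions:
        attempts += 1
        if attempts > 500 * max(spec.n_inclusions, 1):
            raise ValueError(f"could not place {spec.n_inclusions} non-overlapping inclusions in {h}x{w}")
        ax = rng.uniform(a_lo, a_hi)
        ay = rng.uniform(a_lo, a_hi)
        pad = max(ax, ay) + 2.0
        if pad >= w - pad or pad >= h - pad:
            raise ValueError(f"inclusion larger than the {h}x{w} image")
        cx = rng.uniform(pad, w - pad)
        cy = rng.uniform(pad, h - pad)
        angle = rng.uniform(0, np.pi)
        # keep >=3 px between ellipse bounding circles so components stay separable
        ok = all(
            np.hypot(cx - px, cy - py) > max(ax, ay) + max(pax, pay) + 3.0
            for (py, px, pay, pax, _) in placed
        )
        if ok:
            placed.append((cy, cx, ay, ax, angle))
    return placed


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float, ay: float, ax: float, angle: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> GrayImage:
    """Render one phantom deterministically from its spec."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed) & 0x7FFFFFFF, 0x9A17]))
    h, w = spec.height, spec.width
    img = np.full((h, w), spec.background_level, dtype=np.float64)

    if spec.gradient_amplitude > 0:
        angle = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = np.cos(angle) * xx / max(w - 1, 1) + np.sin(angle) * yy / max(h - 1, 1)
        ramp -= ramp.min()
        if ramp.max() > 0:
            ramp /= ramp.max()
        img += spec.gradient_amplitude * (ramp - 0.5)

    if spec.n_inclusions > 0:
        lo, hi = spec.inclusion_contrast_range
        for (cy, cx, ay, ax, angle) in _draw_ellipses(spec, rng):
            magnitude = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            contrast = sign * magnitude if lo >= 0 else magnitude
            mask = _ellipse_mask((h, w), cy, cx, ay, ax, angle)
            img[mask] += contrast

    if spec.blur_radius > 0:
        img = ndimage.gaussian_filter(img, spec.blur_radius, mode="nearest")

    return GrayImage(np.clip(img, 0.0, 1.0), Scale.UNIT)


def generate_dataset(n: int, spec_template: PhantomSpec) -> list[GrayImage]:
    """Generate ``n`` phantoms with per-index derived seeds and uniform size."""
    if n < 1:
        raise ValueError("dataset size must be >= 1")
    return [
        generate_phantom(replace(spec_template, seed=(int(spec_template.seed) * 100003 + i) & 0x7FFFFFFF))
        for i in range(n)
    ]
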