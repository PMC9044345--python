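"""Multiplicative speckle corruption for B-mode-style images.

The corruption model is

    v(x, y) = u(x, y) + u(x, y)^r * theta(x, y),

where ``u`` is the clean intensity, ``theta`` is i.i.d. zero-mean Gaussian
noise of standard deviation ``sigma``, and the exponent ``r`` couples the noise
amplitude to local brightness (``r = 0.5`` is the conventional choice for
simulating ultrasound speckle; ``r = 0`` degenerates to plain additive white
Gaussian noise).  Noise levels are quoted on the 0–255 scale as is customary in
the denoising literature; on unit-scale images the effective deviation is
``sigma / 255``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import GrayImage, Scale

__all__ = ["SpeckleParams", "add_speckle", "corrupt_dataset"]


@dataclass(frozen=True)
class SpeckleParams:
    """Parameters of the speckle corruption.

    Parameters
    ----------
    sigma_8bit
        Noise standard deviation quoted on the 0–255 scale (typical study
        levels: 15, 25, 50).
    r
        Multiplicative exponent coupling noise amplitude to brightness.
        0.5 by default; 0 gives signal-independent Gaussian noise.
    seed
        Seed of the corruption's own random stream.
    clip
        Clip the noisy image to the declared scale's range.  On by default for
        realism; turn off for moment checks of the raw model.
    """

    sigma_8bit: float = 25.0
    r: float = 0.5
    seed: int = 0
    clip: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma_8bit) or self.sigma_8bit < 0:
            raise ValueError(f"sigma_8bit must be finite and >= 0, got {self.sigma_8bit}")
        if not np.isfinite(self.r) or self.r < 0:
            raise ValueError(f"r must be finite and >= 0, got {self.r}")

    def sigma_on(self, scale: Scale) -> float:
        """Effective noise deviation on the given intensity scale."""
        return self.sigma_8bit / 255.0 if scale is Scale.UNIT else float(self.sigma_8bit)


def _rng_for(params: SpeckleParams, stream: int = 0) -> np.random.Generator:
    # named substream: corruption owns stream 0; corrupt_dataset derives one
    # stream per image index so dataset order cannot silently change the noise
    return np.random.default_rng(np.random.SeedSequence([int(params.seed) & 0x7FFFFFFF, 0x5BEC, stream]))


def add_speckle(
    image: GrayImage,
    params: SpeckleParams,
    rng: np.random.Generator | None = None,
) -> GrayImage:
    """Corrupt ``image`` with brightness-coupled Gaussian speckle.

    Returns ``v = u + u^r * theta`` with ``theta ~ N(0, sigma^2)`` drawn i.i.d.
    per pixel from the seeded generator, same shape and scale as the input,
    clipped to the scale's range iff ``params.clip``.
    """
    u = image.pixels
    if params.r != int(params.r) and np.any(u < 0):
        raise ValueError("negative intensities are not in the domain of u**r for non-integer r")
    if rng is None:
        rng = _rng_for(params)
    sigma = params.sigma_on(image.scale)
    if sigma == 0.0:
        return image
    # u**r with the u=0, r>0 limit defined as 0
    if params.r == 0.0:
        amplitude = np.ones_like(u)
    else:
        amplitude = np.power(u, params.r, where=u > 0, out=np.zeros_like(u))
    theta = rng.normal(0.0, sigma, size=u.shape)
    v = u + amplitude * theta
    out = GrayImage(v, image.scale)
    return out.clipped() if params.clip else out


def corrupt_dataset(
    images: list[GrayImage],
    params: SpeckleParams,
) -> list[tuple[GrayImage, GrayImage]]:
    """Corrupt a dataset, returning index-aligned ``(clean, noisy)`` pairs.

    Per-image noise streams are independent but jointly reproducible from
    ``params.seed``: image ``i`` always receives substream ``i`` regardless of
    how many images are in the list.
    """
    if not images:
        raise ValueError("corrupt_dataset requires a nonempty image list")
    pairs = []
    for i, img in enumerate(images):
        rng = _rng_for(params, stream=i + 1)
        pairs.append((img, add_speckle(img, params, rng=rng)))
    return pairs
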