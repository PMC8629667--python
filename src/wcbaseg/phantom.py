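"""Seeded synthetic lung-slice phantoms with exact ground-truth masks.

A phantom is a piecewise-constant composite — dark border background, a
bright elliptical body, two dark elliptical lung fields and one tumor
blob inside a lung — modulated by per-region multiplicative textures
(smoothed seeded white noise, so the texture dictionary has a genuine
spatial-correlation signal), then corrupted by additive Gaussian noise
and salt-and-pepper impulses.  All randomness flows from the single
spec seed through named substreams, so the texture, Gaussian and
impulse components are independently reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse

__all__ = ["Ellipse", "PhantomSpec", "generate", "default_suite"]


@dataclasses.dataclass(frozen=True)
class Ellipse:
    """Rotated ellipse: center (row, col), semi-axes (row, col), rotation in radians."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float = 0.0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = draw_ellipse(
            self.center[0],
            self.center[1],
            self.semi_axes[0],
            self.semi_axes[1],
            shape=shape,
            rotation=self.rotation,
        )
        mask = np.zeros(shape, dtype=bool)
        mask[rr, cc] = True
        return mask


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic slice.

    ``texture_grain`` maps region name ("body", "lung", "tumor") to the
    Gaussian correlation length (pixels) of that region's multiplicative
    texture; a grain of 0 disables texture for the region.
    ``texture_amplitude`` maps region name to the relative intensity
    modulation depth of its texture.
    """

    size: tuple[int, int] = (128, 128)
    background_mean: float = 0.05
    body_mean: float = 0.55
    lung_mean: float = 0.25
    tumor_mean: float = 0.60
    body_ellipse: Ellipse = Ellipse((64.0, 64.0), (58.0, 62.0))
    lung_ellipses: tuple[Ellipse, Ellipse] = (
        Ellipse((64.0, 38.0), (42.0, 22.0), 0.08),
        Ellipse((64.0, 90.0), (42.0, 22.0), -0.08),
    )
    tumor: Ellipse = Ellipse((64.0, 90.0), (24.0, 14.0), 0.30)
    texture_grain: tuple[tuple[str, float], ...] = (("body", 1.5), ("lung", 1.2), ("tumor", 2.5))
    texture_amplitude: tuple[tuple[str, float], ...] = (
        ("body", 0.15),
        ("lung", 0.15),
        ("tumor", 0.15),
    )
    gaussian_sigma: float = 0.01
    impulse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.impulse_rate < 0.5:
            raise ValueError(f"impulse_rate must be in [0, 0.5), got {self.impulse_rate}")
        for name in ("background_mean", "body_mean", "lung_mean", "tumor_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        body, lungs, tumor = self.masks()
        if not tumor.any():
            raise ValueError("tumor ellipse rasterizes to an empty mask")
        if (tumor & ~lungs).any():
            raise ValueError("tumor ellipse must lie fully inside a lung ellipse")
        if (lungs & ~body).any():
            raise ValueError("lung ellipses must lie inside the body")
        l0 = self.lung_ellipses[0].rasterize(self.size)
        l1 = self.lung_ellipses[1].rasterize(self.size)
        if (l0 & l1).any():
            raise ValueError("lung ellipses must be disjoint")

    def grain(self, region: str) -> float:
        return dict(self.texture_grain).get(region, 0.0)

    def amplitude(self, region: str) -> float:
        return dict(self.texture_amplitude).get(region, 0.0)

    def masks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Exact (body, lobe, tumor) boolean masks; tumor ⊆ lobe ⊆ body."""
        body = self.body_ellipse.rasterize(self.size)
        lobe = self.lung_ellipses[0].rasterize(self.size) | self.lung_ellipses[1].rasterize(self.size)
        tumor = self.tumor.rasterize(self.size)
        return body, lobe, tumor


def _texture(shape: tuple[int, int], grain: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance smoothed white noise with the given grain."""
    noise = rng.standard_normal(shape)
    if grain <= 0:
        return noise
    smooth = ndimage.gaussian_filter(noise, sigma=grain, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def generate(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render a phantom.

    Returns ``(image, lobe_mask, tumor_mask)``; the image is a [0, 1]
    float64 array, the masks are exact uint8 rasterizations of the lung
    and tumor ellipses (the tumor is part of the lobe mask).
    """
    body, lobe, tumor = spec.masks()
    lung_only = lobe & ~tumor
    body_only = body & ~lobe

    image = np.full(spec.size, spec.background_mean, dtype=np.float64)
    image[body_only] = spec.body_mean
    image[lung_only] = spec.lung_mean
    image[tumor] = spec.tumor_mean

    tex_ss, gauss_ss, imp_ss = np.random.SeedSequence(spec.seed).spawn(3)
    tex_rng = np.random.default_rng(tex_ss)
    for region, mask in (("body", body_only), ("lung", lung_only), ("tumor", tumor)):
        grain = spec.grain(region)
        amplitude = spec.amplitude(region)
        if grain > 0 and amplitude > 0:
            tex = _texture(spec.size, grain, tex_rng)
            image[mask] *= 1.0 + amplitude * tex[mask]

    if spec.gaussian_sigma > 0:
        image += np.random.default_rng(gauss_ss).normal(0.0, spec.gaussian_sigma, spec.size)

    if spec.impulse_rate > 0:
        imp_rng = np.random.default_rng(imp_ss)
        n = image.size
        n_hit = int(round(spec.impulse_rate * n))
        flat_idx = imp_rng.choice(n, size=n_hit, replace=False)
        values = imp_rng.integers(0, 2, size=n_hit).astype(np.float64)
        image.flat[flat_idx] = values

    np.clip(image, 0.0, 1.0, out=image)
    return image, lobe.astype(np.uint8), tumor.astype(np.uint8)


def default_suite(seed: int = 0) -> list[tuple[PhantomSpec, str]]:
    """The fixed three-member phantom suite.

    * ``easy`` — the tumor is intensity-separated from the lung field.
    * ``texture`` — tumor and lung share the same mean intensity: the
      tumor is a nearly solid (weakly textured) nodule inside strongly
      mottled parenchyma, so intensity thresholding cannot find it and
      only the patch-scale texture statistics carry the boundary.
    * ``noisy`` — intensity-separated but with 5% salt-and-pepper
      impulses and stronger Gaussian noise, exercising the median filter.
    """
    base = np.random.SeedSequence(seed).generate_state(3) % (2**31)
    easy = PhantomSpec(seed=int(base[0]))
    texture = dataclasses.replace(
        easy,
        tumor_mean=easy.lung_mean,
        texture_grain=(("body", 1.5), ("lung", 1.5), ("tumor", 2.5)),
        texture_amplitude=(("body", 0.15), ("lung", 0.40), ("tumor", 0.05)),
        seed=int(base[1]),
    )
    noisy = dataclasses.replace(
        easy,
        gaussian_sigma=0.03,
        impulse_rate=0.05,
        seed=int(base[2]),
    )
    return [(easy, "easy"), (texture, "texture"), (noisy, "noisy")]
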