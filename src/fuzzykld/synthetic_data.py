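"""Synthetic data generators: mixture samples, leaf images, jittered vectors.

The mixture sampler reproduces the simulation settings used to study
mixture estimation (two-component normal mixtures N(−1, 1²) ⊕ N(2, 2²)
under 50/50 and 90/10 weights, and gamma mixtures of G(3; 2) and
G(4; 7)); helper constructors for those settings are provided.

The leaf generator emulates per-class shape and texture variation in
leaf photographs: a superellipse silhouette with a jagged (sinusoidal)
margin, a midrib with angled side veins, and pixel noise.  It is
deliberately simple — its purpose is to give the feature and classifier
stages class-separable, image-shaped input, not botanical realism.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .parametric import ParametricDistribution, make_distribution

__all__ = [
    "LeafSpec",
    "gen_mixture_sample",
    "normal_mixture_spec",
    "gamma_mixture_spec",
    "gen_leaf_images",
    "default_leaf_classes",
    "gen_fuzzy_dataset",
]


# --------------------------------------------------------------------------
# mixture samples


def gen_mixture_sample(spec, n: int, seed=None):
    """Draw n values from a mixture of parametric components.

    ``spec`` is a list of (weight, family, params); weights must sum
    to 1.  Returns (values, component labels).
    """
    weights = np.array([w for w, _, _ in spec], dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(len(spec), size=n, p=weights / weights.sum())
    values = np.empty(n)
    for k, (_, family, params) in enumerate(spec):
        mask = labels == k
        cnt = int(mask.sum())
        if cnt:
            d = make_distribution(family, params)
            values[mask] = d.dist.rvs(size=cnt, random_state=rng)
    return values, labels


def normal_mixture_spec(w1: float = 0.5):
    """Two-component normal mixture N(−1, 1²) and N(2, 2²) with weight w1."""
    return [
        (w1, "normal", {"mean": -1.0, "sd": 1.0}),
        (1.0 - w1, "normal", {"mean": 2.0, "sd": 2.0}),
    ]


def gamma_mixture_spec(w1: float = 0.5):
    """Two-component gamma mixture G(3; 2) and G(4; 7) with weight w1."""
    return [
        (w1, "gamma", {"shape": 3.0, "scale": 2.0}),
        (1.0 - w1, "gamma", {"shape": 4.0, "scale": 7.0}),
    ]


# --------------------------------------------------------------------------
# leaf images


@dataclass(frozen=True)
class LeafSpec:
    """Parameters of one synthetic leaf class.

    exponent: superellipse exponent (2 = ellipse, large = boxy)
    aspect: width/length ratio of the blade, in (0, 1]
    jaggedness: relative amplitude of the sinusoidal margin, >= 0
    teeth: number of margin oscillations
    vein_count: side veins per half-blade
    vein_spread_deg: angle of side veins off the midrib
    vein_contrast: vein brightness lift, in [0, 1]
    ripple_amp: amplitude of blade corrugation shading, in [0, 1]
    ripple_freq: corrugation cycles across the blade
    blade_scale: blade half-length as a fraction of the frame, in (0, 0.5]
    noise_sd: pixel noise standard deviation (on a 0..1 scale)
    size: square image side in pixels (>= 32)
    jitter: relative per-image parameter jitter
    """

    label: str
    exponent: float = 2.0
    aspect: float = 0.55
    jaggedness: float = 0.0
    teeth: int = 9
    vein_count: int = 4
    vein_spread_deg: float = 45.0
    vein_contrast: float = 0.25
    ripple_amp: float = 0.0
    ripple_freq: float = 8.0
    blade_scale: float = 0.40
    noise_sd: float = 0.02
    size: int = 64
    jitter: float = 0.08

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("image size must be >= 32")
        if min(self.exponent, self.aspect) <= 0:
            raise ValueError("exponent and aspect must be positive")
        if not 0.0 < self.blade_scale <= 0.5:
            raise ValueError("blade_scale must lie in (0, 0.5]")
        if min(self.jaggedness, self.vein_contrast, self.ripple_amp,
               self.noise_sd, self.jitter) < 0:
            raise ValueError("jaggedness, vein_contrast, ripple_amp, "
                             "noise_sd, jitter must be non-negative")


def _render_leaf(spec: LeafSpec, rng: np.random.Generator) -> np.ndarray:
    """Rasterize one leaf with per-image parameter jitter; uint8 output."""
    j = spec.jitter

    def jit(v, lo=1e-3):
        return max(lo, v * (1.0 + j * rng.uniform(-1, 1)))

    p = jit(spec.exponent)
    aspect = min(jit(spec.aspect), 1.0)
    jag = spec.jaggedness * (1.0 + j * rng.uniform(-1, 1))
    phase = rng.uniform(0, 2 * np.pi)
    rot = rng.uniform(-0.35, 0.35)
    scale = spec.blade_scale * (1.0 + 0.5 * j * rng.uniform(-1, 1))

    N = spec.size
    yy, xx = np.mgrid[0:N, 0:N]
    u = (xx - (N - 1) / 2) / N
    v = (yy - (N - 1) / 2) / N
    # rotate into the leaf frame; x along the midrib
    c, s = np.cos(rot), np.sin(rot)
    lx = c * u + s * v
    ly = -s * u + c * v

    a, b = scale, scale * aspect
    r = (np.abs(lx / a) ** p + np.abs(ly / b) ** p)
    phi = np.arctan2(ly, lx)
    margin = 1.0 + jag * np.sin(spec.teeth * phi + phase)
    inside = r <= margin

    img = np.full((N, N), 0.15)
    img[inside] = 0.55

    # midrib + side veins: bright thin ridges inside the blade
    width = 0.012
    vein = np.zeros_like(img)
    vein += np.exp(-(ly / width) ** 2)  # midrib along lx
    angle = np.radians(spec.vein_spread_deg * (1.0 + 0.3 * j * rng.uniform(-1, 1)))
    for k in range(1, spec.vein_count + 1):
        x0 = (k / (spec.vein_count + 1) - 0.5) * 2 * a * 0.9
        for sgn in (1.0, -1.0):
            # distance to a line through (x0, 0) at +/- angle off the midrib
            d = np.abs(np.sin(angle) * (lx - x0) - sgn * np.cos(angle) * ly)
            reach = np.abs(ly) < b  # only near the blade
            vein += np.where(reach, np.exp(-(d / width) ** 2), 0.0)
    img += spec.vein_contrast * np.clip(vein, 0, 1) * inside

    if spec.ripple_amp > 0:
        freq = spec.ripple_freq * (1.0 + 0.3 * j * rng.uniform(-1, 1))
        img += spec.ripple_amp * 0.5 * np.sin(
            2 * np.pi * freq * ly + rng.uniform(0, 2 * np.pi)) * inside

    img += rng.normal(0, spec.noise_sd, size=img.shape)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)


def gen_leaf_images(specs, per_class: int, seed=None, outdir=None):
    """Generate ``per_class`` leaf images for every spec.

    Returns (images, labels): a list of uint8 arrays and parallel label
    list.  With ``outdir``, each image is also written as
    ``<label>_<index>.png`` (deterministic bytes for a fixed seed).
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for spec in specs:
        for i in range(per_class):
            img = _render_leaf(spec, rng)
            images.append(img)
            labels.append(spec.label)
            if outdir is not None:
                from PIL import Image
                import os

                Image.fromarray(img).save(
                    os.path.join(outdir, f"{spec.label}_{i:03d}.png"))
    return images, labels


def default_leaf_classes(size: int = 64):
    """Four well-separated class presets spanning shape and texture.

    The classes are spaced along the axis that drives the distribution
    of block-normalized gradient descriptors — the balance of isotropic,
    oriented and silent image regions: a broad matte blade (isotropic
    grain everywhere), a toothed blade (margin edges plus moderate
    veins), a narrow heavily-veined blade (strong thin ridges), and a
    corrugated blade (coherent low-frequency shading ripples).
    """
    return [
        LeafSpec("matte", exponent=6.0, aspect=0.9, jaggedness=0.03,
                 teeth=6, vein_count=0, vein_contrast=0.0, blade_scale=0.5,
                 noise_sd=0.15, size=size),
        LeafSpec("toothed", exponent=2.5, aspect=0.6, jaggedness=0.22,
                 teeth=14, vein_count=6, vein_contrast=0.35, noise_sd=0.06,
                 size=size),
        LeafSpec("veined", exponent=2.0, aspect=0.4, jaggedness=0.02,
                 teeth=8, vein_count=10, vein_contrast=0.6, blade_scale=0.45,
                 noise_sd=0.03, size=size),
        LeafSpec("corrugated", exponent=8.0, aspect=0.95, jaggedness=0.0,
                 vein_count=0, vein_contrast=0.0, ripple_amp=0.6,
                 ripple_freq=3.0, blade_scale=0.5, noise_sd=0.01, size=size),
    ]


# --------------------------------------------------------------------------
# jittered feature vectors


def gen_fuzzy_dataset(base, spread: float, n: int, seed=None):
    """n jittered copies of a base vector, for profile construction.

    Each copy is base + uniform(−spread, spread) noise per position.
    """
    if spread < 0:
        raise ValueError("spread must be non-negative")
    if n < 2:
        raise ValueError("need n >= 2 copies")
    base = np.asarray(base, dtype=float)
    rng = np.random.default_rng(seed)
    return [base + rng.uniform(-spread, spread, size=base.shape)
            for _ in range(n)]
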