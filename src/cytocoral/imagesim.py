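"""Seeded synthetic multi-cell cytology image generator.

Images mimic liquid-preparation Pap micrographs at a desk-friendly scale:
pale background, elliptical cytoplasm blobs, darker nuclei whose relative
area and boundary irregularity increase with Bethesda severity.  Every image
carries its ground-truth cytoplasm and nucleus masks so that downstream
tests can measure morphology directly instead of eyeballing pixels.

Determinism contract: per-cell geometry is drawn from child seeds derived
from ``(seed, cell index)``, so two renders of the same seed that differ
only in photometric style or cell density share the geometry of the cells
they have in common.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from skimage import color as skcolor

from .errors import DomainError
from .types import (
    BethesdaClass,
    LabeledImage,
    MorphologyParams,
    PreparationStyle,
    SOURCE_STYLE,
    TARGET_STYLE,
)

DEFAULT_RESOLUTION = 96
DEFAULT_MORPHOLOGY = MorphologyParams()

_BACKGROUND_RGB = np.array([0.93, 0.89, 0.93], dtype=np.float32)
_CYTOPLASM_RGB = np.array([0.74, 0.67, 0.84], dtype=np.float32)
_NUCLEUS_RGB = np.array([0.33, 0.18, 0.46], dtype=np.float32)
_BASE_NOISE_SIGMA = 0.015


def _cell_geometry(rng: np.random.Generator, size: int, params: MorphologyParams,
                   cls: BethesdaClass, prev_centers: list[tuple[float, float]]):
    """Draw one cell's placement, cytoplasm ellipse and nucleus boundary."""
    cluster_p = params.cluster_tendency[int(cls)]
    if prev_centers and rng.random() < cluster_p:
        cy0, cx0 = prev_centers[rng.integers(len(prev_centers))]
        cy = np.clip(cy0 + rng.normal(0, 0.10 * size), 0, size - 1)
        cx = np.clip(cx0 + rng.normal(0, 0.10 * size), 0, size - 1)
    else:
        cy = rng.uniform(0.12, 0.88) * size
        cx = rng.uniform(0.12, 0.88) * size
    r_cyto = rng.uniform(0.09, 0.15) * size
    aspect = rng.uniform(0.70, 1.0)
    theta0 = rng.uniform(0, np.pi)
    frac_mean = params.nuclear_area_fraction_mean[int(cls)]
    frac = float(np.clip(rng.normal(frac_mean, 0.18 * frac_mean), 0.02, 0.95))
    irr = params.nuclear_irregularity[int(cls)]
    # low-order radial harmonics perturbing the nuclear boundary
    harmonics = [(k, rng.normal(0, 0.6 / k), rng.uniform(0, 2 * np.pi))
                 for k in range(2, 6)]
    cyto_jitter = rng.normal(0, 0.03, size=3)
    nuc_jitter = rng.normal(0, 0.03, size=3)
    return dict(cy=cy, cx=cx, r_cyto=r_cyto, aspect=aspect, theta0=theta0,
                frac=frac, irr=irr, harmonics=harmonics,
                cyto_jitter=cyto_jitter, nuc_jitter=nuc_jitter)


def _render_cell(canvas: np.ndarray, cell_mask: np.ndarray, nucleus_mask: np.ndarray,
                 g: dict) -> None:
    size = canvas.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    dy, dx = yy - g["cy"], xx - g["cx"]
    ct, st = np.cos(g["theta0"]), np.sin(g["theta0"])
    u = ct * dx + st * dy
    v = -st * dx + ct * dy
    rho = np.sqrt((u / g["r_cyto"]) ** 2 + (v / (g["r_cyto"] * g["aspect"])) ** 2)
    cyto = rho <= 1.0
    # nucleus: scaled copy of the ellipse with a perturbed radial boundary
    r_nuc_scale = np.sqrt(g["frac"])
    ang = np.arctan2(v, u)
    boundary = np.ones_like(ang)
    for k, amp, phase in g["harmonics"]:
        boundary = boundary + g["irr"] * amp * np.cos(k * ang + phase)
    boundary = np.clip(boundary, 0.35, 1.8)
    nuc = rho <= r_nuc_scale * boundary
    nuc &= cyto
    cyto_rgb = np.clip(_CYTOPLASM_RGB + g["cyto_jitter"], 0.0, 1.0)
    nuc_rgb = np.clip(_NUCLEUS_RGB + g["nuc_jitter"], 0.0, 1.0)
    canvas[cyto] = cyto_rgb
    canvas[nuc] = nuc_rgb
    cell_mask |= cyto
    nucleus_mask |= nuc


def synth_cell_image(label: BethesdaClass, style: PreparationStyle = SOURCE_STYLE,
                     seed: int = 0, *, size: int = DEFAULT_RESOLUTION,
                     params: MorphologyParams = DEFAULT_MORPHOLOGY) -> LabeledImage:
    """Render one multi-cell image for ``label`` under ``style``.

    Deterministic for fixed arguments.  The returned image carries its
    ground-truth cytoplasm and nucleus masks.
    """
    try:
        label = BethesdaClass(label)
    except ValueError:
        raise DomainError(f"invalid Bethesda label: {label!r}") from None
    if seed < 0:
        raise DomainError("seed must be non-negative")
    if size < 16:
        raise DomainError("size must be >= 16")

    master = np.random.SeedSequence([int(seed), int(label)])
    count_rng = np.random.Generator(np.random.PCG64(master.spawn(1)[0]))
    lo, hi = params.cell_count_range
    raw_count = int(count_rng.integers(lo, hi + 1))
    count = max(1, int(round(raw_count * style.density_scale)))

    canvas = np.tile(_BACKGROUND_RGB, (size, size, 1)).astype(np.float64)
    cell_mask = np.zeros((size, size), dtype=bool)
    nucleus_mask = np.zeros((size, size), dtype=bool)

    centers: list[tuple[float, float]] = []
    for i in range(count):
        child = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(seed), int(label), 101 + i])))
        g = _cell_geometry(child, size, params, label, centers)
        _render_cell(canvas, cell_mask, nucleus_mask, g)
        centers.append((g["cy"], g["cx"]))

    noise_rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([int(seed), int(label), 7_000_003])))
    if style.background_texture > 0:
        # base draws are style-independent; the style only scales amplitude
        canvas += noise_rng.normal(0.0, _BASE_NOISE_SIGMA, canvas.shape) \
            * style.background_texture
    canvas = np.clip(canvas, 0.0, 1.0)

    img = LabeledImage(pixels=canvas.astype(np.float32), label=label,
                       domain=style.domain, cell_mask=cell_mask,
                       nucleus_mask=nucleus_mask)
    if not style.is_photometric_identity:
        img = apply_preparation_shift(img, style)
    return img


def apply_preparation_shift(image: LabeledImage, style: PreparationStyle) -> LabeledImage:
    """Apply a style's photometric transform (hue rotation then contrast).

    The source baseline is the identity.  The label is always preserved;
    output intensities are clipped to [0,1].  Geometry (and therefore any
    ground-truth masks) is untouched — density and background texture act
    at generation time, not here.
    """
    out = image.copy_with(domain=style.domain)
    if style.is_photometric_identity:
        return out
    px = out.pixels.astype(np.float64)
    if style.stain_hue_shift != 0.0:
        hsv = skcolor.rgb2hsv(px)
        hsv[..., 0] = (hsv[..., 0] + style.stain_hue_shift / 360.0) % 1.0
        px = skcolor.hsv2rgb(hsv)
    if style.contrast_scale != 1.0:
        px = px * style.contrast_scale
    return out.copy_with(pixels=np.clip(px, 0.0, 1.0).astype(np.float32))


def synth_dataset(class_counts: Mapping[BethesdaClass, int],
                  style: PreparationStyle = SOURCE_STYLE, seed: int = 0, *,
                  size: int = DEFAULT_RESOLUTION,
                  params: MorphologyParams = DEFAULT_MORPHOLOGY) -> list[LabeledImage]:
    """Generate ``class_counts[c]`` images per class under ``style``.

    Per-image seeds are derived deterministically from the master seed,
    class and index, so regeneration is order-independent and reproducible.
    """
    images: list[LabeledImage] = []
    for cls in sorted(class_counts, key=int):
        n = class_counts[cls]
        if n < 0:
            raise DomainError(f"negative count for {cls}: {n}")
        cls = BethesdaClass(cls)
        for i in range(n):
            ss = np.random.SeedSequence([int(seed), int(cls), i])
            child_seed = int(ss.generate_state(1, dtype=np.uint32)[0])
            images.append(synth_cell_image(cls, style, child_seed,
                                           size=size, params=params))
    return images


def pooled_pixel_features(images: Sequence[LabeledImage], pool: int = 16) -> np.ndarray:
    """Stack images into an (n, d) raw-pixel feature matrix.

    Each image is block-average-pooled by ``pool`` and flattened; used to
    quantify domain shift at the pixel level without any trained network.
    """
    rows = []
    for im in images:
        h, w, c = im.pixels.shape
        hh, ww = h // pool * pool, w // pool * pool
        px = im.pixels[:hh, :ww].reshape(hh // pool, pool, ww // pool, pool, c)
        rows.append(px.mean(axis=(1, 3)).ravel())
    return np.asarray(rows, dtype=np.float64)


__all__ = [
    "DEFAULT_RESOLUTION", "DEFAULT_MORPHOLOGY", "SOURCE_STYLE", "TARGET_STYLE",
    "synth_cell_image", "synth_dataset", "apply_preparation_shift",
    "pooled_pixel_features",
]
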