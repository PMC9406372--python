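"""Core domain types: Bethesda classes, preparation styles, labeled images."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import DomainError


class BethesdaClass(enum.IntEnum):
    """The four Bethesda reporting categories, ordered by severity."""

    NILM = 0
    LSIL = 1
    HSIL = 2
    SCC = 3

    @classmethod
    def from_string(cls, s: str) -> "BethesdaClass":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise DomainError(f"unknown Bethesda label: {s!r}") from None


#: Severity order, i.e. list(BethesdaClass)
CLASSES = tuple(BethesdaClass)
N_CLASSES = len(CLASSES)


@dataclass(frozen=True)
class MorphologyParams:
    """Class-dependent nuclear/cytoplasm geometry knobs for the simulator.

    ``nuclear_area_fraction_mean`` and ``nuclear_irregularity`` are indexed
    by severity and must increase monotonically with it so that the rendered
    morphology carries a learnable class signal.
    """

    cell_count_range: tuple[int, int] = (5, 10)
    nuclear_area_fraction_mean: tuple[float, ...] = (0.10, 0.22, 0.40, 0.58)
    nuclear_irregularity: tuple[float, ...] = (0.04, 0.12, 0.25, 0.40)
    cluster_tendency: tuple[float, ...] = (0.20, 0.30, 0.45, 0.55)

    def __post_init__(self) -> None:
        fr = self.nuclear_area_fraction_mean
        if len(fr) != N_CLASSES or any(not (0.0 < f < 1.0) for f in fr):
            raise DomainError("nuclear area fractions must be 4 values in (0,1)")
        if any(a >= b for a, b in zip(fr, fr[1:])):
            raise DomainError("nuclear area fraction must strictly increase with severity")
        irr = self.nuclear_irregularity
        if any(a > b for a, b in zip(irr, irr[1:])):
            raise DomainError("nuclear irregularity must be non-decreasing with severity")
        lo, hi = self.cell_count_range
        if lo < 1 or hi < lo:
            raise DomainError("invalid cell_count_range")


@dataclass(frozen=True)
class PreparationStyle:
    """Photometric/density rendering style of one slide-preparation method.

    The source style is the identity baseline; the target style deviates from
    it (stain hue rotation, contrast scaling, sparser cells, noisier
    background) to emulate a cross-preparation domain gap.
    """

    domain: str = "source"
    stain_hue_shift: float = 0.0      # degrees of hue rotation
    contrast_scale: float = 1.0       # multiplicative intensity scaling
    density_scale: float = 1.0        # multiplier on the sampled cell count
    background_texture: float = 1.0   # multiplier on background noise sigma

    def __post_init__(self) -> None:
        if self.domain not in ("source", "target"):
            raise DomainError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.contrast_scale <= 0 or self.density_scale <= 0 or self.background_texture < 0:
            raise DomainError("style multipliers must be positive")

    @property
    def is_photometric_identity(self) -> bool:
        return self.stain_hue_shift == 0.0 and self.contrast_scale == 1.0


SOURCE_STYLE = PreparationStyle(domain="source")
TARGET_STYLE = PreparationStyle(
    domain="target",
    stain_hue_shift=20.0,
    contrast_scale=1.3,
    density_scale=0.7,
    background_texture=2.0,
)


@dataclass
class LabeledImage:
    """An RGB image with its Bethesda label and preparation domain.

    ``cell_mask``/``nucleus_mask`` are the generator's ground-truth masks;
    they are absent for images loaded from disk.  ``source_id`` and
    ``transform`` record augmentation provenance.
    """

    pixels: np.ndarray
    label: BethesdaClass
    domain: str = "source"
    split: str = ""
    path: Optional[str] = None
    cell_mask: Optional[np.ndarray] = None
    nucleus_mask: Optional[np.ndarray] = None
    source_id: Optional[int] = None
    transform: Optional[object] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 3 or px.shape[2] != 3:
            raise DomainError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise DomainError("image must be at least 16x16")
        if px.min() < 0.0 or px.max() > 1.0:
            raise DomainError("intensities must lie in [0,1]")
        object.__setattr__(self, "pixels", px)
        self.label = BethesdaClass(self.label)

    def copy_with(self, **kw) -> "LabeledImage":
        return replace(self, **kw)

    @property
    def nuclear_area_fraction(self) -> float:
        """Measured nucleus/cytoplasm area ratio from the ground-truth masks."""
        if self.cell_mask is None or self.nucleus_mask is None:
            raise DomainError("image carries no ground-truth masks")
        cell = int(self.cell_mask.sum())
        return float(self.nucleus_mask.sum()) / cell if cell else 0.0
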