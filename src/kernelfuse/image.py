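"""Core in-memory container for a single CT slice in Hounsfield units."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Allowed provenance tags for a :class:`CTImage`.
PROVENANCE_TAGS = ("ground-truth", "simulated", "model-output", "clinical")


@dataclass
class CTImage:
    """A 2D grid of HU values with physical pixel spacing and series metadata.

    Parameters
    ----------
    pixels
        2D float array of Hounsfield units.
    spacing
        Isotropic in-plane pixel spacing in mm (> 0).
    thickness
        Slice thickness in mm (> 0).
    kernel
        Reconstruction kernel class, ``"smooth"`` or ``"sharp"`` (or ``None``
        for kernel-less images such as the noise-free ground truth).
    dose
        Dose fraction relative to routine dose, in (0, 1].
    provenance
        One of ``ground-truth | simulated | model-output | clinical``.
    """

    pixels: np.ndarray
    spacing: float
    thickness: float = 0.75
    kernel: str | None = None
    dose: float = 1.0
    provenance: str = "simulated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.spacing <= 0:
            raise ValueError(f"spacing must be > 0, got {self.spacing}")
        if self.thickness <= 0:
            raise ValueError(f"thickness must be > 0, got {self.thickness}")
        if not (0 < self.dose <= 1):
            raise ValueError(f"dose fraction must be in (0, 1], got {self.dose}")
        if self.kernel is not None and self.kernel not in ("smooth", "sharp"):
            raise ValueError(f"kernel must be 'smooth' or 'sharp', got {self.kernel!r}")
        if self.provenance not in PROVENANCE_TAGS:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, **changes) -> "CTImage":
        """Copy of this image with new pixel data (metadata preserved)."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.float64), **changes)

    def grid_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (y, x) coordinate grids in mm, origin at the grid centre."""
        ny, nx = self.pixels.shape
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing
        return np.meshgrid(y, x, indexing="ij")
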