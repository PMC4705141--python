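"""The 17-layer environmental predictor stack.

Layers (all 30 m, co-aligned): fractional covers FC / NPV / bare (summing
to one), categorical vegetation type, terrain (elevation, slope, aspect),
six climate surfaces (MAP, wind, VPD, solar, RH, cloud frequency) and four
fire-regime layers (LFS, MFS, RFS, MFRI).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import RasterGrid

__all__ = ["PREDICTOR_NAMES", "PREDICTOR_ROLES", "PredictorStack"]

PREDICTOR_NAMES: tuple[str, ...] = (
    "FC", "NPV", "bare", "veg_type", "elevation", "slope", "aspect",
    "MAP", "wind", "VPD", "solar", "RH", "cloud",
    "LFS", "MFS", "RFS", "MFRI",
)

PREDICTOR_ROLES: dict[str, str] = {
    name: ("categorical" if name == "veg_type" else "continuous")
    for name in PREDICTOR_NAMES
}


@dataclass
class PredictorStack:
    layers: dict[str, RasterGrid]
    roles: dict[str, str] = field(default_factory=lambda: dict(PREDICTOR_ROLES))

    def __post_init__(self) -> None:
        names = list(self.layers)
        missing = [n for n in names if n not in self.roles]
        if missing:
            raise ValueError(f"layers without a declared role: {missing}")
        ref = self.layers[names[0]]
        for n in names[1:]:
            ref.require_aligned(self.layers[n], f"predictor layer {n!r}")

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> RasterGrid:
        """Reference grid (first layer) defining the shared georeferencing."""
        return next(iter(self.layers.values()))

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells where every layer is valid."""
        mask = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.valid_mask
        return mask

    def require_canonical(self) -> None:
        if tuple(self.layers) != PREDICTOR_NAMES:
            raise ValueError(
                f"expected the canonical {len(PREDICTOR_NAMES)}-layer stack, "
                f"got {list(self.layers)}")
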