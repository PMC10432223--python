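"""The localization cloud: fluorophore positions with per-axis precisions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LocalizationCloud:
    """A set of 3D single-molecule localizations.

    Attributes
    ----------
    positions : (N, 3) float array
        Localization coordinates in nm.
    sigmas : (N, 3) float array
        Per-axis localization precision (sigma_x, sigma_y, sigma_z) in nm,
        one triple per localization. Axial precision may differ from lateral
        (astigmatic 3D) or match it (4Pi geometries).
    """

    positions: np.ndarray
    sigmas: np.ndarray

    def __post_init__(self):
        pos = np.ascontiguousarray(self.positions, dtype=np.float64)
        sig = np.ascontiguousarray(self.sigmas, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if sig.shape != pos.shape:
            raise ValueError("sigmas must match positions shape (N, 3)")
        if len(pos) < 1:
            raise ValueError("at least one localization required")
        if not np.isfinite(pos).all():
            raise ValueError("positions contain non-finite values")
        if not np.isfinite(sig).all() or (sig <= 0).any():
            raise ValueError("all sigma components must be finite and > 0")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "sigmas", sig)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) axis-aligned bounding box [min; max], nm."""
        return np.stack([self.positions.min(axis=0), self.positions.max(axis=0)])

    def subset(self, index) -> "LocalizationCloud":
        return LocalizationCloud(self.positions[index], self.sigmas[index])
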