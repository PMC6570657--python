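"""Acquisition and geometry parameters shared across the pipeline.

Defaults reflect single-molecule TIRF imaging of rod outer-segment disc
membranes: 30 frames/s, 76 nm pixels, ~50 nm localization error, and an
8 µm circular disc (or a 1 × 2 µm rectangle mimicking a small lobule).
All lengths are micrometres, all times seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionParams", "DiscGeometry"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera/optics parameters of a tracking experiment.

    Parameters
    ----------
    frame_interval : float
        Time between frames in seconds (default 1/30 s).
    pixel_size : float
        Camera pixel size in µm (default 0.076 µm).
    localization_sigma : float
        Per-coordinate localization error (standard deviation) in µm
        (default 0.050 µm).
    """

    frame_interval: float = 1.0 / 30.0
    pixel_size: float = 0.076
    localization_sigma: float = 0.050

    def __post_init__(self) -> None:
        for name in ("frame_interval", "pixel_size", "localization_sigma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class DiscGeometry:
    """Confining geometry for membrane diffusion.

    ``shape`` is one of ``"disc"`` (circle of ``disc_diameter``),
    ``"rectangle"`` (``width`` × ``height``) or ``"unbounded"``.
    Coordinates are µm with the origin at ``centre``.
    """

    shape: str = "disc"
    disc_diameter: float = 8.0
    width: float = 1.0
    height: float = 2.0
    centre: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.shape not in ("disc", "rectangle", "unbounded"):
            raise ValueError(
                f"shape must be 'disc', 'rectangle' or 'unbounded', got {self.shape!r}"
            )
        for name in ("disc_diameter", "width", "height"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def radius(self) -> float:
        """Disc radius in µm (only meaningful for ``shape == 'disc'``)."""
        return self.disc_diameter / 2.0

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points (… , 2) inside the geometry."""
        xy = np.asarray(xy, dtype=float)
        rel = xy - np.asarray(self.centre)
        if self.shape == "unbounded":
            return np.ones(rel.shape[:-1], dtype=bool)
        if self.shape == "disc":
            return np.einsum("...i,...i->...", rel, rel) <= self.radius**2
        half = np.array([self.width / 2.0, self.height / 2.0])
        return np.all(np.abs(rel) <= half, axis=-1)

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` points uniformly inside the geometry (unbounded: unit box)."""
        c = np.asarray(self.centre, dtype=float)
        if self.shape == "disc":
            r = self.radius * np.sqrt(rng.uniform(size=n))
            theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
            return c + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        if self.shape == "rectangle":
            half = np.array([self.width / 2.0, self.height / 2.0])
            return c + rng.uniform(-half, half, size=(n, 2))
        return c + rng.uniform(-0.5, 0.5, size=(n, 2))
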