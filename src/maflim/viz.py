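"""Posterior-map overlay rendering.

The classifier's posterior probability map (red intensity scale) is
superposed on the total fluorescence intensity map (grey intensity
scale), so suspicious regions glow red while the underlying anatomy
stays visible.  Masked pixels render as plain grayscale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image as PILImage

from .classify import ProbabilityMap
from .core import ValidationError


@dataclass
class OverlaySpec:
    """How posterior and anatomy are blended.

    The output channel values at a pixel with posterior ``p`` and
    normalized gray luminance ``g`` are::

        R = (1 − p)·g + p·(red_floor + (1 − red_floor)·g)
        G = B = (1 − p)·g

    i.e. red scaled by the gray luminance, with a floor so that high
    posteriors stay visible over dark tissue.  ``p = 0`` reproduces the
    grayscale exactly; ``p = 1`` gives maximal red.
    """

    red_floor: float = 0.25
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.red_floor < 1):
            raise ValidationError("red_floor must lie in [0, 1)")


def render_overlay(
    pmap: ProbabilityMap,
    total_intensity: np.ndarray,
    spec: OverlaySpec | None = None,
    path=None,
) -> np.ndarray:
    """Render the overlay as an 8-bit RGB array (and optionally write it).

    The red channel is monotone in the posterior at fixed luminance;
    masked pixels show the grayscale background only.
    """
    spec = spec or OverlaySpec()
    total_intensity = np.asarray(total_intensity, dtype=float)
    if total_intensity.shape != pmap.p.shape:
        raise ValidationError(
            f"intensity map shape {total_intensity.shape} != posterior {pmap.p.shape}"
        )
    lo, hi = float(total_intensity.min()), float(total_intensity.max())
    g = (total_intensity - lo) / (hi - lo) if hi > lo else np.zeros_like(total_intensity)
    if spec.gamma != 1.0:
        g = g ** spec.gamma
    p = np.where(pmap.valid, np.nan_to_num(pmap.p), 0.0)
    red = (1 - p) * g + p * (spec.red_floor + (1 - spec.red_floor) * g)
    gb = (1 - p) * g
    rgb = np.stack([red, gb, gb], axis=-1)
    out = np.clip(np.round(rgb * 255), 0, 255).astype(np.uint8)
    if path is not None:
        PILImage.fromarray(out, mode="RGB").save(path)
    return out


def export_posterior_tiff(pmap: ProbabilityMap, path) -> None:
    """Write the posterior map as 16-bit grayscale TIFF (invalid pixels 0)."""
    p = np.where(pmap.valid, np.nan_to_num(pmap.p), 0.0)
    tifffile.imwrite(path, np.round(p * 65535).astype(np.uint16))
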