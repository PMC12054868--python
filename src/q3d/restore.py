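"""Image restoration: background division and small-scale denoising.

Light-sheet volumes of cleared tissue carry a smooth multiplicative
autofluorescence background plus per-voxel digitization noise from the
camera.  Restoration is three steps: (i) model the background by
Gaussian smoothing of the raw data at a scale larger than the objects of
interest but smaller than the background undulations; (ii) divide the
raw data by the background model, yielding a dimensionless ratio image
in which flat tissue sits near 1 and objects rise above it; (iii)
suppress voxel-level noise with a small Gaussian (scale ~1 voxel).

Restoration is not idempotent: applying it twice re-estimates a
background from an already-flat ratio image and re-smooths, so
``restore(restore(x)) != restore(x)`` in general.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ImageStack

#: Relative floor for the division guard: epsilon = RELATIVE_EPSILON * mean(raw).
RELATIVE_EPSILON = 1e-6


@dataclass(frozen=True)
class RestorationParams:
    """Scales for the two smoothing passes, in native voxels.

    ``background_scale`` (default 50) must exceed the typical object
    radius and stay below the scale of background undulations;
    ``noise_scale`` (default 1) models inter-voxel camera noise.  Both
    are Gaussian standard deviations by default; set
    ``scale_is_variance=True`` to interpret them as variances instead.
    ``epsilon`` guards the division; if None it is set per-volume to
    ``1e-6`` times the global mean intensity (scale-free).
    """

    background_scale: float = 50.0
    noise_scale: float = 1.0
    epsilon: float | None = None
    scale_is_variance: bool = False

    def __post_init__(self) -> None:
        if not self.background_scale > self.noise_scale > 0:
            raise ValueError("need background_scale > noise_scale > 0")
        if self.epsilon is not None and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def sigma(self, scale: float) -> float:
        return float(np.sqrt(scale)) if self.scale_is_variance else float(scale)


def _smooth(data: np.ndarray, sigma: float) -> np.ndarray:
    # reflective padding: avoids darkened rims that would bias detection
    # in edge regions
    return ndimage.gaussian_filter(
        data.astype(np.float64, copy=False), sigma=sigma, mode="reflect"
    )


def estimate_background(raw: ImageStack, background_scale: float,
                        scale_is_variance: bool = False) -> ImageStack:
    """Gaussian-smoothed background model of the raw volume."""
    if background_scale <= 0:
        raise ValueError("background_scale must be positive")
    sigma = np.sqrt(background_scale) if scale_is_variance else background_scale
    return ImageStack(
        data=_smooth(raw.data, float(sigma)), voxel_size_um=raw.voxel_size_um
    )


def normalize(raw: ImageStack, background: ImageStack,
              epsilon: float | None = None) -> ImageStack:
    """Divide raw by background, elementwise: ``raw / max(background, eps)``.

    The result is a dimensionless ratio field; flat input gives values
    near 1 and any global gain cancels.
    """
    if raw.shape != background.shape:
        raise ValueError(
            f"shape mismatch: raw {raw.shape} vs background {background.shape}"
        )
    if epsilon is None:
        mean = float(np.mean(raw.data))
        epsilon = RELATIVE_EPSILON * mean if mean > 0 else RELATIVE_EPSILON
    ratio = raw.data.astype(np.float64, copy=False) / np.maximum(
        background.data, epsilon
    )
    return ImageStack(data=ratio, voxel_size_um=raw.voxel_size_um)


def denoise(normalized: ImageStack, noise_scale: float,
            scale_is_variance: bool = False) -> ImageStack:
    """Small Gaussian smoothing of the ratio image (noise suppression)."""
    if noise_scale <= 0:
        raise ValueError("noise_scale must be positive")
    sigma = np.sqrt(noise_scale) if scale_is_variance else noise_scale
    return ImageStack(
        data=_smooth(normalized.data, float(sigma)),
        voxel_size_um=normalized.voxel_size_um,
    )


def restore(raw: ImageStack, params: RestorationParams | None = None) -> ImageStack:
    """Full restoration: background estimate, division, denoising."""
    params = params or RestorationParams()
    background = estimate_background(
        raw, params.background_scale, params.scale_is_variance
    )
    ratio = normalize(raw, background, params.epsilon)
    return denoise(ratio, params.noise_scale, params.scale_is_variance)
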