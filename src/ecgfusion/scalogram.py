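"""Morlet continuous-wavelet-transform scalogram images.

An ECG trace is convolved with complex Morlet wavelets (center angular
frequency omega0 = 6) at 32 logarithmically spaced scales between 1 and 64,
the coefficient magnitudes are min-max scaled to [0, 1], resampled to
128 x 128 by bilinear interpolation, and mapped to three channels through
the viridis colormap so the result matches the RGB input expected by the
image backbones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from matplotlib import colormaps
from skimage.transform import resize

from .ecg_io import EcgRecord, ValidationError

#: Morlet center angular frequency; fc = omega0 / (2*pi) cycles per unit.
OMEGA0 = 6.0
_FC = OMEGA0 / (2.0 * np.pi)
#: PyWavelets name for the complex Morlet with bandwidth 1 and this fc.
WAVELET = f"cmor1.0-{_FC:.6f}"


@dataclass
class ScalogramConfig:
    scale_min: float = 1.0
    scale_max: float = 64.0
    n_scales: int = 32
    image_size: tuple[int, int] = (128, 128)
    channels: int = 3
    colormap: str = "viridis"

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ValidationError("scale_min must be < scale_max")
        if self.n_scales < 2:
            raise ValidationError("n_scales must be >= 2")

    @property
    def scales(self) -> np.ndarray:
        """Logarithmic scale grid from scale_min to scale_max."""
        return np.logspace(
            np.log10(self.scale_min), np.log10(self.scale_max), self.n_scales
        )


@dataclass
class ScalogramImage:
    """128 x 128 x 3 image in [0, 1] derived from one record."""

    pixels: np.ndarray
    record_id: str = ""


def scale_to_frequency(scale: float, fs: float) -> float:
    """Center frequency in Hz analyzed by a Morlet wavelet at this scale."""
    return float(pywt.scale2frequency(WAVELET, scale) * fs)


def morlet_cwt(record: EcgRecord, config: ScalogramConfig | None = None) -> np.ndarray:
    """Complex-Morlet CWT magnitudes, shape (n_scales, len(record)).

    Row i corresponds to ``config.scales[i]`` (scale 1 first, i.e. highest
    analyzed frequency at the top).
    """
    config = config or ScalogramConfig()
    x = np.asarray(record.samples, dtype=np.float64)
    if x.size == 0:
        raise ValidationError("cannot transform an empty record")
    coeffs, _ = pywt.cwt(x, config.scales, WAVELET, method="fft")
    return np.abs(coeffs)


def render_image(
    coeffs: np.ndarray,
    config: ScalogramConfig | None = None,
    record_id: str = "",
) -> ScalogramImage:
    """Min-max scale magnitudes to [0, 1], resize bilinearly, colormap to RGB.

    A constant coefficient matrix renders as a spatially uniform image (the
    colormap value at 0) rather than raising.
    """
    config = config or ScalogramConfig()
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.size == 0:
        raise ValidationError("empty coefficient matrix")
    lo, hi = coeffs.min(), coeffs.max()
    gray = np.zeros_like(coeffs) if hi == lo else (coeffs - lo) / (hi - lo)
    gray = resize(
        gray, config.image_size, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    gray = np.clip(gray, 0.0, 1.0)
    cmap = colormaps[config.colormap]
    rgb = cmap(gray)[..., : config.channels]
    return ScalogramImage(pixels=rgb.astype(np.float64), record_id=record_id)


def scalogram_image(record: EcgRecord, config: ScalogramConfig | None = None) -> ScalogramImage:
    """Convenience: CWT magnitudes rendered straight to an RGB image."""
    config = config or ScalogramConfig()
    return render_image(morlet_cwt(record, config), config, record_id=record.record_id)


def save_png(image: ScalogramImage, path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    plt.imsave(path, np.clip(image.pixels, 0, 1))
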