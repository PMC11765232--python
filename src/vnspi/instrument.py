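"""Forward model of the single-pixel acquisition chain.

A scene is a per-band transmittance map.  For each illumination mask the
bucket detector integrates the transmitted light over the open pixels; the
analog voltage is corrupted by detector noise and digitized by a 16-bit ADC
(least significant bit ~0.153 mV at a 10 V range).  Each pattern is measured
twice - once with the mask, once with its complement - so that the
differential reading realizes the +-1 Hadamard row and cancels any constant
background (dark) offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .patterns import MaskSequence

ADC_BITS_DEFAULT = 16
ADC_FULL_SCALE_DEFAULT = 10.0  # volts; lsb = 10 / 2**16 ~ 0.1526 mV


class SaturationError(RuntimeError):
    """Raised when the noiseless reading would exceed the ADC full scale."""


@dataclass(frozen=True)
class AdcSpec:
    """Analog-to-digital converter: uniform grid of ``2**bits`` steps."""

    bits: int = ADC_BITS_DEFAULT
    full_scale: float = ADC_FULL_SCALE_DEFAULT

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError("bits must be >= 1")
        if self.full_scale <= 0:
            raise ValueError("full_scale must be positive")

    @property
    def lsb(self) -> float:
        return self.full_scale / (2 ** self.bits)


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: additive Gaussian plus optional signal-dependent term.

    ``additive_sd`` is in volts; ``shot_scale`` multiplies ``sqrt(signal)``
    (0 disables the signal-dependent term).  The default additive level is
    half an LSB of the default ADC - small enough that pattern-domain noise
    stays well below the per-pixel scene contrast after reconstruction.
    """

    additive_sd: float = 0.5 * ADC_FULL_SCALE_DEFAULT / 2 ** ADC_BITS_DEFAULT
    shot_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")
        if self.shot_scale < 0:
            raise ValueError("shot_scale must be >= 0")


@dataclass
class Scene:
    """Ground-truth per-band transmittance maps (values in [0, 1]).

    ``truth_mask`` marks insect pixels when the scene was generated by the
    phantom module; ``clamped_pixels`` counts values that had to be clipped
    into [0, 1] during generation.
    """

    image_side: int
    bands: tuple
    transmittance: dict
    pixel_pitch_mm: float
    truth_mask: np.ndarray | None = None
    clamped_pixels: int = 0

    def __post_init__(self) -> None:
        for band in self.bands:
            arr = np.asarray(self.transmittance[band], dtype=np.float64)
            if arr.shape != (self.image_side, self.image_side):
                raise ValueError(
                    f"band {band}: expected {self.image_side}x{self.image_side}, got {arr.shape}"
                )
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"band {band}: transmittance outside [0, 1]")
            self.transmittance[band] = arr

    def band(self, band) -> np.ndarray:
        return self.transmittance[band]


@dataclass(frozen=True)
class MeasurementSeries:
    """Paired detector readings for one band: mask (y_plus) and complement (y_minus)."""

    band: float | int | None
    y_plus: np.ndarray
    y_minus: np.ndarray
    gain: float
    adc: AdcSpec | None = None
    noise: NoiseModel | None = None

    def __post_init__(self) -> None:
        yp = np.asarray(self.y_plus, dtype=np.float64)
        ym = np.asarray(self.y_minus, dtype=np.float64)
        if yp.shape != ym.shape or yp.ndim != 1:
            raise ValueError("y_plus and y_minus must be 1-D and of equal length")
        object.__setattr__(self, "y_plus", yp)
        object.__setattr__(self, "y_minus", ym)

    @property
    def pattern_count(self) -> int:
        return self.y_plus.size


def quantize(v, adc: AdcSpec):
    """Snap a voltage (scalar or array) to the ADC grid.

    Values are clamped into [0, full_scale] first (the converter cannot
    represent anything outside its range), then rounded half-up to the
    nearest LSB multiple.
    """
    v = np.clip(np.asarray(v, dtype=np.float64), 0.0, adc.full_scale)
    out = np.floor(v / adc.lsb + 0.5) * adc.lsb
    return float(out) if out.ndim == 0 else out


def measure(
    scene_band: np.ndarray,
    seq: MaskSequence,
    gain: float,
    noise: NoiseModel | None = None,
    adc: AdcSpec | None = None,
    dark_offset: float = 0.0,
    band=None,
) -> MeasurementSeries:
    """Simulate the paired single-pixel readings for one spectral band.

    For pattern ``k``: ``y_plus[k] = quantize(gain * sum(mask_k * scene)
    + dark_offset + noise)`` and ``y_minus[k]`` likewise for the complement.
    Deterministic for a fixed ``noise.seed``.  If the *noiseless* reading
    would exceed the ADC full scale a :class:`SaturationError` is raised
    (saturation is something to fix upstream with attenuation, not to clip
    silently); noisy excursions are clamped by the quantizer as a real
    converter would.
    """
    scene_band = np.asarray(scene_band, dtype=np.float64)
    m = seq.image_side
    if scene_band.shape != (m, m):
        raise ValueError(f"scene is {scene_band.shape}, mask sequence expects {(m, m)}")
    s = scene_band.ravel()
    n = seq.n_patterns
    masks = seq.masks.reshape(n, m * m).astype(np.float64)
    base_plus = masks @ s
    base_minus = s.sum() - base_plus  # complement: (1 - mask) . s

    y_plus = gain * base_plus + dark_offset
    y_minus = gain * base_minus + dark_offset

    if adc is not None:
        peak = max(y_plus.max(initial=0.0), y_minus.max(initial=0.0))
        if peak > adc.full_scale:
            raise SaturationError(
                f"noiseless reading {peak:.4g} V exceeds full scale {adc.full_scale} V; "
                "reduce the gain (attenuate) before measuring"
            )

    if noise is not None and (noise.additive_sd > 0 or noise.shot_scale > 0):
        rng = np.random.default_rng(noise.seed)
        eps = rng.standard_normal((2, n))
        y_plus = y_plus + noise.additive_sd * eps[0]
        y_minus = y_minus + noise.additive_sd * eps[1]
        if noise.shot_scale > 0:
            eta = rng.standard_normal((2, n))
            y_plus = y_plus + noise.shot_scale * np.sqrt(np.clip(y_plus, 0, None)) * eta[0]
            y_minus = y_minus + noise.shot_scale * np.sqrt(np.clip(y_minus, 0, None)) * eta[1]

    if adc is not None:
        y_plus = quantize(y_plus, adc)
        y_minus = quantize(y_minus, adc)

    return MeasurementSeries(
        band=band, y_plus=y_plus, y_minus=y_minus, gain=gain, adc=adc, noise=noise
    )


def apply_scatter(scene_band: np.ndarray, blur_width_px: float) -> np.ndarray:
    """Emulate a thin scattering layer behind the sample as a Gaussian blur.

    Reflective boundaries conserve total transmitted power; width 0 is the
    identity.
    """
    if blur_width_px < 0:
        raise ValueError(f"blur width must be >= 0, got {blur_width_px}")
    scene_band = np.asarray(scene_band, dtype=np.float64)
    if blur_width_px == 0:
        return scene_band.copy()
    return ndimage.gaussian_filter(scene_band, sigma=blur_width_px, mode="reflect")
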