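"""Seeded synthetic phantoms: tempered chocolate, embedded insects, flat-field references.

The generator emulates a 3 mm tempered-chocolate slab imaged in transmission
at 32 x 32 pixels (0.2128 mm/pixel) through 850 / 910 / 970 nm bandpass
filters.  Chocolate transmittance rises with wavelength; an embedded fruit
fly (~3 mm, a filled ellipse of ~14 x 6 pixels with a softened edge) adds
extra absorbance that is largest at 970 nm, where insect body fluids absorb
strongly.  Spatial texture is modelled as *one-sided* extra attenuation -
a half-normal absorbance field (the defect-free slab is the transmittance
ceiling; inhomogeneities only remove light) plus a handful of single-pixel
dark inclusions (micro-bubbles / cocoa particles).  Those isolated dark
specks are exactly the kind of sub-5-pixel clutter the detection pipeline's
area filter exists to reject.  An optional tilt gradient reproduces the
non-uniform illumination of a sample positioned at an angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .detect import DEFAULT_BANDS
from .instrument import Scene
from .patterns import spatial_resolution

DEFAULT_IMAGE_SIDE = 32
DEFAULT_PIXEL_PITCH_MM = spatial_resolution(DEFAULT_IMAGE_SIDE)  # 0.2128

#: per-band chocolate baseline transmittance (850, 910, 970 nm): rises with wavelength
DEFAULT_CHOCOLATE_TRANSMITTANCE = (0.10, 0.15, 0.20)
#: per-band extra absorbance of the insect body: largest at 970 nm
DEFAULT_INSECT_ABSORBANCE = (0.15, 0.25, 0.60)

REFERENCE_TRANSMITTANCE = 0.9  # intralipid flat-field level, all bands


@dataclass
class PhantomSpec:
    """Everything needed to regenerate one phantom deterministically."""

    image_side: int = DEFAULT_IMAGE_SIDE
    pixel_pitch_mm: float = DEFAULT_PIXEL_PITCH_MM
    contaminated: bool = False
    insect_length_mm: float = 3.0
    insect_width_mm: float = 1.3
    insect_center: tuple[int, int] | str = "random"
    band_transmittance_chocolate: tuple = DEFAULT_CHOCOLATE_TRANSMITTANCE
    insect_extra_absorbance: tuple = DEFAULT_INSECT_ABSORBANCE
    tilt_gradient: float = 0.0
    texture_sd: float = 0.005        # half-normal absorbance sd of the fine texture
    speck_count_min: int = 3         # deterministic floor of dark inclusions
    speck_count_poisson: float = 5.0  # Poisson mean of additional inclusions
    speck_absorbance: tuple[float, float] = (0.1, 0.35)
    bands: tuple = DEFAULT_BANDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 4:
            raise ValueError("image_side must be >= 4")
        if len(self.band_transmittance_chocolate) != len(self.bands):
            raise ValueError("one chocolate baseline per band required")
        if len(self.insect_extra_absorbance) != len(self.bands):
            raise ValueError("one insect absorbance per band required")
        if not (0.0 <= self.tilt_gradient < 1.0):
            raise ValueError("tilt_gradient must lie in [0, 1)")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")


def _insect_indicator(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Filled-ellipse insect footprint, randomly oriented, fitted inside the field."""
    m = spec.image_side
    a = 0.5 * spec.insect_length_mm / spec.pixel_pitch_mm   # semi-major, px
    b = 0.5 * spec.insect_width_mm / spec.pixel_pitch_mm    # semi-minor, px
    margin = int(np.ceil(a)) + 1
    if 2 * margin >= m:
        raise ValueError(
            f"insect of {spec.insect_length_mm} mm does not fit inside a "
            f"{m}-pixel field at {spec.pixel_pitch_mm} mm/pixel"
        )
    if spec.insect_center == "random":
        cr = rng.integers(margin, m - margin)
        cc = rng.integers(margin, m - margin)
    else:
        cr, cc = spec.insect_center
        if not (margin <= cr < m - margin and margin <= cc < m - margin):
            raise ValueError(f"insect center {spec.insect_center} places the body out of bounds")
    theta = rng.uniform(0.0, np.pi)
    rr, cc_grid = np.mgrid[0:m, 0:m]
    dr, dc = rr - cr, cc_grid - cc
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> Scene:
    """Generate one chocolate scene (with truth mask) from a phantom spec.

    Per band: ``T = baseline * (1 - tilt plane) * 10**-(texture + specks
    + insect absorbance)``, clamped into [0, 1] with the clamp count
    recorded.  Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.image_side

    cols = np.linspace(0.0, 1.0, m)
    tilt_plane = 1.0 - spec.tilt_gradient * np.broadcast_to(cols, (m, m))

    texture = spec.texture_sd * np.abs(rng.standard_normal((m, m)))

    specks = np.zeros((m, m))
    n_specks = spec.speck_count_min + int(rng.poisson(spec.speck_count_poisson))
    if n_specks > 0:
        idx = rng.choice(m * m, size=min(n_specks, m * m), replace=False)
        depths = rng.uniform(*spec.speck_absorbance, size=idx.size)
        specks.ravel()[idx] = depths

    truth = None
    insect_soft = 0.0
    if spec.contaminated:
        indicator = _insect_indicator(spec, rng)
        # soft 1-px edge avoids single-pixel aliasing of the footprint
        insect_soft = ndimage.gaussian_filter(indicator.astype(np.float64), 1.0)
        truth = indicator

    transmittance = {}
    clamped = 0
    for band, base, insect_abs in zip(
        spec.bands, spec.band_transmittance_chocolate, spec.insect_extra_absorbance
    ):
        absorbance = texture + specks
        if spec.contaminated:
            absorbance = absorbance + insect_abs * insect_soft
        t = base * tilt_plane * 10.0 ** (-absorbance)
        clamped += int(np.count_nonzero((t < 0) | (t > 1)))
        transmittance[band] = np.clip(t, 0.0, 1.0)

    return Scene(
        image_side=m,
        bands=tuple(spec.bands),
        transmittance=transmittance,
        pixel_pitch_mm=spec.pixel_pitch_mm,
        truth_mask=truth,
        clamped_pixels=clamped,
    )


def make_reference_phantom(spec: PhantomSpec, share_tilt: bool = False) -> Scene:
    """Flat-field reference: a spatially uniform intralipid cell per band.

    With ``share_tilt`` the reference carries the same illumination gradient
    as the sample (the source non-uniformity the reference correction is
    meant to cancel); without it a tilted *sample* keeps its gradient after
    correction, which is the false-positive mechanism of a sample positioned
    at an angle.
    """
    m = spec.image_side
    if share_tilt and spec.tilt_gradient > 0:
        cols = np.linspace(0.0, 1.0, m)
        plane = 1.0 - spec.tilt_gradient * np.broadcast_to(cols, (m, m))
    else:
        plane = np.ones((m, m))
    transmittance = {band: REFERENCE_TRANSMITTANCE * plane.copy() for band in spec.bands}
    return Scene(
        image_side=m,
        bands=tuple(spec.bands),
        transmittance=transmittance,
        pixel_pitch_mm=spec.pixel_pitch_mm,
    )


@dataclass(frozen=True)
class BenchmarkSample:
    sample_id: int
    seed: int
    contaminated: bool
    scene: Scene
    reference: Scene


def derive_sample_seeds(master_seed: int, n: int) -> np.ndarray:
    """Counter-based per-sample seeds (< 2**31), regenerable in isolation."""
    ss = np.random.SeedSequence(master_seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def make_benchmark(
    n_samples: int = 100,
    contaminated_fraction: float = 0.5,
    master_seed: int = 0,
    spec_template: PhantomSpec | None = None,
) -> list[BenchmarkSample]:
    """A seeded cohort of phantoms with known labels (default 100, 50/50).

    Labels are an exact count (``round(n * fraction)`` contaminated) in a
    seed-determined shuffle; each sample's scene derives from its own seed so
    any one sample can be regenerated without the rest.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not (0.0 <= contaminated_fraction <= 1.0):
        raise ValueError("contaminated_fraction must lie in [0, 1]")
    template = spec_template or PhantomSpec()
    n_cont = int(round(n_samples * contaminated_fraction))
    labels = np.zeros(n_samples, dtype=bool)
    labels[:n_cont] = True
    label_rng = np.random.default_rng(np.random.SeedSequence(master_seed).generate_state(1)[0])
    label_rng.shuffle(labels)
    seeds = derive_sample_seeds(master_seed, n_samples)
    samples = []
    for i in range(n_samples):
        spec = replace(
            template,
            contaminated=bool(labels[i]),
            insect_center="random",
            seed=int(seeds[i]),
        )
        samples.append(
            BenchmarkSample(
                sample_id=i,
                seed=int(seeds[i]),
                contaminated=bool(labels[i]),
                scene=make_phantom(spec),
                reference=make_reference_phantom(spec),
            )
        )
    return samples


def make_piecewise_phantom(side: int, rng: np.random.Generator,
                           n_blocks: int = 4) -> np.ndarray:
    """Piecewise-constant test scene: random axis-aligned rectangles on a background.

    This is the standard phantom for compressive-sensing experiments; its
    sparse gradient is what the total-variation penalty rewards.
    """
    img = np.full((side, side), 0.2)
    for _ in range(n_blocks):
        h = int(rng.integers(side // 4, side // 2 + 1))
        w = int(rng.integers(side // 4, side // 2 + 1))
        r = int(rng.integers(0, side - h + 1))
        c = int(rng.integers(0, side - w + 1))
        img[r:r + h, c:c + w] = rng.uniform(0.3, 1.0)
    return img
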