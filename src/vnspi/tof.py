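"""Time-of-flight diffuse transmittance through a slab, and optical-property fitting.

The temporal point spread function (TPSF) of a short pulse transmitted
through a homogeneous scattering slab of thickness ``d`` is modelled with the
diffusion approximation using four image sources:

    T(d, t) = (4 pi D c)^(-1/2) t^(-3/2) exp(-mu_a c t) *
              [ (d - z0) exp(-(d - z0)^2 / 4 D c t)
              - (d + z0) exp(-(d + z0)^2 / 4 D c t)
              + (3d - z0) exp(-(3d - z0)^2 / 4 D c t)
              - (3d + z0) exp(-(3d + z0)^2 / 4 D c t) ]

with diffusion coefficient ``D = 1 / (3 mu_s')`` (mm), penetration depth
``z0 = 1 / mu_s'`` (mm), and ``c`` the speed of light inside the medium
(mm/ps).  Fitting follows the measured-waveform pipeline: convolve the model
with the instrument response, Savitzky-Golay smooth (quadratic), normalize to
peak 1, and least-squares fit between the 5%-of-peak rise and tail crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import savgol_filter

#: default speed of light inside the medium, mm/ps (refractive index ~1.351)
C_MEDIUM_MM_PS = 0.2219

DEFAULT_T_GRID_PS = np.arange(1.0, 2001.0, 1.0)


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering of a turbid medium (mm^-1)."""

    mu_a: float
    mu_s_prime: float
    c: float = C_MEDIUM_MM_PS

    def __post_init__(self) -> None:
        if self.mu_s_prime <= 0:
            raise ValueError("mu_s_prime must be positive")
        if self.mu_a < 0:
            raise ValueError("mu_a must be >= 0")
        if self.c <= 0:
            raise ValueError("speed of light must be positive")

    @property
    def D(self) -> float:
        """Diffusion coefficient, mm."""
        return 1.0 / (3.0 * self.mu_s_prime)

    @property
    def z0(self) -> float:
        """Penetration depth, mm."""
        return 1.0 / self.mu_s_prime


@dataclass(frozen=True)
class Tpsf:
    """A time-resolved transmitted waveform on a uniform grid (ps)."""

    t: np.ndarray
    intensity: np.ndarray
    d: float | None = None
    irf: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if t.ndim != 1 or t.size < 3 or t.shape != inten.shape:
            raise ValueError("t and intensity must be matching 1-D arrays (>= 3 samples)")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be strictly increasing and uniform")
        if np.any(inten < 0):
            raise ValueError("intensity must be non-negative")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "intensity", inten)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class FitResult:
    """Outcome of a TPSF fit."""

    estimated: OpticalProperties
    window: tuple[float, float]
    residual_norm: float
    converged: bool


def tpsf_model(d: float, t_grid: np.ndarray, props: OpticalProperties) -> Tpsf:
    """Evaluate the slab diffusion TPSF on a time grid (ps).

    Tiny negative values from floating-point cancellation of the image-source
    terms are clamped to 0.
    """
    if d <= 0:
        raise ValueError("slab thickness must be positive")
    t = np.asarray(t_grid, dtype=np.float64)
    if np.any(t <= 0):
        raise ValueError("time grid must be strictly positive")
    D, z0, c = props.D, props.z0, props.c
    four_dct = 4.0 * D * c * t
    pref = (4.0 * np.pi * D * c) ** -0.5 * t ** -1.5 * np.exp(-props.mu_a * c * t)
    terms = np.zeros_like(t)
    for sign, a in ((1, d - z0), (-1, d + z0), (1, 3 * d - z0), (-1, 3 * d + z0)):
        terms = terms + sign * a * np.exp(-(a * a) / four_dct)
    inten = np.clip(pref * terms, 0.0, None)
    return Tpsf(t=t, intensity=inten, d=d)


def convolve_irf(model: Tpsf, irf: Tpsf) -> Tpsf:
    """Convolve a model TPSF with an instrument response on the same grid.

    The discrete linear convolution is truncated back to the grid and
    renormalized so the time integral of the model is preserved.
    """
    if model.t.shape != irf.t.shape or not np.allclose(model.t, irf.t):
        raise ValueError("model and instrument response must share the time grid")
    n = model.t.size
    conv = np.convolve(model.intensity, irf.intensity)[:n] * model.dt
    total_model = np.trapezoid(model.intensity, model.t)
    total_conv = np.trapezoid(conv, model.t)
    if total_conv > 0:
        conv = conv * (total_model / total_conv)
    return Tpsf(t=model.t, intensity=conv, d=model.d)


def preprocess(waveform: Tpsf, sg_window: int = 11, sg_order: int = 2) -> Tpsf:
    """Savitzky-Golay smooth (quadratic by default) and normalize the peak to 1."""
    if sg_window % 2 == 0 or sg_window < 5:
        raise ValueError("sg_window must be odd and >= 5")
    if sg_window <= sg_order:
        raise ValueError("sg_window must exceed sg_order")
    smooth = savgol_filter(waveform.intensity, sg_window, sg_order)
    smooth = np.clip(smooth, 0.0, None)
    peak = smooth.max()
    if peak <= 0:
        raise ValueError("waveform is identically zero; cannot normalize")
    return Tpsf(t=waveform.t, intensity=smooth / peak, d=waveform.d)


def fit_window(waveform: Tpsf, level: float = 0.05) -> tuple[float, float]:
    """Times where the normalized waveform crosses ``level`` of its peak.

    ``t_start`` is the first crossing on the rising side and ``t_end`` the
    last crossing on the falling side, both linearly interpolated between
    samples.  If the waveform is still above the level at the end of the
    grid the window is truncated at the last sample.
    """
    inten = waveform.intensity
    peak = inten.max()
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly between 0 and 1")
    thresh = level * peak
    above = inten >= thresh
    if not above.any():
        raise ValueError("waveform never reaches the requested level")
    i = int(np.argmax(above))
    if i == 0:
        t_start = float(waveform.t[0])
    else:
        f = (thresh - inten[i - 1]) / (inten[i] - inten[i - 1])
        t_start = float(waveform.t[i - 1] + f * (waveform.t[i] - waveform.t[i - 1]))
    j = len(inten) - 1 - int(np.argmax(above[::-1]))
    if j == len(inten) - 1:
        t_end = float(waveform.t[-1])
    else:
        f = (inten[j] - thresh) / (inten[j] - inten[j + 1])
        t_end = float(waveform.t[j] + f * (waveform.t[j + 1] - waveform.t[j]))
    t_peak = float(waveform.t[int(np.argmax(inten))])
    if not (t_start <= t_peak <= t_end):
        raise ValueError("degenerate window: peak outside [t_start, t_end]")
    return t_start, t_end


def fit_optical_properties(
    waveform: Tpsf,
    d: float,
    irf: Tpsf | None = None,
    fix_mu_a_near_zero: bool = False,
    c: float = C_MEDIUM_MM_PS,
    level: float = 0.05,
    sg_window: int = 11,
    x0: tuple[float, float] = (0.001, 10.0),
) -> FitResult:
    """Fit ``mu_a`` and ``mu_s'`` to a preprocessed (peak-normalized) waveform.

    The forward model is tpsf_model -> convolve_irf -> preprocess, compared
    with the measured waveform only between the 5%-rise and 5%-tail
    crossings.  When ``fix_mu_a_near_zero`` is set (a medium with negligible
    absorption at the laser wavelength, e.g. intralipid at 846 nm), ``mu_a``
    is constrained to [0, 0.01] mm^-1.  Optimizer failure is reported via
    ``converged=False``, never as a silent estimate.
    """
    if d <= 0:
        raise ValueError("slab thickness must be positive")
    t = waveform.t
    t_start, t_end = fit_window(waveform, level=level)
    sel = (t >= t_start) & (t <= t_end)
    target = waveform.intensity[sel]

    def forward(params: np.ndarray) -> np.ndarray:
        mu_a, mu_s = params
        props = OpticalProperties(mu_a=mu_a, mu_s_prime=mu_s, c=c)
        model = tpsf_model(d, t, props)
        if irf is not None:
            model = convolve_irf(model, irf)
        model = preprocess(model, sg_window=sg_window)
        return model.intensity[sel]

    mu_a_hi = 0.01 if fix_mu_a_near_zero else 1.0
    lower = np.array([0.0, 0.05])
    upper = np.array([mu_a_hi, 200.0])

    def attempt(start):
        start = np.clip(np.asarray(start, dtype=np.float64), lower + 1e-12, upper - 1e-12)
        try:
            res = least_squares(
                lambda p: forward(p) - target,
                start,
                bounds=(lower, upper),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=400,
            )
            return bool(res.success), res.x, float(np.linalg.norm(res.fun))
        except Exception:
            return False, start, float("inf")

    # the squared-residual landscape has flat shoulders far from the truth, so
    # a poor single start can stall; fall back to a small multi-start grid
    target_norm = float(np.linalg.norm(target))
    converged, best_x, residual_norm = attempt(x0)
    if not converged or residual_norm > 0.05 * target_norm:
        for mu_s_start in (5.0, 10.0, 20.0, 50.0):
            ok, xh, rn = attempt((x0[0], mu_s_start))
            if rn < residual_norm:
                converged, best_x, residual_norm = ok, xh, rn
            if converged and residual_norm <= 0.05 * target_norm:
                break
    mu_a_hat, mu_s_hat = best_x

    return FitResult(
        estimated=OpticalProperties(mu_a=float(mu_a_hat), mu_s_prime=float(mu_s_hat), c=c),
        window=(t_start, t_end),
        residual_norm=residual_norm,
        converged=converged,
    )


def gaussian_irf(t_grid: np.ndarray, center_ps: float, sigma_ps: float) -> Tpsf:
    """A unit-area Gaussian instrument response on the given grid."""
    t = np.asarray(t_grid, dtype=np.float64)
    g = np.exp(-0.5 * ((t - center_ps) / sigma_ps) ** 2)
    area = np.trapezoid(g, t)
    return Tpsf(t=t, intensity=g / area)
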