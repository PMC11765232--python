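"""Image recovery from single-pixel measurement series.

Two routes:

* full sampling - the differential readings of a complete Hadamard basis are
  inverted in closed form, ``x = W.T @ y / n`` (orthogonality makes the
  inverse a transpose);
* sub-sampling - only the first ``m < N`` (ideally Walsh-ordered) patterns
  were measured, and the image is recovered as an approximate minimizer of

      ||Phi x - y||_2^2 + lambda ||Psi x||_1 + mu TV(x)

  with ``Phi`` the retained +-1 rows, ``Psi`` the identity by default, and
  an anisotropic total-variation penalty, via a monotone FISTA iteration
  (soft-thresholding for the l1 term, a dual projected-gradient inner loop
  for the TV proximal step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .instrument import MeasurementSeries
from .patterns import HadamardMatrix, MaskSequence

METHOD_HADAMARD = "hadamard_inverse"
METHOD_COMPRESSIVE = "compressive"


@dataclass(frozen=True)
class ReconImage:
    """A reconstructed band image (relative transmitted intensity)."""

    band: float | int | None
    image: np.ndarray
    method: str
    sampling_ratio: float
    solver_stats: dict | None = None

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=np.float64)
        if img.ndim != 2 or img.shape[0] != img.shape[1]:
            raise ValueError(f"image must be square 2-D, got {img.shape}")
        if self.method not in (METHOD_HADAMARD, METHOD_COMPRESSIVE):
            raise ValueError(f"unknown method {self.method!r}")
        if (self.solver_stats is not None) != (self.method == METHOD_COMPRESSIVE):
            raise ValueError("solver_stats must be present iff method is compressive")
        object.__setattr__(self, "image", img)


@dataclass(frozen=True)
class CsConfig:
    """Penalty weights and iteration control for the compressive solver."""

    lambda_l1: float = 0.01
    mu_tv: float = 0.1
    dictionary: str = "identity"
    max_iter: int = 500
    tol: float = 1e-6
    tv_inner_iter: int = 30

    def __post_init__(self) -> None:
        if self.lambda_l1 < 0 or self.mu_tv < 0:
            raise ValueError("penalty weights must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.dictionary != "identity":
            raise ValueError(
                f"dictionary {self.dictionary!r} not available; 'identity' is built in"
            )


def differential(series: MeasurementSeries) -> np.ndarray:
    """Mask-minus-complement reading per pattern; cancels constant offsets."""
    if series.y_plus.shape != series.y_minus.shape:
        raise ValueError("y_plus and y_minus lengths differ")
    return series.y_plus - series.y_minus


def reconstruct_hadamard(y: np.ndarray, H: HadamardMatrix, band=None) -> ReconImage:
    """Closed-form inversion of a fully sampled differential measurement.

    ``x = H.T @ y / n``, reshaped row-major.  The differential reading of the
    {0,1} mask / complement pair equals the +-1 row applied to the scene
    (times gain), so the noiseless round trip is exact.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    n = H.order
    if y.size != n:
        raise ValueError(
            f"full sampling required: got {y.size} readings for order {n}; "
            "use reconstruct_cs for partial measurements"
        )
    x = H.entries.astype(np.float64).T @ y / n
    m = int(round(np.sqrt(n)))
    return ReconImage(
        band=band, image=x.reshape(m, m), method=METHOD_HADAMARD, sampling_ratio=1.0
    )


def tv_value(img: np.ndarray) -> float:
    """Anisotropic total variation: sum of |horizontal| + |vertical| first differences."""
    return float(
        np.abs(np.diff(img, axis=1)).sum() + np.abs(np.diff(img, axis=0)).sum()
    )


def _soft(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _tv_prox(v: np.ndarray, tau: float, n_iter: int) -> np.ndarray:
    """Proximal operator of ``tau * TV`` via projected gradient on the dual.

    Dual variables live in the box [-tau, tau] per difference; step 1/8 is
    the inverse Lipschitz constant of the 2-D difference operator.
    """
    if tau == 0:
        return v
    p = np.zeros((v.shape[0], v.shape[1] - 1))  # horizontal edges
    q = np.zeros((v.shape[0] - 1, v.shape[1]))  # vertical edges
    for _ in range(n_iter):
        x = v - _tv_div(p, q)
        p = np.clip(p + 0.125 * np.diff(x, axis=1), -tau, tau)
        q = np.clip(q + 0.125 * np.diff(x, axis=0), -tau, tau)
    return v - _tv_div(p, q)


def _tv_div(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Adjoint of the forward-difference operator (negative divergence)."""
    out = np.zeros((q.shape[0] + 1, p.shape[1] + 1))
    out[:, :-1] -= p
    out[:, 1:] += p
    out[:-1, :] -= q
    out[1:, :] += q
    return out


def reconstruct_cs(
    y_subset: np.ndarray, seq: MaskSequence, cfg: CsConfig | None = None, band=None
) -> ReconImage:
    """Recover an image from a leading subset of differential Hadamard readings.

    Monotone FISTA on the composite objective: gradient step on the data
    term (Lipschitz constant is exactly ``N`` since distinct Hadamard rows
    are orthogonal with squared norm ``N``), then soft-thresholding
    (l1, identity dictionary) and an inner TV proximal step.  The recorded
    objective history is non-increasing by construction; if the relative
    objective change never falls below ``tol``, the best iterate is returned
    with ``converged=False`` in ``solver_stats``.
    """
    cfg = cfg or CsConfig()
    y = np.asarray(y_subset, dtype=np.float64).ravel()
    m_meas = y.size
    if m_meas < 1:
        raise ValueError("need at least one measurement")
    if m_meas > seq.n_patterns:
        raise ValueError(
            f"{m_meas} readings but the mask sequence holds {seq.n_patterns} patterns"
        )
    side = seq.image_side
    n = side * side
    phi = seq.hadamard_rows[:m_meas].astype(np.float64)

    scale = np.max(np.abs(y))
    if scale == 0:
        stats = {"iterations": 0, "objective": 0.0, "converged": True,
                 "objective_history": [0.0]}
        return ReconImage(
            band=band, image=np.zeros((side, side)), method=METHOD_COMPRESSIVE,
            sampling_ratio=m_meas / n, solver_stats=stats,
        )
    yn = y / scale
    lip = float(n)

    def objective(xv: np.ndarray) -> float:
        r = phi @ xv - yn
        val = float(r @ r) + cfg.lambda_l1 * float(np.abs(xv).sum())
        if cfg.mu_tv > 0:
            val += cfg.mu_tv * tv_value(xv.reshape(side, side))
        return val

    x = phi.T @ yn / n
    z = x.copy()
    t = 1.0
    f_best = objective(x)
    history = [f_best]
    converged = False
    iterations = 0
    for it in range(1, cfg.max_iter + 1):
        iterations = it
        grad = 2.0 * (phi.T @ (phi @ z - yn))
        v = z - grad / (2.0 * lip)
        if cfg.lambda_l1 > 0:
            v = _soft(v, cfg.lambda_l1 / (2.0 * lip))
        if cfg.mu_tv > 0:
            v = _tv_prox(
                v.reshape(side, side), cfg.mu_tv / (2.0 * lip), cfg.tv_inner_iter
            ).ravel()
        f_v = objective(v)
        x_prev = x
        # monotone variant: never accept an iterate with a worse objective
        if f_v <= f_best:
            x, f_x = v, f_v
        else:
            f_x = f_best
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        z = x + (t / t_next) * (v - x) + ((t - 1.0) / t_next) * (x - x_prev)
        t = t_next
        history.append(f_x)
        rel = abs(history[-2] - f_x) / max(f_best, 1e-30)
        f_best = f_x
        if rel < cfg.tol:
            converged = True
            break

    stats = {
        "iterations": iterations,
        "objective": f_best,
        "converged": converged,
        "objective_history": history,
    }
    return ReconImage(
        band=band,
        image=(x * scale).reshape(side, side),
        method=METHOD_COMPRESSIVE,
        sampling_ratio=m_meas / n,
        solver_stats=stats,
    )
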