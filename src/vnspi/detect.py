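"""Three-band insect-detection pipeline for reconstructed chocolate images.

Stages, in order: divide each band by its flat-field (intralipid) reference
to cancel source-intensity variation; treat every pixel as a 3-feature
observation (850 / 910 / 970 nm corrected transmittance) and extract the
first principal component; min-max scale the PC1 score image to [-1, 1];
flag pixels below a fixed 0.7 threshold as insect candidates (insects absorb
more - most strongly at 970 nm, a water-absorption band - so they sit low on
PC1 once its sign is anchored to brightness); drop connected components
smaller than 5 pixels as noise; call the sample contaminated iff any
candidate pixels survive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure
from sklearn.decomposition import PCA

DEFAULT_BANDS = (850, 910, 970)
DEFAULT_THRESHOLD = 0.7
DEFAULT_MIN_AREA_PX = 5
DEFAULT_CONNECTIVITY = 8
DEFAULT_REFERENCE_FLOOR = 1e-6

_DEGENERATE_VAR = 1e-24


@dataclass
class SpectralStack:
    """Per-band sample and reference images, plus the corrected ratio images."""

    bands: tuple
    images: dict
    reference: dict
    corrected: dict | None = None
    floored_pixels: int = 0

    def __post_init__(self) -> None:
        shapes = set()
        for band in self.bands:
            if band not in self.images:
                raise ValueError(f"missing sample image for band {band}")
            if band not in self.reference:
                raise ValueError(f"missing reference image for band {band}")
            self.images[band] = np.asarray(self.images[band], dtype=np.float64)
            self.reference[band] = np.asarray(self.reference[band], dtype=np.float64)
            shapes.add(self.images[band].shape)
            shapes.add(self.reference[band].shape)
        if len(shapes) != 1:
            raise ValueError(f"all band images must share one shape, got {shapes}")


@dataclass
class DetectParams:
    threshold: float = DEFAULT_THRESHOLD
    min_area_px: int = DEFAULT_MIN_AREA_PX
    connectivity: int = DEFAULT_CONNECTIVITY
    reference_floor: float = DEFAULT_REFERENCE_FLOOR

    def __post_init__(self) -> None:
        if not (-1.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [-1, 1]")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class DetectionResult:
    """All intermediates of one pipeline run plus the final call."""

    pc1: np.ndarray
    pc1_scaled: np.ndarray
    loadings: np.ndarray
    binary: np.ndarray
    binary_denoised: np.ndarray
    removed_components: int
    contaminated: bool
    threshold: float
    min_area_px: int
    connectivity: int
    degenerate: bool = False
    floored_pixels: int = 0


def reference_correct(stack: SpectralStack, floor: float = DEFAULT_REFERENCE_FLOOR) -> dict:
    """Per-band ratio sample / max(reference, floor).

    Also stores the result on ``stack.corrected`` and counts reference pixels
    that had to be floored (a dark reference pixel would otherwise blow up
    the ratio).
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    corrected = {}
    floored = 0
    for band in stack.bands:
        ref = stack.reference[band]
        floored += int(np.count_nonzero(ref < floor))
        corrected[band] = stack.images[band] / np.maximum(ref, floor)
    stack.corrected = corrected
    stack.floored_pixels = floored
    return corrected


@dataclass(frozen=True)
class Pc1Result:
    scores: np.ndarray
    loadings: np.ndarray
    degenerate: bool


def pca_pc1(corrected: dict, bands: tuple | None = None,
            loadings: np.ndarray | None = None) -> Pc1Result:
    """First principal component over pixels, with 3 band features each.

    Bands are mean-centered but not variance-standardized, so loadings
    reflect the physical contrast magnitude of each band.  The eigenvector
    sign is anchored so the score image correlates non-negatively with mean
    band brightness (bright chocolate -> high PC1).  A constant stack (zero
    covariance) yields a flagged all-zero score image.  Precomputed
    ``loadings`` (e.g. fitted across a whole cohort) may be supplied instead
    of fitting per sample.
    """
    bands = tuple(bands) if bands is not None else tuple(sorted(corrected))
    if len(bands) < 2:
        raise ValueError("PCA needs at least two bands")
    shape = corrected[bands[0]].shape
    X = np.stack([corrected[b].ravel() for b in bands], axis=1)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two pixels")
    centered = X - X.mean(axis=0)
    total_var = float((centered ** 2).sum())
    if total_var < _DEGENERATE_VAR:
        return Pc1Result(
            scores=np.zeros(shape), loadings=np.zeros(len(bands)), degenerate=True
        )
    if loadings is None:
        pca = PCA(n_components=1)
        scores = pca.fit_transform(X)[:, 0]
        load = pca.components_[0].copy()
    else:
        load = np.asarray(loadings, dtype=np.float64)
        load = load / np.linalg.norm(load)
        scores = centered @ load
    brightness = X.mean(axis=1)
    corr = float(scores @ (brightness - brightness.mean()))
    if corr < 0:
        scores, load = -scores, -load
    return Pc1Result(scores=scores.reshape(shape), loadings=load, degenerate=False)


def fit_cohort_loadings(corrected_stacks: list[dict], bands: tuple = DEFAULT_BANDS) -> np.ndarray:
    """Fit PC1 loadings across the pooled pixels of many samples (cohort mode)."""
    X = np.concatenate(
        [np.stack([c[b].ravel() for b in bands], axis=1) for c in corrected_stacks]
    )
    pca = PCA(n_components=1)
    pca.fit(X)
    return pca.components_[0].copy()


def scale_pc1(pc1: np.ndarray) -> tuple[np.ndarray, bool]:
    """Affine min-max map of the score image onto [-1, 1].

    A constant image has no range to map; it becomes all zeros with the
    degenerate flag set.
    """
    pc1 = np.asarray(pc1, dtype=np.float64)
    lo, hi = pc1.min(), pc1.max()
    if hi - lo < 1e-30:
        return np.zeros_like(pc1), True
    return 2.0 * (pc1 - lo) / (hi - lo) - 1.0, False


def binarize(pc1_scaled: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Insect-candidate mask: 1 where the scaled PC1 is strictly below threshold."""
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [-1, 1], got {threshold}")
    return (np.asarray(pc1_scaled) < threshold)


def denoise(mask: np.ndarray, min_area_px: int = DEFAULT_MIN_AREA_PX,
            connectivity: int = DEFAULT_CONNECTIVITY) -> tuple[np.ndarray, int]:
    """Clear connected components with fewer than ``min_area_px`` pixels.

    Components of exactly ``min_area_px`` pixels survive ("smaller than"
    is strict).  Returns the cleaned mask and the number of components
    removed.
    """
    mask = np.asarray(mask).astype(bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(mask, connectivity=1 if connectivity == 4 else 2)
    if labels.max() == 0:
        return mask.copy(), 0
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area_px)
    small = small[small != 0]  # 0 is background
    keep = mask.copy()
    if small.size:
        keep[np.isin(labels, small)] = False
    return keep, int(small.size)


def classify(binary_denoised: np.ndarray) -> bool:
    """Contaminated iff at least one candidate pixel survived denoising."""
    return bool(np.asarray(binary_denoised).any())


def run_pipeline(stack: SpectralStack, params: DetectParams | None = None,
                 loadings: np.ndarray | None = None) -> DetectionResult:
    """Full detection chain; all intermediates are retained in the result.

    A degenerate (constant) PC1 image carries no contrast and therefore no
    evidence of contamination: the sample is called clean.
    """
    params = params or DetectParams()
    corrected = reference_correct(stack, floor=params.reference_floor)
    pc1 = pca_pc1(corrected, bands=stack.bands, loadings=loadings)
    shape = pc1.scores.shape
    if pc1.degenerate:
        empty = np.zeros(shape, dtype=bool)
        return DetectionResult(
            pc1=pc1.scores, pc1_scaled=np.zeros(shape), loadings=pc1.loadings,
            binary=empty, binary_denoised=empty.copy(), removed_components=0,
            contaminated=False, threshold=params.threshold,
            min_area_px=params.min_area_px, connectivity=params.connectivity,
            degenerate=True, floored_pixels=stack.floored_pixels,
        )
    scaled, degenerate = scale_pc1(pc1.scores)
    if degenerate:
        empty = np.zeros(shape, dtype=bool)
        binary, denoised, removed, contaminated = empty, empty.copy(), 0, False
    else:
        binary = binarize(scaled, params.threshold)
        denoised, removed = denoise(binary, params.min_area_px, params.connectivity)
        contaminated = classify(denoised)
    return DetectionResult(
        pc1=pc1.scores, pc1_scaled=scaled, loadings=pc1.loadings,
        binary=binary, binary_denoised=denoised, removed_components=removed,
        contaminated=contaminated, threshold=params.threshold,
        min_area_px=params.min_area_px, connectivity=params.connectivity,
        degenerate=degenerate, floored_pixels=stack.floored_pixels,
    )
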