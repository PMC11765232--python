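"""Hadamard illumination patterns and their layout on a digital micromirror device.

Single-pixel imaging recovers an ``M x M`` image from a sequence of structured
binary illumination masks and the scalar detector reading produced by each.
This module builds the mask basis: Sylvester Hadamard matrices (+1/-1 rows,
mutually orthogonal, ``W @ W.T = n * I``), an optional sequency ("Walsh")
re-ordering that places coarse patterns first, conversion of +-1 rows into
displayable 0/1 mask / inverse-mask pairs, and expansion of a mask into a full
micromirror frame for a 1140 x 912 DMD with 28 x 28 mirrors binned per image
pixel (896 x 896 active mirrors, centered).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import hadamard as _sylvester

# DMD geometry (DLP 0.45" WXGA-class device driven as a second screen).
DMD_ROWS = 1140
DMD_COLS = 912
SUPERPIXEL = 28            # mirrors per image pixel, per side
ACTIVE_MIRRORS = 896       # 32 * 28, centered active square
MIRROR_PITCH_MM = 0.0076   # mirror pitch in mm

SUPPORTED_SIDES = (32, 64, 128, 256, 512)

_MAX_ORDER = 2 ** 20


class Ordering(str, enum.Enum):
    """Row ordering of a Hadamard matrix."""

    NATURAL = "natural"   # Sylvester recursion order
    WALSH = "walsh"       # rows sorted by sequency (number of sign changes)


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class HadamardMatrix:
    """A +-1 Hadamard matrix with a declared row ordering.

    Invariants: ``order`` is a power of two, every entry is +1 or -1, and
    ``entries @ entries.T == order * I`` (checked lazily by
    :meth:`check_orthogonality`; an O(n^3) product is too costly to run on
    every construction at large orders).
    """

    order: int
    entries: np.ndarray
    ordering: Ordering = Ordering.NATURAL

    def __post_init__(self) -> None:
        if not _is_power_of_two(self.order):
            raise ValueError(f"Hadamard order must be a power of two, got {self.order}")
        e = np.asarray(self.entries)
        if e.shape != (self.order, self.order):
            raise ValueError(f"entries must be {self.order}x{self.order}, got {e.shape}")
        if not np.all(np.abs(e) == 1):
            raise ValueError("Hadamard entries must all be +1 or -1")
        object.__setattr__(self, "entries", e.astype(np.int8, copy=False))

    def check_orthogonality(self) -> None:
        """Raise ``ValueError`` unless ``W @ W.T == order * I`` exactly."""
        w = self.entries.astype(np.float64)
        g = w @ w.T
        if not np.array_equal(g, self.order * np.eye(self.order)):
            raise ValueError("matrix rows are not mutually orthogonal (not Hadamard)")

    def sequencies(self) -> np.ndarray:
        """Number of adjacent sign changes along each row (1-D, pre-reshape)."""
        e = self.entries
        return np.count_nonzero(e[:, 1:] != e[:, :-1], axis=1)


def build_hadamard(k: int) -> HadamardMatrix:
    """Sylvester Hadamard matrix of order ``2**k`` in natural ordering.

    The order-``2n`` matrix is the 2x2 block composition
    ``[[W_n, W_n], [W_n, -W_n]]`` starting from ``W_1 = [[1]]``.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise TypeError(f"k must be an integer, got {k!r}")
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    order = 2 ** int(k)
    if order > _MAX_ORDER:
        raise ValueError(f"order 2**{k} exceeds the supported maximum {_MAX_ORDER}")
    return HadamardMatrix(order=order, entries=_sylvester(order, dtype=np.int8))


def walsh_order(H: HadamardMatrix) -> HadamardMatrix:
    """Permute rows of a natural-order Hadamard matrix into sequency order.

    After reordering, row ``k`` has exactly ``k`` sign changes
    (sequency 0, 1, ..., N-1); columns are untouched.  Low-sequency rows carry
    the coarse spatial structure, which is what makes this ordering effective
    when only a leading fraction of patterns is measured.
    """
    if H.ordering is not Ordering.NATURAL:
        raise ValueError("walsh_order expects a matrix in natural (Sylvester) ordering")
    H.check_orthogonality()
    seq = H.sequencies()
    perm = np.argsort(seq, kind="stable")
    reordered = H.entries[perm]
    got = np.count_nonzero(reordered[:, 1:] != reordered[:, :-1], axis=1)
    if not np.array_equal(got, np.arange(H.order)):
        raise ValueError("row sequencies are not a complete 0..N-1 set; not a Sylvester matrix")
    return HadamardMatrix(order=H.order, entries=reordered, ordering=Ordering.WALSH)


@dataclass(frozen=True)
class MaskSequence:
    """Ordered binary mask / inverse-mask pairs derived from Hadamard rows.

    ``masks[k]`` is row ``k`` of the source matrix reshaped row-major to
    ``image_side x image_side`` with +1 -> 1 (transmit) and -1 -> 0 (block);
    the inverse mask is the complement ``1 - mask`` so that the differential
    reading of the pair realizes the +-1 row on 0/1 hardware.
    """

    image_side: int
    masks: np.ndarray                # (n_patterns, M, M) uint8 in {0, 1}
    ordering: Ordering
    sampling_ratio: float

    def __post_init__(self) -> None:
        m = np.asarray(self.masks)
        if m.ndim != 3 or m.shape[1:] != (self.image_side, self.image_side):
            raise ValueError(f"masks must be (n, {self.image_side}, {self.image_side})")
        if not np.all((m == 0) | (m == 1)):
            raise ValueError("masks must be binary")
        if not (0.0 < self.sampling_ratio <= 1.0):
            raise ValueError(f"sampling_ratio must be in (0, 1], got {self.sampling_ratio}")
        object.__setattr__(self, "masks", m.astype(np.uint8, copy=False))

    @property
    def n_patterns(self) -> int:
        return self.masks.shape[0]

    @property
    def inverse_masks(self) -> np.ndarray:
        return (1 - self.masks).astype(np.uint8)

    @property
    def hadamard_rows(self) -> np.ndarray:
        """Retained +-1 rows, flattened: the sensing matrix Phi (n_patterns x N)."""
        n = self.image_side * self.image_side
        return (2 * self.masks.reshape(self.n_patterns, n).astype(np.int16) - 1).astype(np.int8)

    def metadata(self) -> dict:
        return {
            "image_side": self.image_side,
            "n_patterns": self.n_patterns,
            "ordering": self.ordering.value,
            "sampling_ratio": self.sampling_ratio,
        }


def to_mask_sequence(H: HadamardMatrix, image_side: int, sampling_ratio: float = 1.0) -> MaskSequence:
    """Convert the first ``ceil(sampling_ratio * N)`` rows of ``H`` to mask pairs."""
    n = image_side * image_side
    if H.order != n:
        raise ValueError(
            f"Hadamard order {H.order} does not match image_side**2 = {n}"
        )
    if not (0.0 < sampling_ratio <= 1.0):
        raise ValueError(f"sampling_ratio must be in (0, 1], got {sampling_ratio}")
    n_keep = math.ceil(sampling_ratio * n)
    rows = H.entries[:n_keep]
    masks = ((rows + 1) // 2).reshape(n_keep, image_side, image_side)
    return MaskSequence(
        image_side=image_side,
        masks=masks.astype(np.uint8),
        ordering=H.ordering,
        sampling_ratio=float(sampling_ratio),
    )


@dataclass(frozen=True)
class DmdFrame:
    """A full 1140 x 912 binary mirror frame with a centered superpixel grid."""

    bits: np.ndarray
    image_side: int
    superpixel: int = SUPERPIXEL
    mirror_pitch_mm: float = MIRROR_PITCH_MM
    height: int = DMD_ROWS
    width: int = DMD_COLS

    def __post_init__(self) -> None:
        b = np.asarray(self.bits)
        if b.shape != (self.height, self.width):
            raise ValueError(f"frame must be {self.height}x{self.width}, got {b.shape}")
        if not np.all((b == 0) | (b == 1)):
            raise ValueError("frame bits must be binary")
        object.__setattr__(self, "bits", b.astype(np.uint8, copy=False))

    @property
    def active_slices(self) -> tuple[slice, slice]:
        side = self.image_side * self.superpixel
        r0 = (self.height - side) // 2
        c0 = (self.width - side) // 2
        return slice(r0, r0 + side), slice(c0, c0 + side)

    def extract_mask(self) -> np.ndarray:
        """Block-average the active area back to the image-pixel mask (exact)."""
        rs, cs = self.active_slices
        area = self.bits[rs, cs].astype(np.float64)
        m = self.image_side
        s = self.superpixel
        blocks = area.reshape(m, s, m, s).mean(axis=(1, 3))
        return np.rint(blocks).astype(np.uint8)


def layout_on_dmd(mask: np.ndarray, superpixel: int = SUPERPIXEL) -> DmdFrame:
    """Expand an ``M x M`` binary mask into a centered full-frame mirror image.

    Each image pixel becomes a ``superpixel x superpixel`` constant mirror
    block; everything outside the active area stays 0 (blocked).
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError(f"mask must be square 2-D, got shape {mask.shape}")
    if not np.all((mask == 0) | (mask == 1)):
        raise ValueError("mask must be binary")
    m = mask.shape[0]
    side = m * superpixel
    if side > min(DMD_ROWS, DMD_COLS):
        raise ValueError(
            f"mask of side {m} needs {side} mirrors, exceeding the "
            f"{DMD_ROWS}x{DMD_COLS} frame"
        )
    frame = np.zeros((DMD_ROWS, DMD_COLS), dtype=np.uint8)
    block = np.kron(mask.astype(np.uint8), np.ones((superpixel, superpixel), dtype=np.uint8))
    r0 = (DMD_ROWS - side) // 2
    c0 = (DMD_COLS - side) // 2
    frame[r0:r0 + side, c0:c0 + side] = block
    return DmdFrame(bits=frame, image_side=m, superpixel=superpixel)


def spatial_resolution(image_side: int) -> float:
    """Physical size of one image pixel, in mm, at a given resolution.

    The centered active area spans 896 mirrors of 0.0076 mm pitch, so one
    image pixel covers ``(896 / image_side) * 0.0076`` mm: 0.2128 mm at 32 x 32.
    Note that at 512 x 512 this geometric value is 0.0133 mm/pixel (1.75
    mirrors per pixel); the device's nominal "maximum resolution" of one
    mirror per pixel (0.0076 mm) cannot be realized by the centered
    896-mirror layout, and this function deliberately returns the geometric
    value rather than the nominal one.
    """
    if image_side not in SUPPORTED_SIDES:
        raise ValueError(
            f"image_side must be one of {SUPPORTED_SIDES}, got {image_side}"
        )
    return (ACTIVE_MIRRORS / image_side) * MIRROR_PITCH_MM
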