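"""Hounsfield-unit windowing transfer functions.

CT attenuation is recorded in Hounsfield units (HU): water = 0, air about
-1000, dense bone well above +1000. Displaying a slice requires mapping a
chosen HU interval ``[level - width/2, level + width/2]`` onto 8-bit display
intensities. Two transfer functions are provided:

* the *traditional* clamp-and-linear-map used on every CT workstation, and
* a *sigmoid* transfer that compresses out-of-window values toward a small
  margin ``eps`` (below the window) and ``U - eps`` (above it) instead of
  clipping them, so that subtle attenuation differences just outside the
  window survive quantization.

The sigmoid is

    f(h) = U / (1 + exp(-(2 (h - l) / w) * ln(U/eps - 1)))

which satisfies f(l) = U/2, f(l - w/2) = eps and f(l + w/2) = U - eps
exactly, and tends to the traditional clamp as eps -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HU_MIN",
    "HU_MAX",
    "WindowSetting",
    "TransferParams",
    "as_hu_image",
    "round_half_up",
    "traditional_transform",
    "sigmoid_transform",
    "transform_image",
]

#: Plausible HU range accepted on ingest. CT numbers outside this interval
#: indicate corrupt pixel data or a missing rescale, and are rejected.
HU_MIN = -1100.0
HU_MAX = 3100.0


@dataclass(frozen=True)
class WindowSetting:
    """A (window width, window level) pair in HU.

    The interval of interest is ``[level - width/2, level + width/2]``.
    """

    width: float
    level: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.width) or not np.isfinite(self.level):
            raise ValueError("window width/level must be finite")
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")

    @property
    def lower(self) -> float:
        return self.level - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.level + self.width / 2.0


@dataclass(frozen=True)
class TransferParams:
    """Parameters of the sigmoid transfer.

    upper
        Upper intensity limit ``U`` (8-bit display: 255).
    eps
        Margin between the asymptotic output and the hard limits; must lie
        in ``(0, U/2)``. Small eps approaches the traditional clamp.
    """

    upper: float = 255.0
    eps: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.eps < self.upper / 2.0):
            raise ValueError(
                f"eps must satisfy 0 < eps < U/2, got eps={self.eps}, U={self.upper}"
            )


def as_hu_image(values: np.ndarray) -> np.ndarray:
    """Validate and coerce a 2D HU matrix to float64.

    Rejects empty or non-2D input, non-finite values, and values outside
    the plausible CT range [-1100, 3100].
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"HU image must be 2D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("HU image is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError("HU image contains non-finite values")
    lo, hi = float(arr.min()), float(arr.max())
    if lo < HU_MIN or hi > HU_MAX:
        raise ValueError(
            f"HU values [{lo}, {hi}] outside plausible CT range [{HU_MIN}, {HU_MAX}]"
        )
    return arr


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round with ties away from zero toward +inf (0.5 -> 1), elementwise.

    numpy's round() is banker's rounding; display quantization here is fixed
    to round-half-up for reproducibility.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def traditional_transform(h, s: WindowSetting):
    """Traditional windowing: clamp outside the window, linear inside.

    Values below ``l - w/2`` map to 0, above ``l + w/2`` to 255, and in
    between to ``round(255 * (h - lower) / w)``. Accepts scalars or arrays;
    non-finite input raises.
    """
    arr = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite HU value in input")
    out = round_half_up(255.0 * (arr - s.lower) / s.width)
    out = np.clip(out, 0.0, 255.0)
    if np.isscalar(h) or arr.ndim == 0:
        return float(out)
    return out


def sigmoid_transform(h, s: WindowSetting, p: TransferParams = TransferParams()):
    """Sigmoid windowing transfer, continuous output in (0, U).

    Strictly increasing in h; equals U/2 at the window level, eps at the
    lower window bound and U - eps at the upper bound.
    """
    arr = np.asarray(h, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite HU value in input")
    slope = np.log(p.upper / p.eps - 1.0)
    z = -(2.0 * (arr - s.level) / s.width) * slope
    # exp overflow is harmless here (maps to 0 or U); suppress the warning.
    with np.errstate(over="ignore"):
        out = p.upper / (1.0 + np.exp(z))
    if np.isscalar(h) or arr.ndim == 0:
        return float(out)
    return out


def transform_image(
    P: np.ndarray,
    s: WindowSetting,
    method: str = "sigmoid",
    p: TransferParams = TransferParams(),
) -> np.ndarray:
    """Transform a whole HU slice into an 8-bit grayscale image.

    The sigmoid output is quantized by round-half-up and clamped to
    [0, 255]; the traditional transform already quantizes. Output dtype is
    uint8 with the input's shape.
    """
    arr = as_hu_image(P)
    if method == "traditional":
        out = traditional_transform(arr, s)
    elif method == "sigmoid":
        out = np.clip(round_half_up(sigmoid_transform(arr, s, p)), 0.0, 255.0)
    else:
        raise ValueError(f"unknown transfer method: {method!r}")
    return out.astype(np.uint8)
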