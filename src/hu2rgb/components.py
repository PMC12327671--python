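"""Brain-component extraction from a non-contrast CT slice.

The pipeline builds binary masks under predefined window settings, selects
the hemorrhage window automatically by tracking boundary-point counts across
a window-level sweep, and derives suspect regions (matrices whose nonzero
entries carry the HU value of provisionally assigned pixels) for hemorrhage,
CSF, white matter and gray matter.

The window sweep mirrors how a radiologist scrubs the window level: narrow
windows (width 10 HU) at levels 30..75 HU each produce a binary mask of
pixels brighter than intensity 128. As the level rises past a tissue's HU,
that tissue drops out of the mask; the boundary-point count of the largest
connected region falls sharply when a large low-HU structure (parenchyma,
liquid) vanishes, and the mask just after the largest drop isolates blood.

Suspect-region algebra (caps in HU):

    hemorrhage  H_hat = |K - H_l| * f(P),  f(P) = P if P <= 110 else 0
    CSF         C_hat = |M - H'|  * f(P),  f(P) = P if P <= 15  else 0
    white       M_hat = |M - H'|  * f(P),  f(P) = P if 15 <= P <= b/2 else 0
    gray        G_hat = |M - H'|  * f(P),  f(P) = P if b/2 < P <= b else 0

where K is the skull-and-calcium mask, M the matter mask, H' the selected
hemorrhage mask, and b the minimum nonzero HU of the selected hemorrhage
region (fallback 40 HU, the upper bound of normal parenchyma, when no
hemorrhage is found). The |A - B| factor is the printed exclusive-difference
semantics: a pixel contributes only where exactly one of the two masks is 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure, segmentation

from .windowing import TransferParams, WindowSetting, as_hu_image, transform_image

__all__ = [
    "DEFAULT_SWEEP_LEVELS",
    "ExtractionConfig",
    "HemorrhageSweep",
    "ComponentSet",
    "binarize",
    "initial_hemorrhage_masks",
    "skull_mask",
    "matter_mask",
    "suspect_hemorrhage",
    "boundary_point_count",
    "select_hemorrhage_window",
    "csf_region",
    "white_matter_region",
    "gray_matter_region",
    "extract_components",
]

#: Window levels of the hemorrhage sweep (HU), width 10 each.
DEFAULT_SWEEP_LEVELS = (30.0, 35.0, 40.0, 45.0, 50.0, 55.0, 60.0, 65.0, 70.0, 75.0)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable parameters of the component-extraction pipeline."""

    sweep_ww: float = 10.0
    sweep_wl: Sequence[float] = DEFAULT_SWEEP_LEVELS
    skull_window: WindowSetting = WindowSetting(100.0, 135.0)
    matter_window: WindowSetting = WindowSetting(80.0, 40.0)
    transfer: TransferParams = TransferParams()
    binarize_threshold: int = 128
    hemorrhage_cap: float = 110.0
    csf_cap: float = 15.0
    wm_min: float = 15.0
    fallback_b: float = 40.0
    #: use H_l AND NOT K instead of |K - H_l| in the hemorrhage equation
    strict_containment: bool = False
    #: ablation toggle: when False, the HU caps in the suspect-region
    #: equations are dropped (f(P) = P everywhere)
    apply_thresholds: bool = True
    #: boundary tracer: "isocontour" (0.5-level trace) or "morph_acwe"
    contour_method: str = "isocontour"


@dataclass
class HemorrhageSweep:
    """State of the window-level sweep for hemorrhage selection."""

    settings: list[WindowSetting]
    regions: list[np.ndarray]
    boundary_counts: list[int]
    selected_index: Optional[int] = None
    min_hu: Optional[float] = None
    hemorrhage_mask: Optional[np.ndarray] = None  # H'

    def __post_init__(self) -> None:
        n = len(self.settings)
        if n < 2:
            raise ValueError("sweep needs at least 2 window settings")
        if len(self.regions) != n or len(self.boundary_counts) != n:
            raise ValueError("sweep lists must share one length")


@dataclass
class ComponentSet:
    """All extracted components of one slice."""

    hu: np.ndarray
    skull: np.ndarray  # K
    matter: np.ndarray  # M
    sweep: HemorrhageSweep
    hemorrhage_mask: np.ndarray  # H'
    hemorrhage_region: np.ndarray  # selected suspect region (zeros if none)
    csf: np.ndarray
    white_matter: np.ndarray
    gray_matter: np.ndarray
    min_hu: Optional[float]
    b: float
    config: ExtractionConfig = field(default_factory=ExtractionConfig)


def binarize(gray: np.ndarray, threshold: int = 128) -> np.ndarray:
    """Mask pixels whose intensity is *strictly* greater than threshold."""
    arr = np.asarray(gray)
    return (arr > threshold).astype(np.uint8)


def initial_hemorrhage_masks(
    P: np.ndarray,
    sweep_wl: Sequence[float] = DEFAULT_SWEEP_LEVELS,
    ww: float = 10.0,
    tp: TransferParams = TransferParams(),
    threshold: int = 128,
) -> list[np.ndarray]:
    """Binary masks H_l for each window level of the sweep (ascending)."""
    levels = list(sweep_wl)
    if len(levels) < 2:
        raise ValueError("sweep needs at least 2 window levels")
    if sorted(levels) != levels:
        raise ValueError("sweep levels must be sorted ascending")
    arr = as_hu_image(P)
    return [
        binarize(transform_image(arr, WindowSetting(ww, l), "sigmoid", tp), threshold)
        for l in levels
    ]


def skull_mask(
    P: np.ndarray,
    setting: WindowSetting = WindowSetting(100.0, 135.0),
    tp: TransferParams = TransferParams(),
    threshold: int = 128,
) -> np.ndarray:
    """Mask K of skull and intracranial calcium (high-HU structures)."""
    return binarize(transform_image(P, setting, "sigmoid", tp), threshold)


def matter_mask(
    P: np.ndarray,
    setting: WindowSetting = WindowSetting(80.0, 40.0),
    tp: TransferParams = TransferParams(),
    threshold: int = 128,
) -> np.ndarray:
    """Mask M from the brain window, used as the matter reference mask."""
    return binarize(transform_image(P, setting, "sigmoid", tp), threshold)


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def _capped(P: np.ndarray, keep: np.ndarray, apply_thresholds: bool) -> np.ndarray:
    """f(P): P where `keep`, else 0; identity when thresholds are ablated."""
    if not apply_thresholds:
        return P
    return np.where(keep, P, 0.0)


def suspect_hemorrhage(
    P: np.ndarray,
    H_l: np.ndarray,
    K: np.ndarray,
    hu_cap: float = 110.0,
    strict_containment: bool = False,
    apply_thresholds: bool = True,
) -> np.ndarray:
    """Suspect hemorrhage region for one sweep mask.

    Pixels masked in both H_l and K (skull/calcium) are excluded; nonzero
    entries carry the slice HU, capped at `hu_cap` (HU above 110 is not
    hemorrhage).
    """
    arr = as_hu_image(P)
    _check_shapes(arr, np.asarray(H_l), np.asarray(K))
    if strict_containment:
        mask = (np.asarray(H_l) == 1) & (np.asarray(K) == 0)
    else:
        mask = np.abs(np.asarray(K, dtype=float) - np.asarray(H_l, dtype=float)) > 0
    f = _capped(arr, arr <= hu_cap, apply_thresholds)
    return np.where(mask, f, 0.0)


def _largest_component(mask: np.ndarray) -> Optional[np.ndarray]:
    """Largest 8-connected component; area ties broken by the component
    containing the smallest row-major pixel index. None if mask is empty."""
    labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
    if n == 0:
        return None
    areas = np.bincount(labels.ravel())[1:]  # skip background
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area) + 1
    if len(candidates) == 1:
        best = candidates[0]
    else:
        flat = labels.ravel()
        best = min(candidates, key=lambda lab: int(np.flatnonzero(flat == lab)[0]))
    return labels == best


def _trace_vertices(comp: np.ndarray) -> int:
    """Vertex count of the outer 0.5-level iso-contour of a component."""
    padded = np.pad(comp.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0
    outer = max(contours, key=len)
    n = len(outer)
    if n > 1 and np.allclose(outer[0], outer[-1]):
        n -= 1  # closed contour repeats its first vertex
    return n


def boundary_point_count(region: np.ndarray, method: str = "isocontour") -> int:
    """Number of boundary points of the largest connected suspect area.

    The region is binarized (nonzero -> 1), its largest 8-connected
    component is taken, and the closed boundary of that component is traced.
    An empty region counts 0.
    """
    mask = np.asarray(region) != 0
    comp = _largest_component(mask)
    if comp is None:
        return 0
    if method == "isocontour":
        return _trace_vertices(comp)
    if method == "morph_acwe":
        # Morphological active contour initialized from the component
        # itself; the converged level set is traced the same way.
        evolved = segmentation.morphological_chan_vese(
            comp.astype(float), num_iter=10, init_level_set=comp.astype(np.int8)
        )
        return _trace_vertices(np.asarray(evolved, dtype=bool))
    raise ValueError(f"unknown contour method: {method!r}")


def select_hemorrhage_window(sweep: HemorrhageSweep) -> HemorrhageSweep:
    """Pick the sweep member following the largest boundary-count decrease.

    Over consecutive pairs (s, s+1), the drop counts[s] - counts[s+1] is
    computed; only positive drops qualify (a large low-HU structure leaving
    the mask). The selected region is the one *after* the largest drop, ties
    going to the smallest s. With no positive drop the slice is declared
    hemorrhage-free: H' is all-zero and min_hu is None.
    """
    counts = np.asarray(sweep.boundary_counts, dtype=float)
    drops = counts[:-1] - counts[1:]
    if drops.size == 0 or drops.max() <= 0:
        selected = None
    else:
        selected = int(np.argmax(drops)) + 1  # argmax takes the first maximum

    if selected is None:
        hp = np.zeros_like(sweep.regions[0], dtype=np.uint8)
        min_hu = None
    else:
        region = sweep.regions[selected]
        hp = (region > 0).astype(np.uint8)
        positive = region[region > 0]
        # an empty selected region leaves min_hu undefined; callers fall
        # back to the configured b
        min_hu = float(positive.min()) if positive.size else None
    return replace(
        sweep, selected_index=selected, min_hu=min_hu, hemorrhage_mask=hp
    )


def csf_region(
    P: np.ndarray,
    M: np.ndarray,
    Hp: np.ndarray,
    csf_cap: float = 15.0,
    apply_thresholds: bool = True,
) -> np.ndarray:
    """Suspect CSF region: matter/hemorrhage exclusive difference, <= 15 HU."""
    arr = as_hu_image(P)
    _check_shapes(arr, np.asarray(M), np.asarray(Hp))
    mask = np.abs(np.asarray(M, dtype=float) - np.asarray(Hp, dtype=float)) > 0
    f = _capped(arr, arr <= csf_cap, apply_thresholds)
    return np.where(mask, f, 0.0)


def white_matter_region(
    P: np.ndarray,
    M: np.ndarray,
    Hp: np.ndarray,
    a: float = 15.0,
    b: float = 40.0,
    apply_thresholds: bool = True,
) -> np.ndarray:
    """Suspect white matter: HU in [a, b/2] under the exclusive difference.

    b is the minimum HU of the selected hemorrhage region; with b <= a the
    band is empty and an all-zero region is returned.
    """
    arr = as_hu_image(P)
    _check_shapes(arr, np.asarray(M), np.asarray(Hp))
    if b <= a and apply_thresholds:
        return np.zeros_like(arr)
    mask = np.abs(np.asarray(M, dtype=float) - np.asarray(Hp, dtype=float)) > 0
    f = _capped(arr, (arr >= a) & (arr <= b / 2.0), apply_thresholds)
    return np.where(mask, f, 0.0)


def gray_matter_region(
    P: np.ndarray,
    M: np.ndarray,
    Hp: np.ndarray,
    b: float = 40.0,
    apply_thresholds: bool = True,
) -> np.ndarray:
    """Suspect gray matter: HU in (b/2, b] under the exclusive difference."""
    arr = as_hu_image(P)
    _check_shapes(arr, np.asarray(M), np.asarray(Hp))
    mask = np.abs(np.asarray(M, dtype=float) - np.asarray(Hp, dtype=float)) > 0
    f = _capped(arr, (arr > b / 2.0) & (arr <= b), apply_thresholds)
    return np.where(mask, f, 0.0)


def extract_components(
    P: np.ndarray, config: ExtractionConfig = ExtractionConfig()
) -> ComponentSet:
    """Run the full extraction pipeline on one slice. Deterministic."""
    arr = as_hu_image(P)
    tp = config.transfer
    K = skull_mask(arr, config.skull_window, tp, config.binarize_threshold)
    M = matter_mask(arr, config.matter_window, tp, config.binarize_threshold)
    H_masks = initial_hemorrhage_masks(
        arr, config.sweep_wl, config.sweep_ww, tp, config.binarize_threshold
    )
    regions = [
        suspect_hemorrhage(
            arr,
            h,
            K,
            config.hemorrhage_cap,
            config.strict_containment,
            config.apply_thresholds,
        )
        for h in H_masks
    ]
    counts = [boundary_point_count(r, config.contour_method) for r in regions]
    sweep = HemorrhageSweep(
        settings=[WindowSetting(config.sweep_ww, l) for l in config.sweep_wl],
        regions=regions,
        boundary_counts=counts,
    )
    sweep = select_hemorrhage_window(sweep)
    hp = sweep.hemorrhage_mask
    selected_region = (
        regions[sweep.selected_index]
        if sweep.selected_index is not None
        else np.zeros_like(arr)
    )
    b = sweep.min_hu if sweep.min_hu is not None else config.fallback_b
    csf = csf_region(arr, M, hp, config.csf_cap, config.apply_thresholds)
    wm = white_matter_region(arr, M, hp, config.wm_min, b, config.apply_thresholds)
    gm = gray_matter_region(arr, M, hp, b, config.apply_thresholds)
    return ComponentSet(
        hu=arr,
        skull=K,
        matter=M,
        sweep=sweep,
        hemorrhage_mask=hp,
        hemorrhage_region=selected_region,
        csf=csf,
        white_matter=wm,
        gray_matter=gm,
        min_hu=sweep.min_hu,
        b=b,
        config=config,
    )
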