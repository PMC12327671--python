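"""RGB rendering of extracted brain components.

Fixed colors mark skull (gray), white-and-gray matter (green) and CSF
(blue); hemorrhage pixels get an *adaptive red* channel that encodes the
HU value: brightest (255) at the suspect region's minimum HU — fresh,
unclotted blood — falling linearly to 55 at the 110-HU cap, so clot ages
render as distinguishable shades while never fading into black.

    r(i,j) = H'(i,j) * round(|255 - (200 / (110 - min_hu)) * (P(i,j) - min_hu)|)

Three output styles exist: a *full* component view, a *dnn* view showing
only skull and hemorrhage (the classifier input: bleeding location relative
to the skull is what separates hemorrhage types), and an *overlay* view
painting the hemorrhage on the brain-window grayscale for radiologists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .components import ComponentSet
from .windowing import (
    TransferParams,
    WindowSetting,
    as_hu_image,
    round_half_up,
    transform_image,
)

__all__ = [
    "Palette",
    "adaptive_red",
    "compose_full_view",
    "compose_dnn_view",
    "compose_overlay_view",
]

RGB = tuple[int, int, int]


def _check_rgb(c: RGB) -> RGB:
    if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
        raise ValueError(f"invalid RGB color {c!r}")
    return tuple(int(v) for v in c)


@dataclass(frozen=True)
class Palette:
    """Fixed component colors (8-bit RGB)."""

    skull: RGB = (155, 155, 155)
    matter: RGB = (0, 145, 0)
    csf: RGB = (25, 25, 145)
    background: RGB = (0, 0, 0)

    def __post_init__(self) -> None:
        for c in (self.skull, self.matter, self.csf, self.background):
            _check_rgb(c)


def adaptive_red(
    P: np.ndarray,
    Hp: np.ndarray,
    min_hu: float,
    hu_cap: float = 110.0,
    clamp: bool = False,
) -> np.ndarray:
    """Red channel for hemorrhage pixels, in [55, 255] for HU in
    [min_hu, hu_cap].

    Off-mask pixels are 0. By construction of the pipeline no in-mask pixel
    can lie below min_hu or above the cap; this is asserted rather than
    clamped, except in ablation runs (``clamp=True``) where the cap no
    longer bounds the mask.
    """
    arr = as_hu_image(P)
    hp = np.asarray(Hp)
    if arr.shape != hp.shape:
        raise ValueError(f"shape mismatch: {arr.shape} vs {hp.shape}")
    if min_hu >= hu_cap:
        raise ValueError(f"degenerate red scale: min_hu={min_hu} >= cap={hu_cap}")
    on = hp != 0
    if on.any():
        in_vals = arr[on]
        if in_vals.min() < min_hu:
            raise ValueError("in-mask HU below the suspect-region minimum")
        if not clamp and in_vals.max() > hu_cap:
            raise ValueError("in-mask HU above the hemorrhage cap")
    r = round_half_up(np.abs(255.0 - (200.0 / (hu_cap - min_hu)) * (arr - min_hu)))
    if clamp:
        r = np.clip(r, 0.0, 255.0)
    out = np.where(on, r, 0.0)
    return out.astype(np.uint8)


def _blank(shape, color: RGB) -> np.ndarray:
    img = np.zeros(shape + (3,), dtype=np.uint8)
    img[...] = color
    return img


def _paint(img: np.ndarray, mask: np.ndarray, color: RGB) -> None:
    img[np.asarray(mask) != 0] = color


def _red_layer(comp: ComponentSet) -> tuple[np.ndarray, np.ndarray]:
    """(mask, red channel) for the selected hemorrhage, empty-safe."""
    hp = comp.hemorrhage_mask
    if comp.min_hu is None or not np.any(hp):
        return np.zeros_like(hp), np.zeros(hp.shape, dtype=np.uint8)
    red = adaptive_red(
        comp.hu,
        hp,
        comp.min_hu,
        comp.config.hemorrhage_cap,
        clamp=not comp.config.apply_thresholds,
    )
    return hp, red


def compose_full_view(comp: ComponentSet, palette: Palette = Palette()) -> np.ndarray:
    """All components on black; precedence hemorrhage > skull > CSF > GM > WM
    so blood is never occluded."""
    img = _blank(comp.hu.shape, palette.background)
    _paint(img, comp.white_matter, palette.matter)
    _paint(img, comp.gray_matter, palette.matter)
    _paint(img, comp.csf, palette.csf)
    _paint(img, comp.skull, palette.skull)
    hp, red = _red_layer(comp)
    on = hp != 0
    img[on] = 0
    img[on, 0] = red[on]
    return img


def compose_dnn_view(comp: ComponentSet, palette: Palette = Palette()) -> np.ndarray:
    """Classifier input style: only skull (gray) and hemorrhage (red)."""
    img = _blank(comp.hu.shape, palette.background)
    _paint(img, comp.skull, palette.skull)
    hp, red = _red_layer(comp)
    on = hp != 0
    img[on] = 0
    img[on, 0] = red[on]
    return img


def compose_overlay_view(
    P: np.ndarray,
    comp: ComponentSet,
    brain_setting: WindowSetting = WindowSetting(80.0, 40.0),
    tp: TransferParams = TransferParams(),
    method: str = "sigmoid",
) -> np.ndarray:
    """Reader style: hemorrhage painted over the brain-window grayscale."""
    arr = as_hu_image(P)
    if arr.shape != comp.hu.shape:
        raise ValueError("slice shape does not match extracted components")
    base = transform_image(arr, brain_setting, method, tp)
    img = np.repeat(base[..., None], 3, axis=2)
    hp, red = _red_layer(comp)
    on = hp != 0
    img[on] = 0
    img[on, 0] = red[on]
    return img
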