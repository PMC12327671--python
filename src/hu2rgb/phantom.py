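"""Synthetic 2D axial head phantom with per-component ground truth.

The phantom emulates the structures a non-contrast head CT slice shows, at
their literature HU ranges: an elliptical skull ring (700-1200 HU), a
peripheral gray-matter band (default 31 HU) around a white-matter interior
(25 HU), ventricular CSF (uniform 0-15 HU), one or more hemorrhage blobs
(default 60 HU) and an optional calcification (>110 HU), on an air
background (-1000 HU), plus optional additive Gaussian noise. Every
component's pixel set is returned as a ground-truth mask, so each pipeline
stage can be scored (e.g. by Dice overlap) without any external data.

Geometric constraints the extraction method relies on are enforced or
baked into the defaults:

* bleeds must lie strictly inside the skull's inner boundary (validated);
* the default bleed is subcortical and abuts the gray-matter band, so at
  the lowest sweep level the band+bleed form one connected region whose
  long boundary dominates the boundary-point counts; when the band leaves
  the mask (between levels 30 and 35) the count drops sharply and the
  window just after the drop isolates the bleed;
* the band is thick (10 px) and its HU sits below the midpoint of the
  adjacent sweep levels (31 HU between 30 and 35): under per-pixel noise a
  thin band at a knife-edge HU fragments into pieces smaller than the
  bleed, which silently hands the largest-component role (and hence the
  boundary-count sweep) to the bleed's own threshold crossing. The thick,
  lower-HU band stays connected at realistic noise and keeps a small
  speckle tail above window level 35.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Ellipse",
    "Blob",
    "PhantomSpec",
    "GroundTruth",
    "default_spec",
    "spec_from_dict",
    "generate_phantom",
    "dice",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: center (row, col), semi-axes (row, col)."""

    center: tuple[float, float]
    axes: tuple[float, float]

    def contains(self, rr: np.ndarray, cc: np.ndarray, strict: bool = False):
        d = ((rr - self.center[0]) / self.axes[0]) ** 2 + (
            (cc - self.center[1]) / self.axes[1]
        ) ** 2
        return d < 1.0 if strict else d <= 1.0


@dataclass(frozen=True)
class Blob:
    """Circular blob: center (row, col), radius in pixels, HU value."""

    center: tuple[float, float]
    radius: float
    hu: float

    def contains(self, rr: np.ndarray, cc: np.ndarray):
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom slice. Deterministic given `seed`."""

    shape: tuple[int, int] = (128, 128)
    skull_outer: Ellipse = Ellipse((64.0, 64.0), (54.0, 44.0))
    skull_thickness: float = 6.0
    skull_hu_range: tuple[float, float] = (700.0, 1200.0)
    gm_band_width: float = 10.0
    wm_hu: float = 25.0
    gm_hu: float = 31.0
    csf: tuple[Ellipse, ...] = (
        Ellipse((52.0, 52.0), (10.0, 4.0)),
        Ellipse((52.0, 76.0), (10.0, 4.0)),
    )
    csf_hu_range: tuple[float, float] = (0.0, 15.0)
    bleeds: tuple[Blob, ...] = (Blob((94.0, 64.0), 16.0, 60.0),)
    calcifications: tuple[Blob, ...] = (Blob((50.0, 64.0), 3.0, 120.0),)
    background_hu: float = -1000.0
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def skull_inner(self) -> Ellipse:
        t = self.skull_thickness
        return Ellipse(
            self.skull_outer.center,
            (self.skull_outer.axes[0] - t, self.skull_outer.axes[1] - t),
        )

    @property
    def wm_interior(self) -> Ellipse:
        w = self.gm_band_width
        inner = self.skull_inner
        return Ellipse(inner.center, (inner.axes[0] - w, inner.axes[1] - w))


@dataclass
class GroundTruth:
    """Pairwise-disjoint binary masks, one per component kind."""

    skull: np.ndarray
    wm: np.ndarray
    gm: np.ndarray
    csf: np.ndarray
    bleed: np.ndarray
    calcification: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {
            "skull": self.skull,
            "wm": self.wm,
            "gm": self.gm,
            "csf": self.csf,
            "bleed": self.bleed,
            "calcification": self.calcification,
        }


def default_spec(**overrides) -> PhantomSpec:
    """The default phantom, optionally with fields replaced."""
    return PhantomSpec(**overrides)


def spec_from_dict(data: dict) -> PhantomSpec:
    """Build a PhantomSpec from a parsed YAML mapping (subset of fields).

    Ellipses are given as ``{center: [r, c], axes: [ar, ac]}`` and blobs as
    ``{center: [r, c], radius: R, hu: V}``.
    """
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("phantom spec must be a mapping")
    allowed = {
        "shape",
        "skull_outer",
        "skull_thickness",
        "skull_hu_range",
        "gm_band_width",
        "wm_hu",
        "gm_hu",
        "csf",
        "csf_hu_range",
        "bleeds",
        "calcifications",
        "background_hu",
        "noise_sd",
        "seed",
    }
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown phantom spec key(s): {sorted(unknown)}")

    def ellipse(d: dict) -> Ellipse:
        return Ellipse(tuple(map(float, d["center"])), tuple(map(float, d["axes"])))

    def blob(d: dict) -> Blob:
        return Blob(tuple(map(float, d["center"])), float(d["radius"]), float(d["hu"]))

    kwargs: dict = {}
    for key in (
        "skull_thickness",
        "gm_band_width",
        "wm_hu",
        "gm_hu",
        "background_hu",
        "noise_sd",
    ):
        if key in data:
            kwargs[key] = float(data[key])
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "shape" in data:
        kwargs["shape"] = tuple(int(x) for x in data["shape"])
    for key in ("skull_hu_range", "csf_hu_range"):
        if key in data:
            kwargs[key] = tuple(float(x) for x in data[key])
    if "skull_outer" in data:
        kwargs["skull_outer"] = ellipse(data["skull_outer"])
    if "csf" in data:
        kwargs["csf"] = tuple(ellipse(d) for d in data["csf"])
    if "bleeds" in data:
        kwargs["bleeds"] = tuple(blob(d) for d in data["bleeds"])
    if "calcifications" in data:
        kwargs["calcifications"] = tuple(blob(d) for d in data["calcifications"])
    return PhantomSpec(**kwargs)


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, GroundTruth]:
    """Rasterize a phantom slice and its ground truth.

    Components are painted in order background, WM, GM band, CSF, bleeds,
    calcifications, skull ring; later paints overwrite earlier ones and the
    ground-truth masks record the final owner of each pixel, so they are
    disjoint by construction. Pixel membership uses center-of-pixel
    inclusion. Noise is zero-mean Gaussian, added after painting.
    """
    rows, cols = spec.shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"invalid phantom shape {spec.shape}")
    rng = np.random.default_rng(spec.seed)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)

    hu = np.full(spec.shape, spec.background_hu, dtype=float)
    owner = np.zeros(spec.shape, dtype=np.uint8)  # 0=background
    WM, GM, CSF, BLEED, CALC, SKULL = 1, 2, 3, 4, 5, 6

    inner = spec.skull_inner
    wm_int = spec.wm_interior
    if min(inner.axes) <= 0 or min(wm_int.axes) <= 0:
        raise ValueError("skull thickness / GM band leave no brain interior")

    brain = inner.contains(rr, cc)
    wm = wm_int.contains(rr, cc) & brain
    gm = brain & ~wm
    hu[wm] = spec.wm_hu
    owner[wm] = WM
    hu[gm] = spec.gm_hu
    owner[gm] = GM

    lo, hi = spec.csf_hu_range
    for e in spec.csf:
        m = e.contains(rr, cc)
        hu[m] = rng.uniform(lo, hi, size=int(m.sum()))
        owner[m] = CSF

    for b in spec.bleeds:
        m = b.contains(rr, cc)
        if not m.any():
            raise ValueError(f"bleed {b} rasterizes to no pixels")
        if not bool(inner.contains(rr[m], cc[m], strict=True).all()):
            raise ValueError(f"bleed {b} extends outside the skull inner boundary")
        hu[m] = b.hu
        owner[m] = BLEED

    for c in spec.calcifications:
        m = c.contains(rr, cc)
        hu[m] = c.hu
        owner[m] = CALC

    ring = spec.skull_outer.contains(rr, cc) & ~inner.contains(rr, cc)
    s_lo, s_hi = spec.skull_hu_range
    hu[ring] = rng.uniform(s_lo, s_hi, size=int(ring.sum()))
    owner[ring] = SKULL

    if spec.noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd, size=spec.shape)

    truth = GroundTruth(
        skull=(owner == SKULL).astype(np.uint8),
        wm=(owner == WM).astype(np.uint8),
        gm=(owner == GM).astype(np.uint8),
        csf=(owner == CSF).astype(np.uint8),
        bleed=(owner == BLEED).astype(np.uint8),
        calcification=(owner == CALC).astype(np.uint8),
    )
    return hu, truth


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(A) != 0
    b = np.asarray(B) != 0
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total
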