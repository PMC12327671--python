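"""YAML configuration for the preprocessing pipeline.

Every threshold of the method is exposed: the sweep (width, level list),
the skull and matter windows, the HU caps, the sigmoid transfer parameters,
the selection rule knobs and the palette. Omitted keys keep their defaults;
unknown keys are rejected to catch typos.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .components import ExtractionConfig
from .rendering import Palette
from .windowing import TransferParams, WindowSetting

__all__ = ["PipelineConfig", "load_config", "config_from_dict"]


@dataclass(frozen=True)
class PipelineConfig:
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    palette: Palette = field(default_factory=Palette)
    #: transfer used for the overlay view's grayscale base
    overlay_method: str = "sigmoid"


def _expect_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML mapping."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    _expect_keys(
        data,
        {
            "transfer",
            "sweep",
            "skull",
            "matter",
            "caps",
            "selection",
            "fallback_b",
            "strict_containment",
            "palette",
        },
        "config",
    )
    ext = ExtractionConfig()
    overlay_method = "sigmoid"

    t = data.get("transfer", {})
    _expect_keys(t, {"method", "U", "eps"}, "transfer")
    if t:
        tp = TransferParams(
            upper=float(t.get("U", 255.0)), eps=float(t.get("eps", 1.0))
        )
        ext = replace(ext, transfer=tp)
        overlay_method = str(t.get("method", "sigmoid"))
        if overlay_method not in ("sigmoid", "traditional"):
            raise ValueError(f"unknown transfer.method {overlay_method!r}")

    s = data.get("sweep", {})
    _expect_keys(s, {"ww", "wl_list"}, "sweep")
    if s:
        ext = replace(
            ext,
            sweep_ww=float(s.get("ww", ext.sweep_ww)),
            sweep_wl=tuple(float(x) for x in s.get("wl_list", ext.sweep_wl)),
        )

    for key, attr in (("skull", "skull_window"), ("matter", "matter_window")):
        w = data.get(key, {})
        _expect_keys(w, {"ww", "wl"}, key)
        if w:
            cur: WindowSetting = getattr(ext, attr)
            ext = replace(
                ext,
                **{
                    attr: WindowSetting(
                        float(w.get("ww", cur.width)), float(w.get("wl", cur.level))
                    )
                },
            )

    caps = data.get("caps", {})
    _expect_keys(caps, {"hemorrhage_hu", "csf_hu", "wm_min_hu"}, "caps")
    if caps:
        ext = replace(
            ext,
            hemorrhage_cap=float(caps.get("hemorrhage_hu", ext.hemorrhage_cap)),
            csf_cap=float(caps.get("csf_hu", ext.csf_cap)),
            wm_min=float(caps.get("wm_min_hu", ext.wm_min)),
        )

    sel = data.get("selection", {})
    _expect_keys(sel, {"mode", "tie_break", "contour"}, "selection")
    if sel:
        mode = sel.get("mode", "largest_decrease")
        tie = sel.get("tie_break", "smallest_index")
        if mode != "largest_decrease":
            raise ValueError(f"unknown selection.mode {mode!r}")
        if tie != "smallest_index":
            raise ValueError(f"unknown selection.tie_break {tie!r}")
        ext = replace(ext, contour_method=str(sel.get("contour", ext.contour_method)))

    if "fallback_b" in data:
        ext = replace(ext, fallback_b=float(data["fallback_b"]))
    if "strict_containment" in data:
        ext = replace(ext, strict_containment=bool(data["strict_containment"]))

    pal = data.get("palette", {})
    _expect_keys(pal, {"skull", "matter", "csf", "background"}, "palette")
    palette = Palette(
        **{k: tuple(int(c) for c in v) for k, v in pal.items()}
    )
    return PipelineConfig(extraction=ext, palette=palette, overlay_method=overlay_method)


def load_config(path=None) -> PipelineConfig:
    """Load a pipeline config from YAML; defaults when path is None."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)
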