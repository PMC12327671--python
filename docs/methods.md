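# Methods

## Model and procedure

The pipeline treats one 2D ncCT slice `P` of Hounsfield units (validated to
the plausible CT range [−1100, 3100]) and proceeds in three stages.

**Transfer functions.** The traditional windowing transform clamps HU
outside `[l − w/2, l + w/2]` to 0/255 and maps linearly inside (quantized
round-half-up). The sigmoid transform

    f(h) = U / (1 + exp(−(2(h − l)/w) · ln(U/ε − 1)))

is strictly increasing with `f(l) = U/2`, `f(l − w/2) = ε`,
`f(l + w/2) = U − ε`. `U` defaults to 255 and `ε` to 1.0 intensity unit;
`ε` controls how hard the out-of-window compression is (ε → 0 approaches a
step at the level — *not* the linear ramp — so the traditional and sigmoid
transforms agree in that limit only outside the window and at the level).
All mask building uses the sigmoid; binarization keeps intensities
strictly greater than 128, which for the sigmoid means HU strictly above
the window level (up to the quantization width).

**Window selection.** The sweep applies windows of width 10 HU at levels
{30, 35, …, 75} (the published level set; the accompanying prose mentions
an eleventh setting that is not printed, so the ten printed values are the
default and the list is configurable). For each level the suspect
hemorrhage region is

    Ĥ_l(i,j) = |K(i,j) − H_l(i,j)| · f(P(i,j)),   f(P) = P if P ≤ 110 else 0

with `K` the skull/calcium mask (window (100, 135), i.e. HU ∈ [85, 185]
mapped so that K = 1 above ≈135 HU) and `H_l` the sweep mask. The boundary
of the largest 8-connected component of each Ĥ_l is traced and its vertex
count recorded; the selected window is the one *following* the largest
positive decrease between consecutive counts, ties to the smaller level,
no positive decrease meaning "no hemorrhage". H′ marks the selected
region's positive entries; `b = min(Ĥ) > 0` (undefined → fallback 40 HU,
the upper bound of normal parenchyma).

**Component regions and rendering.** CSF, white matter and gray matter use
the same exclusive-difference algebra against the brain-window mask `M`
(window (80, 40)) and H′, with caps ≤15, [15, b/2], (b/2, b]. Rendering
maps skull to (155,155,155), matter to (0,145,0), CSF to (25,25,145) and
blood to `(r, 0, 0)` with `r = |255 − 200/(110 − b)·(P − b)|`, giving
255 at `P = b` and 55 at `P = 110`.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| sweep width / levels | 10 / {30..75 step 5} | HU | published sweep; narrow windows give sharp per-level masks |
| binarize threshold | 128 (strict) | intensity | published mask rule |
| skull window | (100, 135) | HU | bone/calcium above ≈135 HU; read as (WW, WL) like the brain window |
| brain window | (80, 40) | HU | standard brain display window |
| hemorrhage cap | 110 | HU | above 110 HU is not blood (calcium) |
| CSF cap | 15 | HU | CSF range 0–15 |
| WM minimum | 15 | HU | lower bound of parenchyma band |
| fallback b | 40 | HU | upper bound of normal parenchyma when no bleed found |
| U, ε | 255, 1.0 | intensity | 8-bit display; 1-unit margin keeps out-of-window detail |

## Numerical choices

- Quantization is round-half-up then clamp to [0, 255]; fixed so repeated
  runs are byte-identical.
- "log" in the sigmoid is the natural logarithm.
- Boundary points: 0.5-level iso-contour (marching squares) of the largest
  8-connected component, padded so border components close; the vertex
  count drops the closing duplicate. Component-area ties break toward the
  smallest row-major pixel index. A morphological active-contour mode
  (`selection.contour: morph_acwe`) is available since "active contour"
  admits many algorithms; only the *relative* drops matter for selection,
  so the tracer choice does not change which window wins on clean input.
- The outer `‖·‖` in the adaptive red formula is read as absolute value
  with round-half-up; for in-range HU the two readings (absolute value vs
  clamping) coincide. In-mask HU outside `[b, 110]` cannot occur by
  construction and is asserted, except under threshold ablation where the
  red channel is clamped instead.
- Coordinates are (row, col), 0-based, origin top-left.

## The exclusive-difference algebra and its consequences

The printed region equations multiply by `|A − B|`, which zeroes a pixel
when the two masks *agree* (both 1 — the stated exclusion — but also both
0). Combined with the HU caps this is very restrictive: a CSF pixel
(≤ 15 HU) is below the brain-window mask's effective threshold (> 40 HU),
so `M = H′ = 0` there and the CSF suspect map is typically empty; the same
applies to the matter bands. The package implements the equations as
printed — the hemorrhage channel, which the method exists for, is
unaffected — and exposes `strict_containment` (use `H_l AND NOT K`) for
the hemorrhage equation. Consumers should expect `full` renderings to be
dominated by skull and blood on typical inputs.

## The phantom: what it emulates and what it does not

The generator paints, on a 128×128 grid (≈1.7 mm/pixel): an elliptical
skull ring at 700–1200 HU; a peripheral gray-matter band (31 HU, 10 px)
around a white-matter interior (25 HU); two ventricular CSF ellipses
(uniform 0–15 HU); a subcortical 60-HU bleed (radius 16) abutting the
band; a small 120-HU calcification; optional iid Gaussian noise. Ground
truth is one disjoint mask per component. Determinism is guaranteed by a
single seed.

Geometry and HU values were chosen so the method's selection mechanism is
exercised non-trivially and remains stable under noise:

- The bleed must abut the band: at WL 30 the band+bleed form one connected
  region with a long boundary, and the largest count drop occurs when the
  band leaves the mask (WL 30 → 35), isolating the bleed. A free-floating
  band fragments under noise into pieces smaller than the bleed, silently
  handing the boundary count to the bleed's own threshold crossing.
- The band HU (31) sits below the 30/35 midpoint rather than on a level:
  tissue exactly at a sweep level is a knife-edge where any noise flips
  half its pixels into the selected mask. 31 HU is within the literature
  spread for gray matter (≈35 ± 10–20%).
- The band is thick (10 px) so it stays 8-connected at the ≈63% pixel
  retention that 3-HU noise leaves at WL 30.

With these defaults the noise-free pipeline recovers the bleed with Dice
1.0, and at noise sd 3 HU the 20-seed median Dice is ≈0.89. The phantom
does *not* emulate partial-volume gradients, beam hardening, streaks,
gantry tilt, asymmetric anatomy or 3D context; passing tests demonstrate
the algebra and the selection logic, not clinical segmentation accuracy.
Known failure mode: in roughly 8% of noisy seeds the selection still
latches onto the bleed's own threshold crossing (the level equal to the
bleed HU), yielding a near-empty hemorrhage mask — an inherent brittleness
of counts-based selection with a single-HU lesion, which is why the
robustness check asserts the median, not the minimum.

## Problem sizes

Tests run on 128×128 phantoms (single slices, ≤ 20 noisy replicates) and
16–32 pixel random grids for the algebraic oracles; the full suite
completes in a few seconds on one core.

## Limitations

- Slice-level (2D) only; no volume aggregation or registration.
- The sweep levels target acute-to-subacute blood on CT; MRI inputs would
  need a value mapping that is out of scope (the window set is
  configurable, the mapping is not provided).
- The Fig-style absolute boundary counts depend on the tracer; only
  relative drops are meaningful across implementations.
- DICOM reading is single-frame, uncompressed-or-backend-supported
  syntaxes; no DICOM writing or PACS networking.
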