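# envmech

Single-cell AFM and fluorescence analysis of bacterial envelope mechanics
under complement attack.

When the complement system's membrane attack complex (MAC, the C5b–C9 pore)
perforates the outer membrane of Gram-negative bacteria such as *E. coli*,
the cells do not die immediately: death follows a mechanical destabilization
of the whole envelope — loss of surface order, growing outer-membrane
defects, swelling and stiffening under turgor pressure — that precedes
inner-membrane permeation. `envmech` re-implements, as a tested and
reusable library, the quantitative single-cell analysis chain used to
establish that sequence, and pairs every stage with a ground-truthed
synthetic scene generator so each estimator can be validated against known
inputs.

It is aimed at AFM and quantitative-microscopy practitioners who want the
analysis (not the instrument control): it reads plain TIFF/CSV/JSON
exports, not vendor raw formats.

## What it computes

**AFM image conditioning and roughness** (`envmech.afm_image`) — masked
plane levelling, per-row polynomial alignment, the iterative flatten-base
background fit, Gaussian smoothing; RMS roughness of re-aligned crops
(the readout that quantifies surface disruption, e.g. 1.6 → 3.1 nm when a
cell's envelope fails); line profiles and feature-protrusion readouts
(MAC rims protrude ~3 nm above the corrugated membrane).

**MAC spatial statistics** (`envmech.mac_spatial`) — point patterns on a
projected spherocylinder cell footprint: axial densities in five bins from
midpoint to pole, nearest-neighbour distances, the pair distribution
function

&nbsp;&nbsp;&nbsp;&nbsp;g(r) = observed pairs in [r, r+dr) / λ · Σᵢ area(annulusᵢ ∩ region),

with per-point edge correction, dilate–skeletonize–longest-branch chain
analysis, and comparison against a complete-spatial-randomness (CSR) null:
replicate uniform patterns with the observed count over the same region,
rank-based empirical p-values, and a χ² test of axial counts against
area-proportional expectation.

**Force-curve mechanics** (`envmech.force_mech`) — constant baseline from
the far-from-surface tail, contact-point detection at the first sustained
deviation from the zero-force line, indentation δ = piezo travel −
cantilever bending (d = F/k), and a least-squares fit of the Hertz
sphere-on-half-space model

&nbsp;&nbsp;&nbsp;&nbsp;F = (4/3) · E/(1−ν²) · √R_tip · δ^{3/2},&nbsp;&nbsp;ν = 0.5, R_tip = 65 nm, δ ≤ 200 nm,

giving an effective Young's modulus E. Quantitative-imaging (QI) force
maps become un-indented height maps (contact point above a substrate
reference) and stiffness maps; time series of maps yield swelling
(relative height change), stiffening, and plateau detection after cell
death.

**Fluorescence morphometrics** (`envmech.morphometrics`) — rod-cell
segmentation, medial-axis distance-transform widths (poles excluded),
per-cell SYTOX intensity with a two-component positive/negative call, and
Welch's unequal-variance t test for group comparison.

**Synthetic scenes** (`envmech.synthetic_scene`) — every generator returns
its ground truth: corrugated membranes with annular MAC rims and ≥50 nm
defects, CSR or Thomas-clustered pore patterns, Hertzian force curves and
QI maps, swelling/stiffening trajectories, and two-channel fluorescence
populations. Named presets (`pre_disruption`, `post_disruption`,
`mac_patch`, `dying`, `melittin`, `untreated_width`, `treated_width`)
encode the study conditions so tests and scripts reference presets, not
magic numbers.

**Workflow** (`envmech.workflow`) — YAML-configured generate → condition →
analyze runs with per-stage seeds derived from one master seed and a
hashed artifact manifest; identical configs reproduce identical hashes.

## Worked example

```python
import numpy as np
from envmech import (
    scene_from_preset, simulate_timeseries, analyze_timeseries,
    relative_change, plateau_detect, rms_roughness,
)

# surface roughness before and after envelope disruption
for preset in ("pre_disruption", "post_disruption"):
    hm, truth = scene_from_preset(preset, seed=0)
    print(preset, round(rms_roughness(hm), 2), "nm")

# a dying cell: swelling and stiffening, then a plateau at death
mech = scene_from_preset("dying")          # 7% swelling, E 100 -> 150 kPa
frames, truth = simulate_timeseries(mech, n_frames=10, seed=0,
                                    grid_shape=(16, 16))
series = analyze_timeseries(frames)
dh, de = relative_change(series)
print(f"height change {dh:+.1%}, stiffness change {de:+.1%}")
print("plateau:", plateau_detect(series),
      "first SYTOX+ frame:", int(np.argmax(series.sytox_flags)))
```

prints

```
pre_disruption 1.51 nm
post_disruption 2.92 nm
height change +6.9%, stiffness change +48.2%
plateau: (True, 6) first SYTOX+ frame: 6
```

The single-seed roughness readouts scatter around the presets' 1.6 and
3.1 nm conditions (the seed medians recover them; see the acceptance
script); the
dying-cell series reports the programmed 7% swelling (inside the 5–10%
band of dying cells), ~50% stiffening, and an E plateau at the frame where
the cell turns SYTOX-positive — the mechanical signature that distinguishes
complement killing from, e.g., the melittin control preset, which dies
without swelling.

A configuration-driven version of the same pipeline:

```bash
envmech run examples/demo.yaml      # writes artifacts + manifest.json
envmech report out/manifest.json
```

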