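"""Grow per-channel cell masks from the nuclear margin and quantify them.

Masks expand in 0.5 um rings, outward up to the per-channel growing limit
(2.0 steps for AF488/AF594, 4.0 for eFluor 570 to capture elongated
connective-tissue cells) and inward toward the nucleus centre, stopping at
a sudden intensity step.  Contested pixels go to the nearer nucleus, so
masks are disjoint.
"""

import imic

cfg = imic.PhantomConfig(width_px=1380, height_px=1380, seed=1)
stack, truth, regions = imic.generate_phantom(cfg)
ps = stack.pixel_size_um

labels = imic.segment_nuclei(stack.channel("dapi"), pixel_size_um=ps)
gated = imic.remove_labels(labels, ps)
nuclei = imic.nucleus_records(gated, ps)
masks = imic.grow_all_channels(gated, stack)
cells = imic.quantify_cells(stack, nuclei, masks, regions)

print(f"{len(cells)} cell records")
for c in imic.MARKER_CHANNELS:
    print(f"{c:10s} mean mask area {cells[f'mask_area_um2_{c}'].mean():6.1f} um^2, "
          f"mean intensity {cells[f'mean_{c}'].mean():7.1f}")
# eFluor 570 masks are the largest: their deeper growing limit (4.0 steps
# = 2.0 um outward) reaches further into the cytoplasmic annulus.

events = imic.background_area(labels, stack, regions)
background = imic.estimate_background(events)
print("background medians:", {k: round(v, 1) for k, v in background.median.items()})
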