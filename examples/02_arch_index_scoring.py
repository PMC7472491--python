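"""Score one footprint: toe removal, third-band segmentation, arch index.

The arch index AI = B / (A + B + C) is the midfoot share of the toe-less
contact area after splitting the foot axis into three equal bands.  The
fixed cut-offs label AI < 0.17 concave (high arch), 0.17-0.28 normal and
AI > 0.28 flat.  The analytic AI of the generated template is the oracle the
measured value is checked against.
"""

from plantar import (
    FIXED_THRESHOLDS,
    SyntheticFootParams,
    compute_ai,
    generate_foot,
    label_foot,
    remove_toes_grid,
    segment_thirds,
)

params = SyntheticFootParams(midfoot_band_fraction=0.4, noise_cv=0.03, seed=7)
grid, truth = generate_foot(params)

toeless = remove_toes_grid(grid.values)  # heel-anchored disk keeps the sole only
seg = segment_thirds(toeless)
score = compute_ai(seg)

print(f"band areas   A={seg.area_A}  B={seg.area_B}  C={seg.area_C} contact cells")
print(f"axis length  {seg.axis_length} cells")
print(f"measured AI  {score.ai:.3f}   (analytic truth {truth.analytic_ai:.3f})")
print(f"label        {label_foot(score, FIXED_THRESHOLDS)}  (truth {truth.label})")
# The measured AI tracks the analytic value to a few thousandths; a band
# fraction of 0.4 lands just above the 0.17 cut-off, in the normal range.
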