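"""The footprint-image chain: detect, center, rotate, remove toes.

A both-feet pressure frame is rendered as the device-style 918x918 color
image, then pushed through the preprocessing chain: HSV foot detection
against the white background, centering each foot in its image half,
rotating each foot so its medial line is vertical, and masking everything
beyond the heel-anchored radius around the high-pressure (red) region.
The arch index measured from the processed image matches the analytic truth.
"""

from dataclasses import replace

from plantar import (
    SyntheticFootParams,
    combine_frame,
    compute_ai,
    contact_mask_from_image,
    generate_foot,
    grid_to_image,
    preprocess_frame,
    segment_thirds,
)

params = SyntheticFootParams(noise_cv=0.05, rotation_jitter=5.0, translation_jitter=2)
left, truth_left = generate_foot(replace(params, side="left", seed=1))
right, truth_right = generate_foot(replace(params, side="right", seed=2))

image = grid_to_image(combine_frame(left, right))
print(f"raw image: {image.pixels.shape}")

processed = preprocess_frame(image)
mask = contact_mask_from_image(processed)
w = mask.shape[1]
for name, truth, sl in (
    ("left", truth_left, slice(0, w // 2)),
    ("right", truth_right, slice(w // 2, w)),
):
    ai = compute_ai(segment_thirds(mask[:, sl])).ai
    print(
        f"{name:<5} foot: jittered by {truth.applied_rotation:+.1f} deg, "
        f"AI from processed image {ai:.3f} (truth {truth.analytic_ai:.3f})"
    )
# Pose jitter of several degrees is undone by the medial-line correction;
# the image-measured AI stays within ~0.01 of the analytic value.
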