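"""Extract the 14 plantar features and select the arch-related ones.

Fourteen per-foot scalars (pressure statistics, contact areas on the same
bands as the arch index, regional pressure ratios, foot-shape parameters)
are correlated with the arch index across the cohort; features with
|Pearson r| >= 0.2 survive.  Midfoot-driven features dominate because the
midfoot band is what the generator varies between classes.
"""

from plantar import (
    extract_features,
    feature_table,
    generate_cohort,
    remove_toes_grid,
    segment_thirds,
    compute_ai,
    select_features,
)

cohort = generate_cohort(n_subjects=24, seed=3)
vectors, ai_values = [], []
for foot in cohort.feet:
    toeless = remove_toes_grid(foot.grid.values)
    seg = segment_thirds(toeless)
    vectors.append(extract_features(toeless, seg))
    ai_values.append(compute_ai(seg).ai)

table = feature_table(vectors)
selection = select_features(table, ai_values, threshold=0.2)

print(f"{'feature':<22} {'r with AI':>9}  selected")
for name, r in selection.correlations.items():
    mark = "yes" if name in selection.selected else "no"
    print(f"{name:<22} {r:>9.3f}  {mark}")
print(f"\n{len(selection.selected)} of {len(table.columns)} features pass |r| >= 0.2")
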