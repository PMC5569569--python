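"""A miniature multi-subject comparison study with repeated-measures ANOVA.

Three surrogate "subjects" x three exercise programs are decomposed with
all three methods; per-subject program-averaged alignment is then tested
with a one-way repeated-measures ANOVA and LSD pairwise contrasts.
"""

from memdkit import (
    SegmentationSpec,
    SurrogateSpec,
    gen_surrogate,
    lsd_posthoc,
    rm_anova_oneway,
    run_comparison,
    segment_motion,
    subject_method_means,
)

recordings = {}
for subject in (1, 2, 3):
    for k, program in enumerate(("sitting", "standing", "walking")):
        rec = gen_surrogate(SurrogateSpec(seed=100 * subject + k))
        recordings[(subject, program)] = segment_motion(rec, SegmentationSpec())[0]

table = run_comparison(recordings)
means = subject_method_means(table, "alignment")
print("subject x method alignment means:")
print(means.round(3).to_string())
print()
print(rm_anova_oneway(means).round(4).to_string(index=False))
print()
print(lsd_posthoc(means).round(4).to_string(index=False))
# The condition row tests whether the three methods differ after removing
# between-subject variability; the LSD table shows which pairs drive it.
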