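# Minimal study configuration: two single-training conditions, fewer
# subjects, fixed seed. Run with:
#   tidlearn replicate --config examples/study_small.toml --out results/
seed = 11
conditions = ["auditory_single", "visual_single"]

[designs.auditory_single]
n_subjects = 7

[observers.visual_single]
lapse = 0.02
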