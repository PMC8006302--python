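"""Generate a synthetic two-cohort repertoire and classify it.

Builds a small case/control study with planted cohort-biased clonal
clusters, runs the repeated-holdout pipeline with true labels and with
the permuted-label control, and prints mean +/- sd holdout F1 and
accuracy for both. With real signal the true-label run should far exceed
the control, which should sit near 50%.
"""

import repstrat as rs

cfg = rs.SimConfig(
    n_case=16, n_control=16, seqs_per_subject=500,
    n_planted_clusters=8, planted_purity=0.9, seed=1,
)
reps, truth = rs.generate_repertoires(cfg)
print(f"{reps.n_sequences} sequences from {len(reps.subjects)} subjects")
print(f"{len(truth.table)} planted clusters "
      f"({(truth.table['biased_label'] == 'case').sum()} case-biased)")

pipe = rs.PipelineConfig(seed=3, n_iterations=20)
true_run = rs.repeated_cv(reps, pipe)
control = rs.permutation_control(reps, pipe)

s, c = true_run.summary(), control.summary()
print(f"true labels:      F1 = {s['mean_f1']:.3f} +/- {s['sd_f1']:.3f}, "
      f"accuracy = {s['mean_accuracy']:.3f}")
print(f"permuted control: F1 = {c['mean_f1']:.3f} +/- {c['sd_f1']:.3f}, "
      f"accuracy = {c['mean_accuracy']:.3f}")
print("the gap between the two lines is the recoverable cohort signal")
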