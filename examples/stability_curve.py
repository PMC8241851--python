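"""Bootstrap pattern-stability curve vs subsample size.

Subsamples a 120-subject synthetic cohort without replacement, rebuilds the
FDR-thresholded group connectivity pattern per replicate, and correlates it
with the full-sample pattern. The curve shows how large a sample is needed
for a stable multivariate causal-influence pattern.
"""

import numpy as np

from dynconn import stability, synth

basis = synth.make_hrf_basis(1.0, 8.0, 1)
design = synth.make_nback_design(
    tr_seconds=1.0, frames_per_session=40, n_sessions=1, cue_seconds=0.0,
    fixation_blocks=0, blocks_per_session=4, trials_per_block=4,
    trial_seconds=2.0)
template = synth.default_template_model(n_regions=5, basis=basis, seed=2)
spec = synth.CohortSpec(n_subjects=120, between_subject_sd=0.3,
                        master_seed=23)
cohort = synth.simulate_cohort(spec, template, design)
off = ~np.eye(5, dtype=bool)
edges = np.asarray([s.truth.coupling[1][off] for s in cohort])

curve = stability.pattern_stability(
    edges, sizes=[10, 20, 30, 50, 80, 120], n_boot=50, alpha=0.01, seed=1)
print("subsample size -> mean pattern correlation with full sample")
for size, mean, vals in zip(curve.sizes, curve.mean, curve.values):
    print(f"  n = {size:3d}   r = {mean:.3f}  (replicate sd {vals.std():.3f})")
# the correlation rises toward 1 and its spread shrinks as the subsample
# approaches the full cohort; at the full size it is exactly 1 by design
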