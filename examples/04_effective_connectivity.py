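"""Effective-connectivity estimation and its round-trip validation.

Prepares a structural matrix (scale to max 0.2, epsilon-seed missing
homologous links), pre-scales it by the synchrony ratio, then descends on
the link weights against a target FC.  The printed distance trace must be
non-increasing; the round-trip correlation (re-estimating EC from the
first pass's own best model FC) measures the self-consistency of the
procedure — near 1 means reliable.
"""

import numpy as np

from hopfnet import (
    CohortSpec,
    ECConfig,
    FilterSpec,
    compute_fc,
    estimate_intrinsic_frequencies,
    generate_sc,
    generate_two_state_cohort,
    group_average_fc,
    phase_locking_stats,
    prepare_sc,
    prescale_by_synchrony,
    preprocess,
    validate_roundtrip,
)
from hopfnet.connectivity import node_strength

band = FilterSpec()
n = 24
sc = generate_sc(n, density=0.35, seed=13)
spec = CohortSpec(n_subjects=4, n_rois=n, n_volumes=400, seed=13)
study = generate_two_state_cohort(spec, sc)

clean = [preprocess(ts, band) for ts in study.recordings("awake")]
fc_target = group_average_fc([compute_fc(c) for c in clean])
sync_target = float(np.mean(
    [phase_locking_stats(c, band, preprocessed=True).synchrony for c in clean]
))
omega = estimate_intrinsic_frequencies(clean, band)

cfg = ECConfig(max_iter=40, n_repeats=3, n_volumes=300)
prepared = prepare_sc(study.sc, study.homologous_pairs)
scaled, rounds = prescale_by_synchrony(prepared, sync_target, omega, cfg, seed=1)
print(f"synchrony pre-scaling: {rounds} round(s) toward target {sync_target:.3f}")

corr, first, second = validate_roundtrip(scaled, fc_target, omega, cfg, seed=2)
print(f"descent: FC distance {first.distances[0]:.3f} -> {first.distances[-1]:.3f} "
      f"over {len(first.distances) - 1} accepted updates")
print(f"mean EC node strength: {node_strength(first.ec).mean():.4f}")
print(f"round-trip EC correlation: {corr:.4f} (self-consistency of the estimate)")
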