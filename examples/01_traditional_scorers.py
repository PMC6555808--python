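"""Score one simulated night with the six traditional algorithms.

Each algorithm thresholds a weighted combination of nearby activity
counts into sleep/wake. The printout shows epoch-level agreement with
the PSG-derived truth: high sensitivity / lower specificity is the
classic signature of count-threshold scorers (they over-call sleep),
while the causal Sazonov scorer shows the opposite trade-off.
"""

import numpy as np

from sleepwake import (
    SimulationConfig,
    build_task_night,
    epoch_metrics,
    generate_subject,
    registered_scorers,
    score,
)

subject = generate_subject(SimulationConfig(seed=9), 0)
night = build_task_night(subject)
print(f"subject {subject.subject_id}: {len(night)} night epochs, "
      f"{100 * np.nanmean(night.truth.labels):.1f}% asleep by PSG\n")

print(f"{'algorithm':<14}{'accuracy':>9}{'sens':>7}{'spec':>7}{'f1':>7}")
for name in registered_scorers():
    pred = score(name, night.counts).predictions
    em = epoch_metrics(pred, night.truth)
    print(f"{name:<14}{em.accuracy:>9.1f}{em.sensitivity:>7.1f}{em.specificity:>7.1f}{em.f1:>7.1f}")

print("\ntheta controls the device scorer's wake threshold: lower theta -> more wake calls")
for theta in (10, 40, 80):
    em = epoch_metrics(score("oakley", night.counts, theta=theta).predictions, night.truth)
    print(f"  oakley theta={theta:<3} accuracy {em.accuracy:.1f}  specificity {em.specificity:.1f}")
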