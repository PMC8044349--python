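"""Covariate-adjusted nodal comparison and ROC discrimination.

Replays the nodal analysis on reported group moments: resamples betweenness
scores for the right putamen (AD vs SIVD) at the published means and SDs,
computes the empirical Mann-Whitney AUC, and compares it with the binormal
closed form.
"""

from strucnet import auc_recovery_experiment, binormal_auc, roc_auc
import numpy as np

# right-putamen betweenness moments: AD 610.14 +/- 222.58 (n=31),
# SIVD 230.00 +/- 132.35 (n=19); reported AUC 0.946
mean_auc, mc_se = auc_recovery_experiment(
    610.14, 222.58, 31, 230.00, 132.35, 19, n_reps=1000, rng=0
)
closed = binormal_auc(610.14, 222.58, 230.00, 132.35)
print(f"empirical mean AUC over 1000 resamples: {mean_auc:.4f} (MC SE {mc_se:.4f})")
print(f"binormal closed form:                    {closed:.4f}")
print(f"reported AUC:                            0.946")

# single-sample ROC with curve points
rng = np.random.default_rng(1)
scores = np.concatenate([rng.normal(610.14, 222.58, 31), rng.normal(230.0, 132.35, 19)])
labels = np.concatenate([np.ones(31, int), np.zeros(19, int)])
r = roc_auc(scores, labels)
print(f"one draw: AUC={r.auc:.3f}, {len(r.fpr)} ROC points, flipped={r.flipped}")
# The resampled AUC sits within a few hundredths of both the closed form and
# the reported value: the printed moments imply the printed discrimination.
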