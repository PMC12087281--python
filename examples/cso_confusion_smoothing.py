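"""Pseudo-count smoothing of a CSO confusion matrix.

A finite validation study leaves many (clinical, predicted) CSO pairs
unobserved; augmenting the counts with the training-prior frequencies keeps
every prediction probability strictly positive without distorting well-observed
rows.
"""

import numpy as np
import pandas as pd

from mcedscreen import ConfusionCounts, augment_confusion, fp_cso_distribution

labels = ["lung", "breast", "colorectal"]
counts = ConfusionCounts(
    matrix=pd.DataFrame(
        [[88, 7, 5], [3, 95, 2], [0, 0, 0]],  # colorectal row never observed
        index=labels, columns=labels,
    ),
    fp_counts=pd.Series([2, 0, 0], index=labels),
    prior_freq=pd.Series([0.5, 0.3, 0.2], index=labels),
)

p_tp = augment_confusion(counts, alpha=1.0)
p_fp = fp_cso_distribution(counts, alpha=1.0)

print("P(predicted CSO | clinical CSO), smoothed:")
print(p_tp.round(4))
print()
print("P(predicted CSO | false positive), smoothed:")
print(p_fp.round(4).to_string())
print()
print(
    "Rows with many observations barely move (lung diagonal "
    f"{counts.matrix.loc['lung','lung']}/100 -> {p_tp.loc['lung','lung']:.3f}); "
    "the never-observed colorectal row falls back to the reference prior, and "
    f"no probability is exactly zero (smallest: {p_tp.values.min():.4f})."
)
assert (p_tp.values > 0).all() and np.allclose(p_tp.sum(axis=1), 1.0)
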