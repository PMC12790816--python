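"""Label-based and unsupervised feature filtering on a toy expression matrix.

Simulates a small two-class cohort where a handful of features carry a real
group difference, then shows the two preprocessing paths: Mann-Whitney U
selection with Bonferroni correction (labels available) and the
variance-to-mean-ratio filter (labels unavailable).
"""

import numpy as np
import pandas as pd

from jointmds import drop_zero_variance, mannwhitney_select, variance_mean_ratio_filter

rng = np.random.default_rng(0)
n, p, p_signal = 40, 50, 5
labels = pd.Series(["LGG"] * 20 + ["GBM"] * 20, index=[f"s{i}" for i in range(n)])

X = rng.lognormal(mean=1.0, sigma=0.5, size=(n, p))
X[labels.to_numpy() == "GBM", :p_signal] *= 3.0  # planted group effect
X[:, -1] = 7.0  # one constant feature
F = pd.DataFrame(X, index=labels.index, columns=[f"g{j}" for j in range(p)])

F = drop_zero_variance(F)
print(f"after zero-variance drop: {F.shape[1]} of {p} features")

F_sel, report = mannwhitney_select(F, labels, alpha=0.05, top_n=10)
print(f"Mann-Whitney + Bonferroni keeps {report.n_selected} of {report.n_tested}")
print("selected features:", ", ".join(F_sel.columns))

F_vmr = variance_mean_ratio_filter(F, threshold=0.01)
print(f"variance-to-mean filter keeps {F_vmr.shape[1]} features (unsupervised path)")
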