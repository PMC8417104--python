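"""Rank-based cohort comparison and PCA on a feature matrix.

Shows the inferential layer on its own: Kruskal-Wallis omnibus, Dunn
pairwise post-hoc with Benjamini-Hochberg adjustment, an exact Wilcoxon
rank-sum test, and a small PCA.
"""

import numpy as np

from repfeat.stats import compare_groups, pca, wilcoxon_rank_sum

rng = np.random.default_rng(1)
groups = {
    "XLA": rng.normal(loc=-0.8, size=8),
    "old": rng.normal(loc=0.0, size=8),
    "young": rng.normal(loc=0.4, size=8),
}
res = compare_groups("shannon_norm", groups)
print(f"Kruskal-Wallis H = {res.kw_statistic:.3f}, p = {res.kw_pvalue:.4f}")
for gi, gj, z, p_raw, p_adj in res.pairwise:
    print(f"  Dunn {gi} vs {gj}: z = {z:+.2f}, p_raw = {p_raw:.4f}, p_adj = {p_adj:.4f}")

w, p = wilcoxon_rank_sum([1, 2], [3, 4])
print(f"exact Wilcoxon [1,2] vs [3,4]: rank sum = {w}, two-sided p = {p:.4f}")

x = rng.normal(size=(12, 4))
x[:, 1] = x[:, 0] * 2 + rng.normal(scale=0.05, size=12)  # near-duplicate feature
res = pca(x, ["f1", "f2", "f3", "f4"], [f"s{i}" for i in range(12)])
print("explained variance fractions:", np.round(res.explained_variance_ratio, 3))

# A negative Dunn z for (XLA, young) means the XLA group ranks lower; the
# BH-adjusted p controls the false discovery rate within the feature's
# three pairwise contrasts.  PC1 absorbs the correlated feature pair.
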