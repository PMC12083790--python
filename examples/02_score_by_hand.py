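"""Walk the separability score through its intermediate quantities.

Uses the committed 6x4 two-class anchor matrix whose class means,
deviations and scores are small enough to verify on paper.
"""

from sepselect import fixture_small, score_all, select_features
from sepselect.selector import abs_deviations, class_means

fx = fixture_small()
codes = fx.label_codes
print("labels:", list(fx.labels), "-> codes:", codes.tolist())

for j, gene in enumerate(fx.gene_ids):
    values = fx.values[:, j]
    means = class_means(values, codes)          # per-class means m_j
    b = abs_deviations(values, codes)           # |a_k - m_j|
    print(f"{gene}: values={values.tolist()} means={means.tolist()} "
          f"deviations={b.tolist()}")

print("scores (min over classes of max within-class deviation):",
      score_all(fx).tolist())
print("descending ranking:", select_features(fx, k=4).ranking.tolist())
# g3 scores 4 (both classes spread widely around their means); g2 scores 0
# (class A is constant on it), so descending order picks g3 first, g2 last
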