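"""The two k-nearest-neighbour baselines next to the template classifier.

POC-kNN ranks training samples by their POC peak against the test profile;
correlation-kNN ranks by 1 - Pearson correlation.  The template classifier
is effectively 1-NN against one averaged profile per subclass.
"""

import numpy as np

from pocclass import (
    SplitSpec,
    bdm_split,
    build_templates,
    classify_corr_knn,
    classify_dataset,
    classify_poc_knn,
    kruskal_wallis_rank,
    select_top,
    subset_features,
)
from pocclass.simulate import SyntheticConfig, generate

ds, _ = generate(
    SyntheticConfig(4, (15, 15, 15, 15), 1024, n_informative=100, seed=8)
)
train, test = bdm_split(ds, SplitSpec(q_per_class=5, seed=8))
keep = select_top(kruskal_wallis_rank(train), 100)  # pipeline step 1
train, test = subset_features(train, keep), subset_features(test, keep)

_, acc_tmpl = classify_dataset(test, build_templates(train))
acc_poc_knn = np.mean(
    [classify_poc_knn(x, train, k=5) == y for x, y in zip(test.values, test.labels)]
)
acc_corr_knn = np.mean(
    [classify_corr_knn(x, train, k=5) == y for x, y in zip(test.values, test.labels)]
)
print(f"template POC:        accuracy {acc_tmpl:.4f}")
print(f"POC 5-NN:            accuracy {acc_poc_knn:.4f}")
print(f"correlation 5-NN:    accuracy {acc_corr_knn:.4f}")
# Averaging each subclass into a template denoises the reference profile,
# so the template rule matches or edges out sample-level POC 5-NN while
# scoring only K correlations per test sample instead of M.
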