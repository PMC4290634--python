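"""Single SVM vs motif-clustered SVMs under five-fold cross-validation.

Builds the synthetic benchmark, balances the negatives by K-means
subsampling, and compares one SVM trained on all positives with the
per-motif-subgroup models routed through the decomposition tree.
"""

from glycmotif.benchmark import benchmark_config
from glycmotif.classifier import SVMParams, cross_validate
from glycmotif.sampling import SamplingConfig, kmeans_subsample
from glycmotif.simulate import make_dataset

data = make_dataset(benchmark_config(seed=1))
negatives = kmeans_subsample(
    data.neg_fragments, SamplingConfig(k=len(data.pos_fragments), seed=1)
)
print(f"balanced training data: {len(data.pos_fragments)} positives, "
      f"{len(negatives)} K-means-selected negatives\n")

params = SVMParams(C=8.0, gamma=2.0**-6)
print("          Sn   Sp   Acc  MCC   (pooled over 5 folds)")
for mode in ("single", "mdd_clustered"):
    m = cross_validate(
        data.pos_fragments, negatives, k=5, scheme="binary",
        mode=mode, params=params, seed=1,
    )
    print(f"{mode:<14}{m.format_row()}")
print("\nThe clustered model trains one SVM per motif subgroup and routes"
      "\neach query window to its subgroup; specialisation typically lifts"
      "\nsensitivity and specificity over the single pooled model.")
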