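"""Band-wise SVM classification and top-weight connection ranking.

Generates a cohort whose impaired group has reduced alpha coupling on three
ROI pairs, classifies impaired vs control per band, and annotates the
top-ranked connections with their network membership.
"""

import numpy as np

from trinet_eeg import (
    CohortDesign, CouplingSpec, FeatureTable, GroupEffect, connectivity_matrix,
    crossval_svm, generate_cohort, get_band, network_annotate, toy_atlas,
)

alpha = get_band("alpha")
atlas = toy_atlas(8, n_networks=2)
pairs = [(0, 1), (2, 3), (4, 5)]
design = CohortDesign(
    n_per_group=10, n_roi=8, noise_sd=0.5, n_epochs=40,
    sampling_rate=250.0, epoch_len=1.0, seed=21,
    effects=tuple(
        GroupEffect(CouplingSpec(p, alpha, np.pi / 2, 0.8),
                    values={"impaired": 0.2, "control": 0.8})
        for p in pairs
    ),
)
cohort = generate_cohort(design)
y = np.array([r.group for r in cohort])

print(f"{'band':>8} {'accuracy':>9} {'sens':>6} {'spec':>6}")
reports = {}
for band_name in ("delta", "theta", "alpha", "beta", "gamma"):
    band = get_band(band_name)
    X = np.array([connectivity_matrix(r, band, atlas=atlas).vector()
                  for r in cohort])
    ft = FeatureTable(X=X, y=y, feature_names=atlas.pair_names(),
                      band=band_name)
    rep = crossval_svm(ft, k_folds=5, seed=21)
    reports[band_name] = rep
    print(f"{band_name:>8} {rep.accuracy:>9.3f} {rep.sensitivity:>6.3f} "
          f"{rep.specificity:>6.3f}")

top = reports["alpha"].top_set  # floor(0.05 * 28) -> 1 feature
print(f"\ntop-ranked alpha connection(s): {top}")
print("network annotation:", network_annotate(top, atlas))
print("The effect was planted in alpha, so alpha beats the non-adjacent")
print("delta and gamma bands, and the top-weighted connection is one of the")
print("three planted pairs. Theta and beta share their printed edge")
print("frequencies (8, 13 Hz) with alpha, so on otherwise-silent synthetic")
print("data they inherit part of the effect through the shared edge bins.")
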