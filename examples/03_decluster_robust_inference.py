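"""Spatial declustering and cluster-robust inference.

Sites sampled close together share unmodelled local controls, so the
independence likelihood understates uncertainty.  This example declusters
the sites into quasi-independent subsets (>25 km apart), computes sandwich
standard errors from subset score sums, and runs the adjusted
likelihood-ratio test for one covariate.
"""

import numpy as np
from scipy import stats

from cengrm import (
    ModelSpec,
    bangladesh_like,
    decluster_sites,
    fit_weibull_grm,
    generate_synthetic_survey,
)
from cengrm.robust_inference import adjusted_lr_test, sandwich_covariance
from cengrm.weibull_grm import fit_design

# frailty_sd > 0 induces real within-cluster dependence
cfg = bangladesh_like(seed=11, n_sites=1000, n_clusters=60,
                      geology_levels=5, frailty_sd=0.5,
                      cluster_scatter_km=4.0)
ds, truth = generate_synthetic_survey(cfg)

sv = ds.survey
ca = decluster_sites(sv["site_id"], sv["lon"], sv["lat"],
                     link_threshold_km=25, max_subset_size=50)
print(f"declustering: {ca.n_subsets} independent subsets, "
      f"{len(ca.removed_sites)} sites removed to enforce >25 km separation")

cal = ds.subset(sv["site_id"].isin(ca.labels.index).to_numpy())
spec = ModelSpec(continuous_terms=("depth", "k_h"),
                 categorical_terms=("geology",))
fit = fit_weibull_grm(spec, cal)
sw = sandwich_covariance(fit, cal, ca)

j = fit.design.columns.index("k_h")
print(f"k_h coefficient {fit.beta[j]:+.4f}: "
      f"naive SE {fit.se()[j]:.4f}, robust SE {sw.robust_se[j]:.4f} "
      f"(ratio {sw.robust_se[j] / fit.se()[j]:.2f})")

t, delta, _ = cal.response
red = fit.design.drop_columns(fit.design.term_blocks["k_h"])
fit_red = fit_design(red.X, t, delta, design=red)
res = adjusted_lr_test(fit, fit_red, sw, fit.design.term_blocks["k_h"],
                       t=t, delta=delta)
print(f"k_h deletion: raw LR {res.raw_lr:.2f} "
      f"(naive p {stats.chi2.sf(res.raw_lr, res.df):.4g}), "
      f"adjusted LR {res.adjusted_lr:.2f} (p {res.formatted_p()})")
print()
print("Robust SEs exceed naive ones because nearby wells are correlated; "
      "the adjusted LR re-curves the likelihood so its chi-square "
      "reference stays valid under that dependence.")
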