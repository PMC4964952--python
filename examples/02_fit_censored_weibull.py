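"""Fitting the censored Weibull regression on a synthetic survey.

Generates a survey with known coefficients, fits the log-mean-link Weibull
model by maximum likelihood (nondetects enter through the CDF at their
detection limit), and reports coefficients as multiplicative effects.
"""

from cengrm import (
    ModelSpec,
    bangladesh_like,
    fit_weibull_grm,
    generate_synthetic_survey,
    multiplicative_effect,
)

cfg = bangladesh_like(seed=7, n_sites=1200, n_clusters=120,
                      geology_levels=6)
ds, truth = generate_synthetic_survey(cfg)
print(f"survey: {len(ds)} wells, {ds.n_censored} nondetects "
      f"({100 * ds.n_censored / len(ds):.0f}%), "
      f"detection limits {sorted(float(x) for x in ds.survey['tau'].unique())}")

spec = ModelSpec(
    continuous_terms=("depth", "tssc", "k_h"),
    categorical_terms=("geology",),
    interactions=(("geology", "depth"), ("geology", "tssc")),
    name="demo",
)
fit = fit_weibull_grm(spec, ds)
print(f"shape alpha_hat = {fit.alpha_hat:.3f} (truth {cfg.alpha}), "
      f"log-likelihood {fit.loglik:.1f}, {fit.convergence['status']}")

co = fit.coefficients()
print(f"{'term':8s} {'fitted':>9s} {'truth':>9s}   per-unit effect")
for name in ("depth", "tssc", "k_h"):
    eff = multiplicative_effect(co[name])
    print(f"{name:8s} {co[name]:9.4f} {truth.beta[name]:9.4f}   "
          f"x{eff['factor']:.4f} ({eff['percent_change_exact']:+.2f}% "
          f"per unit)")
print()
print("Each exp(beta_j) multiplies the mean concentration per unit of the "
      "covariate; the common shape alpha fixes the coefficient of "
      "variation across all wells.")
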