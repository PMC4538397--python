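"""Predicting whole-plot AGB from the N largest trees.

Fits the per-N power models AGB_TOT = alpha * AGB_topN^beta across plots,
then the generic meta-model alpha(N), beta(N) valid for N in [5, 100], and
uses it to predict a plot total from its top-20 biomass.
"""

from toptrees import (
    SyntheticConfig,
    fit_generic_model,
    fit_power_models,
    generate_region,
    predict_agb_tot,
)

plots, _ = generate_region(SyntheticConfig(seed=2))
models = fit_power_models(plots, range(5, 101, 5))
for m in models:
    if m.n in (5, 20, 100):
        print(
            f"N={m.n:>3}: alpha={m.alpha:.3f} beta={m.beta:.3f} "
            f"R2={m.r2:.3f} RSEr={m.rser:.1%}"
        )
# R2 rises and the relative residual error falls as more large trees enter.

generic = fit_generic_model(models)
x = 250_000.0  # summed AGB of the 20 largest trees, kg/ha
pred = predict_agb_tot(x, 20, generic)
print(f"generic model: AGB_top20={x/1000:.0f} t/ha -> AGB_TOT={pred/1000:.0f} t/ha")
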