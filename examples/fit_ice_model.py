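"""Fit one directed ICE model from a handful of paired SMAVs.

Builds SMAVs for two earthworm species over four shared chemicals, pairs
them on the log10 scale, and fits the least-squares relation
log10(predicted) = a * log10(surrogate) + b.
"""

from soilice import SMAV, fit_ice, pair_species, predict_toxicity

smavs = [
    SMAV("Eisenia fetida", "carbaryl", "LC50", 106.0, 2),
    SMAV("Eisenia fetida", "copper", "LC50", 520.0, 3),
    SMAV("Eisenia fetida", "lindane", "LC50", 140.0, 1),
    SMAV("Eisenia fetida", "pentachlorophenol", "LC50", 83.0, 2),
    SMAV("Eisenia andrei", "carbaryl", "LC50", 75.0, 1),
    SMAV("Eisenia andrei", "copper", "LC50", 410.0, 2),
    SMAV("Eisenia andrei", "lindane", "LC50", 180.0, 1),
    SMAV("Eisenia andrei", "pentachlorophenol", "LC50", 62.0, 1),
]

data = pair_species(smavs, "Eisenia fetida", "Eisenia andrei", "LC50")
model = fit_ice(data)

print(f"model: {model.surrogate_species} -> {model.predicted_species} [{model.endpoint_type}]")
print(f"  slope a      = {model.slope_a:.3f}")
print(f"  intercept b  = {model.intercept_b:.3f}  (log10 mg/kg)")
print(f"  R^2 = {model.r_squared:.3f}   p = {model.p_value:.3g}   MSE = {model.mse:.3f}   n = {model.n}")

value = 250.0
pred = predict_toxicity(model, value)
print(f"predicted Eisenia andrei LC50 from a {value:g} mg/kg surrogate value: {pred:.1f} mg/kg")
# The slope near 1 says the two congeneric earthworms share chemical
# sensitivities almost one-to-one on the log scale; the prediction is the
# back-transformed regression value in mg/kg soil.
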