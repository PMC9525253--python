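"""Simulate a study area and run the full assessment on it.

Generates a reproducible synthetic bundle — compartment rectangles, 52
plots of 400 m² with Braun-Blanquet codes, species traits, and raw
indicator values with forest/grassland assessability — then scores it and
verifies that the injected per-indicator rankings are recovered.
"""

from urbes import SimulationConfig, score_bundle, simulate_study

bundle = simulate_study(SimulationConfig(seed=11))
print("plots per compartment:",
      bundle.surveys.groupby("compartment_id")["plot_id"].nunique().to_dict())

scores, averaged = score_bundle(bundle)
print("\naveraged ES-ED score per compartment:")
print(averaged.round(3).to_string())

raw = bundle.raw_values
ok = True
for ind in scores.columns:
    sub = raw[(raw["indicator_id"] == ind) & raw["assessable"]]
    injected = sub.set_index("compartment_id")["value"]
    got = scores.loc[injected.index, ind].abs()
    ok &= (injected.rank() == got.rank()).all()
print("\ninjected indicator rankings recovered by the score pipeline:", ok)
print(
    "\nscores are monotone in the raw magnitudes, so the generator's built-in\n"
    "compartment ordering survives standardization — the recovery check the\n"
    "synthetic module is designed around."
)
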