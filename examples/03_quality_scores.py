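"""Endogenous and exogenous quality indicators.

Scores the shipped registry of 28 published input datasets and shows the
two exogenous indicators on a toy comparison.
"""
from cropfuse import endogenous_scores, load_registry, q_fao, q_resolution

registry = load_registry()
print("dataset   endo-sum   (of 7)")
for acr in ("MRF", "SPAM", "GEOGLAM", "EU", "USA", "CA"):
    print(f"{acr:9s} {endogenous_scores(registry[acr]).total:6.3f}")
print(f"\nresolution score of a 0.05-degree product: "
      f"{q_resolution(0.05):.3f}")
print(f"statistics agreement, dataset 9.5 Mha vs reference 10 Mha: "
      f"{q_fao(9.5e6, 10e6):.3f}")
# Higher endogenous sums mean newer, finer, better-validated official
# datasets; the agreement score is 1 minus the capped relative error.
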