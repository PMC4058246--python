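"""Compute the six topological descriptors for the screening candidates and
evaluate the frozen published activity model.

The printed pEC50 values are predicted PPAR-γ agonist potencies on the
log10(1/EC50) scale — higher means more potent (5.0 corresponds to a 10 μM
EC50). The vendor-emulation conventions are the calibrated preset used for
the published worked example (see docs/methods.md).
"""

from phytoscreen import DS_EMULATION, descriptor_vector, eq1_predict, fixture_library

candidates = ["5-hydroxy-L-tryptophan", "abrine", "saussureamine C"]
library = {g.name: g for g in fixture_library()}

print(f"{'compound':28s} {'ES_Sum_sssCH':>12s} {'BIC':>7s} {'CHI_3_P':>8s} "
      f"{'JY':>6s} {'pEC50':>6s}")
for name in candidates:
    vec = descriptor_vector(library[name], DS_EMULATION)
    pred = eq1_predict(vec)
    print(f"{name:28s} {vec['ES_Sum_sssCH']:12.4f} {vec['BIC']:7.4f} "
          f"{vec['CHI_3_P']:8.4f} {vec['JY']:6.4f} {pred:6.2f}")
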