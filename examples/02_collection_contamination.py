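"""Quantify dead-space contamination of valve-gated vs whole-breath collection.

Runs the acquisition state machine on one breath at its own threshold, then
forces whole-breath collection, and sweeps the threshold error to show how
robust the gating is.
"""

import breathgate as bg

trace = bg.generate_breath(bg.BreathProfile(total_volume=500.0))
geometry = bg.DeviceGeometry(container_volume=0.0)
threshold = bg.separation_threshold(trace, geometry).threshold_flow

gated = bg.run_collection(trace, threshold, geometry)
whole = bg.run_collection(trace, threshold, geometry, trigger_at_start=True)

print(f"threshold            : {threshold:.2f} L/min")
print(f"gated   — volume {gated.collected_volume:6.1f} mL, "
      f"dead fraction {gated.collected_dead_fraction:.4f}")
print(f"whole   — volume {whole.collected_volume:6.1f} mL, "
      f"dead fraction {whole.collected_dead_fraction:.4f}")
# Gated collection keeps contamination near zero; collecting the whole
# breath stores the full 30% dead-space share.

table = bg.contamination_vs_threshold_error(
    trace, geometry, [0.10, 0.05, 0.0, -0.05, -0.10]
)
print("\nthreshold mis-estimation sweep:")
print(table[["relative_error", "collected_dead_fraction", "collected_volume"]]
      .to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# A threshold set too high (positive error) triggers early and admits some
# dead-space gas; too low only sacrifices a little end-tidal volume.
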