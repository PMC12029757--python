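"""Segment a single exhalation into dead-space and end-tidal gas.

Generates a 500 mL synthetic breath, applies the 30% dead-space rule, and
reports the valve switch times and the subject's flow threshold.
"""

import breathgate as bg

trace = bg.generate_breath(bg.BreathProfile(total_volume=500.0))
geometry = bg.DeviceGeometry(container_volume=100.0)
result = bg.separation_threshold(trace, geometry)

print(f"total exhaled volume : {result.v_total:7.1f} mL")
print(f"dead-space volume    : {result.v_dead:7.1f} mL (30% of total)")
print(f"end-tidal volume     : {result.v_endtidal:7.1f} mL")
print(f"t1 (dead space clear): {result.t1:7.3f} s")
print(f"t2 (container clear) : {result.t2:7.3f} s")
print(f"flow threshold       : {result.threshold_flow:7.2f} L/min")
# The threshold is the expiratory flow at t2: once flow decays below it,
# everything still coming out of the mouth is end-tidal (alveolar) gas.
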