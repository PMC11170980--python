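"""Simulate one calibrated subject through the staged-hemorrhage protocol.

Loads subject LR1 from the packaged reference table, builds the sheep-like
protocol (25 ml/kg hemorrhage over 15 min, 5 ml/kg top-ups at 50 and 70 min,
closed-loop infusion from minute 30), and prints the six model outputs at a
few landmark times. BP collapses with the hemorrhage, HR rises
compensatorily, and the resuscitation phase restores pressure while
hematocrit stays diluted (the infused fluid carries no red cells).
"""

import hemofluid as hf

lr1 = hf.load_reference_parameters()[0]
protocol = hf.make_sheep_protocol(weight_kg=40.0, params=lr1)
result = hf.simulate(lr1, protocol, output_interval=1.0)

print(f"subject {lr1.subject_id}: BV0={lr1.BV0} l, baseline BP={lr1.BP0:.1f} mmHg")
print(f"hemorrhage {protocol.total_loss():.2f} l, infusion {protocol.total_infusion():.2f} l")
print(f"{'t (min)':>8} {'BV (l)':>8} {'HCT (%)':>8} {'HR (bpm)':>9} "
      f"{'SV (ml)':>8} {'CO (l/min)':>10} {'BP (mmHg)':>10}")
for t in (0, 15, 30, 60, 120, 180):
    i = int(t)
    print(f"{t:8d} {result.bv[i]:8.3f} {result.hct[i]:8.1f} {result.hr[i]:9.1f} "
          f"{result.sv[i] * 1000:8.1f} {result.co[i]:10.2f} {result.bp[i]:10.1f}")
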