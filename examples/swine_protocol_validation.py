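"""Build a swine-like hemorrhage-to-target protocol and inspect it.

The anesthetized-swine study design bleeds at a constant rate until blood
pressure reaches a stop target (40 mmHg here), then gives repeated
500-ml-per-70-kg boluses, each followed by a 60-min washout. The stop time
depends on the subject's own dynamics, so a parameter set is needed to
compile the protocol; virtual subjects are then simulated under the exact
same input schedule.
"""

import hemofluid as hf

subject = hf.load_reference_parameters()[0]
protocol = hf.make_swine_protocol(weight_kg=70.0, params=subject,
                                  hemorrhage_rate_ml_per_kg_min=1.0,
                                  bp_stop_target_mmHg=40.0)

result = hf.simulate(subject, protocol, output_interval=1.0)
print(f"duration {protocol.duration:.0f} min, "
      f"hemorrhage {protocol.total_loss() * 1000:.0f} ml, "
      f"infused {protocol.total_infusion() * 1000:.0f} ml in boluses")
print(f"BP: baseline {result.bp[0]:.1f} mmHg, "
      f"minimum {result.bp.min():.1f} mmHg, final {result.bp[-1]:.1f} mmHg")
print("bolus windows (start min, rate l/min):",
      [(float(t), round(float(u), 3))
       for t, u in zip(protocol.times, protocol.infusion) if u > 0])
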