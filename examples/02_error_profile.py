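"""Measure per-cycle error rates from a control-phage spike-in.

The simulated run injects a 3% substitution spike at cycles 12-24 while
reporting a high Phred score there (the early-cycle miscalibration
regime): only the control profile reveals those cycles as unreliable.
"""

import dealkit as dk

cfg = dk.SimulationConfig(
    error_spec=dk.ErrorSpec(baseline=0.0005, spikes=((12, 24, 0.03),)),
    rng_seed=7,
)
ctrl = dk.simulate_phix(cfg, 20000)
profile = dk.compute_phix_profile(ctrl.reads, ctrl.reference)

print(f"control reads profiled: {len(ctrl.reads)} ({profile.n_excluded} excluded)")
for cycle in (5, 15, 20, 100, 300):
    print(f"R1 cycle {cycle:3d}: {profile.rate('R1', cycle):6.3f}% mismatches")
print("Cycles 12-24 exceed the 1% flagging threshold; the baseline "
      "cycles sit near 0.05%, below it.")
print(f"Phred 38 alone would promise {100 * (1 - dk.phred_error(38)):.4f}% accuracy "
      "everywhere - which the spike cycles do not deliver.")
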