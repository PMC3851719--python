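"""Simulate a small pulling ensemble and build its Jarzynski profile.

A calibrated apo-like double-well landscape is pulled by a stiff moving
restraint; the exponential work average gives the equilibrium free-energy
profile along the schedule, always bounded above by the mean work.
"""

import pullfe as pf

cfg = pf.load_config()
landscape = pf.calibrate_depth(cfg.systems["apo"].landscape, -2.5, 300.0)
print(f"bound-well depth after calibration: {landscape.wells[0].depth:.2f} kJ/mol")
print(f"quadrature breaking dF (ground truth): "
      f"{pf.quadrature_delta_f(landscape, 300.0):+.3f} kJ/mol")

protocol = pf.PullingProtocol()  # 0 -> 0.35 nm at 0.175 nm/ns, k = 3.9e4
ensemble = pf.simulate_ensemble(landscape, protocol, n_replicas=64, base_seed=2024)

jar = pf.jarzynski_profile(ensemble, 300.0)
mean = pf.mean_work_profile(ensemble)
print(f"\nfinal mean work      : {mean.values[-1]:+.3f} kJ/mol")
print(f"final Jarzynski F    : {jar.values[-1]:+.3f} kJ/mol")
print("(the exponential average is always below the mean work; the gap is "
      "the dissipation recovered by Jarzynski's identity)")
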