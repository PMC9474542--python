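"""Extract dwell-time kinetics of intra-cavity hopping.

The ligand's axial position is registered to a lattice of sites one
layer apart; a hop is committed only when the signal settles into the
core of the new site's cell, so thermal jitter at a cell boundary does
not fragment dwells. Detected statistics are compared with the exact
Markov ground truth of the generator.
"""

import numpy as np

from fibrilsite import (HoppingSpec, anle138b_topology, build_toy_fibril,
                        detect_dwell_events, dwell_time_summary,
                        simulate_hopping)
from fibrilsite.geometry import axial_series

fibril = build_toy_fibril(n_layers=16, residues_per_layer=4)
ligand = anle138b_topology()
spec = HoppingSpec(n_sites=16, site_spacing=0.48, rate_up=0.25,
                   rate_down=0.25, jitter_sigma=0.048, n_frames=20000,
                   frame_interval=0.05, n_trajectories=2, seed=4)
ensemble, truth = simulate_hopping(spec, ligand, fibril)

z = axial_series(ensemble, ligand, np.array([0.0, 0.0, 1.0]))
detected = detect_dwell_events(z, spec.site_spacing, origin=truth.origin,
                               times=[t.times for t in ensemble.trajectories])
summary = dwell_time_summary(detected)

print(f"ground truth: {truth.n_transitions()} transitions, "
      f"mean dwell {truth.durations().mean():.2f} ns")
print(f"detected:    {detected.n_transitions()} transitions, "
      f"mean dwell {summary.mean:.2f} +/- {summary.sem:.2f} ns "
      f"(n = {summary.n_events} uncensored events)")
print("The total exit rate is 0.5/ns, so interior dwells average ~2 ns; "
      "censored first/last dwells are excluded from the mean.")
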