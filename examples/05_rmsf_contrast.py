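"""Per-strand RMSF contrast between ligand-contacted and distant layers.

Two synthetic protein trajectories of the same fibril are compared: in
one, residues of the 'contact' layers fluctuate twice as strongly,
mimicking the local mobility increase a cavity-bound ligand induces.
Edge strands are excluded from the class averages.
"""

import numpy as np

from fibrilsite import build_toy_fibril, rmsf
from fibrilsite.model_io import Trajectory, TrajectoryEnsemble

fibril = build_toy_fibril(n_layers=8, residues_per_layer=6)
rng = np.random.default_rng(5)
contact_layers = {3, 4}

sigma = np.where(np.isin(fibril.layer_index, sorted(contact_layers)),
                 0.06, 0.03)[None, :, None]
trajs = [Trajectory(np.arange(2000) * 0.1,
                    fibril.coords[None]
                    + rng.normal(0, 1, (2000, fibril.n_atoms, 3)) * sigma)
         for _ in range(3)]
ensemble = TrajectoryEnsemble(tuple(fibril.atom_names),
                              tuple(fibril.elements), trajs)

table = rmsf(ensemble, fibril, superpose=False,
             contact_layers=contact_layers)
for cls in ("contact", "non_contact"):
    mean, sem = table.class_average(cls)
    print(f"{cls:12s} strands: RMSF = {mean:.4f} +/- {sem:.4f} nm")
print("The contact strands fluctuate about twice as much (input sigma "
      "0.06 vs 0.03 nm; RMSF = sigma * sqrt(3) for isotropic jitter).")
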