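"""Map ligand-protein contacts and classify per-frame binding modes.

A short hopping trajectory is trimmed (keep the last 75%), per-residue
contact probabilities are averaged over time and then over trajectories,
and each frame is assigned one of the four major binding modes (unbound,
partial, bound-without-polar-bonds, polar) from its heavy-atom contact
count and detected hydrogen/halogen bonds.
"""

from fibrilsite import (ContactCriteria, HoppingSpec, anle138b_topology,
                        build_toy_fibril, classify_ensemble,
                        contact_probabilities, discard_equilibration,
                        mode_populations, simulate_hopping)

fibril = build_toy_fibril(n_layers=8, residues_per_layer=6, seed=2)
ligand = anle138b_topology()
spec = HoppingSpec(n_sites=6, rate_up=0.3, rate_down=0.3, n_frames=400,
                   n_trajectories=2, seed=2)
ensemble, _ = simulate_hopping(spec, ligand, fibril)
ensemble = discard_equilibration(ensemble, fraction=0.25)
print(f"{ensemble.n_trajectories} trajectories, "
      f"{ensemble.trajectories[0].n_frames} frames each after trimming")

criteria = ContactCriteria()  # 0.4 nm heavy-atom rule, edge layers excluded
cmap = contact_probabilities(ensemble, fibril, ligand, criteria, "heavy")
top = cmap.nlargest(3, "probability")[["chain", "residue", "probability"]]
print("most contacted residues (heavy-atom rule, edge strands excluded):")
print(top.to_string(index=False))

labels = classify_ensemble(ensemble, fibril, ligand)
pops = mode_populations(labels)
print(pops[pops.kind == "major"].to_string(index=False))
print("Fractions are trajectory means of per-trajectory frame fractions; "
      "the four major modes always sum to 1.")
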