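"""Heuristic per-frame binding-mode classification.

Four mutually exclusive major modes describe how the ligand engages the
protofilament in a frame:

* ``I_unbound`` — no atomic contacts;
* ``II_partial`` — fewer than half of the ligand heavy atoms in contact
  with protein heavy atoms (transient surface binding);
* ``III_no_polar`` — half or more of the heavy atoms in contact but no
  hydrogen or halogen bond;
* ``IV_polar`` — at least one hydrogen or halogen bond, sub-typed by the
  ligand moiety involved: ``IVa`` pyrazole hydrogen bond, ``IVb``
  benzodioxole hydrogen bond, ``IVc`` bromophenyl halogen bond.

The presence of a polar bond dominates: a frame with a bond is mode IV
regardless of its contact count. "Atoms in contact" counts heavy atoms,
consistent with the heavy-atom contact definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import (ContactCriteria, PolarBondCriteria, HydrogenBond,
                           HalogenBond, ligand_protein_hbonds,
                           ligand_protein_xbonds, _considered_residues)
from .model_io import FibrilModel, LigandTopology, TrajectoryEnsemble
from scipy.spatial import cKDTree

MAJOR_MODES = ("I_unbound", "II_partial", "III_no_polar", "IV_polar")
SUB_MODES = ("IVa_pyrazole_HB", "IVb_benzodioxole_HB", "IVc_bromophenyl_XB")


@dataclass
class BindingModeLabel:
    frame_time: float               # ns
    major: str
    sub: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.major not in MAJOR_MODES:
            raise ValueError(f"unknown major mode {self.major!r}")
        unknown = set(self.sub) - set(SUB_MODES)
        if unknown:
            raise ValueError(f"unknown sub modes {sorted(unknown)}")
        if (self.major == "IV_polar") != bool(self.sub):
            raise ValueError("sub labels are present iff major is IV_polar")


def classify_frame(n_atoms_in_contact: int, n_heavy: int,
                   hbs: list[HydrogenBond] = (),
                   xbs: list[HalogenBond] = (),
                   frame_time: float = 0.0) -> BindingModeLabel:
    """Classify one frame from its contact count and polar bonds.

    ``n_atoms_in_contact`` is the number of ligand heavy atoms within
    the heavy-atom contact cutoff of any protein heavy atom.
    """
    if n_heavy <= 0:
        raise ValueError("n_heavy must be positive")
    if not (0 <= n_atoms_in_contact <= n_heavy):
        raise ValueError("contact count outside [0, n_heavy]")
    sub = set()
    for b in hbs:
        if b.ligand_group == "pyrazole":
            sub.add("IVa_pyrazole_HB")
        elif b.ligand_group == "benzodioxole":
            sub.add("IVb_benzodioxole_HB")
    if xbs:
        sub.add("IVc_bromophenyl_XB")
    if sub:
        return BindingModeLabel(frame_time, "IV_polar", frozenset(sub))
    if n_atoms_in_contact == 0:
        return BindingModeLabel(frame_time, "I_unbound")
    if n_atoms_in_contact < n_heavy / 2:
        return BindingModeLabel(frame_time, "II_partial")
    return BindingModeLabel(frame_time, "III_no_polar")


def classify_ensemble(ensemble: TrajectoryEnsemble, model: FibrilModel,
                      ligand: LigandTopology,
                      criteria: ContactCriteria | None = None,
                      bond_criteria: PolarBondCriteria | None = None,
                      ) -> list[list[BindingModeLabel]]:
    """Per-frame binding-mode labels for every trajectory."""
    criteria = criteria or ContactCriteria()
    bond_criteria = bond_criteria or PolarBondCriteria()
    residues = set(_considered_residues(model, criteria.exclude_edge_layers))
    res_idx = model.residue_atom_indices()
    keep = np.concatenate([res_idx[k] for k in residues]) if residues else \
        np.arange(model.n_atoms)
    prot_heavy = keep[model.heavy_mask[keep]]
    tree = cKDTree(model.coords[prot_heavy])
    lig_heavy = ligand.heavy_mask
    n_heavy = ligand.n_heavy

    labelled = []
    for traj in ensemble.trajectories:
        labels = []
        for t, frame in zip(traj.times, traj.coords):
            d, _ = tree.query(frame[lig_heavy], k=1)
            n_contact = int(np.sum(d <= criteria.heavy_cutoff))
            hbs = ligand_protein_hbonds(frame, ligand, model, bond_criteria,
                                        residues)
            xbs = ligand_protein_xbonds(frame, ligand, model, bond_criteria,
                                        residues)
            labels.append(classify_frame(n_contact, n_heavy, hbs, xbs,
                                         frame_time=float(t)))
        labelled.append(labels)
    return labelled


def mode_populations(labels_per_trajectory) -> pd.DataFrame:
    """Mode fractions: trajectory-mean of per-trajectory frame fractions.

    Returns one row per major mode and sub mode with columns
    ``mode, fraction, sem, kind``; fractions over the four major modes
    sum to one.
    """
    if not labels_per_trajectory or any(len(t) == 0
                                        for t in labels_per_trajectory):
        raise ValueError("need at least one labelled frame per trajectory")
    all_modes = list(MAJOR_MODES) + list(SUB_MODES)
    rows = []
    for labels in labels_per_trajectory:
        n = len(labels)
        counts = dict.fromkeys(all_modes, 0)
        for lab in labels:
            counts[lab.major] += 1
            for s in lab.sub:
                counts[s] += 1
        rows.append([counts[m] / n for m in all_modes])
    arr = np.array(rows)
    frac = arr.mean(axis=0)
    sem = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
           if arr.shape[0] > 1 else np.full(arr.shape[1], np.nan))
    return pd.DataFrame({
        "mode": all_modes,
        "fraction": frac,
        "sem": sem,
        "kind": ["major"] * len(MAJOR_MODES) + ["sub"] * len(SUB_MODES),
    })
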