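"""Protofilament axis, insertion depth, equilibration trimming and RMSF.

The protofilament axis is the normalised mean of backbone N->H unit
vectors of every second residue in the folded N-terminal part of the
fold (default start G36, stride 2): in a parallel in-register cross-beta
stack these amide vectors all point along the stacking direction. The
insertion depth x is the centre-of-mass distance between the ligand
pyrazole ring and the edge beta-strand layer (the protofilament tip).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .model_io import FibrilModel, LigandTopology, Trajectory, TrajectoryEnsemble

BACKBONE_NAMES = ("N", "H", "CA", "C", "O")
BACKBONE_HEAVY = ("N", "CA", "C", "O")


@dataclass
class AxisDefinition:
    """Residue selection defining the stacking axis from amide NH vectors."""

    start_residue: int = 36
    stride: int = 2
    residue_span: tuple[int, int] = (36, 56)

    def selected_residues(self) -> list[int]:
        lo, hi = self.residue_span
        start = max(self.start_residue, lo)
        return list(range(start, hi + 1, self.stride))


def protofilament_axis(model: FibrilModel,
                       axis_def: AxisDefinition | None = None) -> np.ndarray:
    """Unit vector along the fibril stacking axis.

    Averages unit N->H vectors over the selected residues (across all
    layers in which they occur), normalises, and orients the result from
    layer 0 toward the last layer.
    """
    axis_def = axis_def or AxisDefinition()
    if axis_def.stride < 1:
        raise ValueError("stride must be >= 1")
    wanted = set(axis_def.selected_residues())

    vectors = []
    for (chain, resid), idx in model.residue_atom_indices().items():
        if resid not in wanted:
            continue
        names = model.atom_names[idx]
        n_pos = [model.coords[i] for i, nm in zip(idx, names) if nm == "N"]
        h_pos = [model.coords[i] for i, nm in zip(idx, names)
                 if nm in ("H", "HN", "H1")]
        if not n_pos:
            continue
        if not h_pos:
            raise ValueError(
                f"residue {resid} (chain {chain}) selected for the axis "
                f"has no amide hydrogen")
        v = h_pos[0] - n_pos[0]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"zero-length NH vector at residue {resid}")
        vectors.append(v / norm)
    if not vectors:
        raise ValueError("no residues matched the axis definition")
    mean = np.mean(vectors, axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        raise ValueError("NH vectors cancel; axis undefined")
    axis = mean / norm

    if model.layer_count >= 2:
        span = (model.layer_centroid(model.layer_count - 1)
                - model.layer_centroid(0))
        if axis @ span < 0:
            axis = -axis
    return axis


# ---------------------------------------------------------------------------
# Insertion depth
# ---------------------------------------------------------------------------

def _com(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return np.average(coords, axis=0, weights=masses)


def insertion_depth(frame: np.ndarray, ligand: LigandTopology,
                    model: FibrilModel, tip_layer: int = 0) -> float:
    """Distance (nm) between the pyrazole-ring COM and the tip-layer COM.

    ``frame`` holds the ligand coordinates (n_ligand_atoms, 3) in nm.
    Both centres of mass are mass-weighted; hydrogens are included where
    present.
    """
    ring = ligand.group_indices("pyrazole_ring")
    if ring.size == 0:
        raise ValueError("pyrazole_ring group is empty")
    frame = np.asarray(frame, dtype=float)
    lig_com = _com(frame[ring], ligand.masses[ring])
    tip_idx = model.layer_atom_indices(tip_layer)
    tip_com = _com(model.coords[tip_idx], model.masses[tip_idx])
    return float(np.linalg.norm(lig_com - tip_com))


def depth_series(ensemble: TrajectoryEnsemble, ligand: LigandTopology,
                 model: FibrilModel, tip_layer: int = 0) -> list[np.ndarray]:
    """Per-frame insertion depth for every trajectory (vectorised)."""
    ring = ligand.group_indices("pyrazole_ring")
    if ring.size == 0:
        raise ValueError("pyrazole_ring group is empty")
    w = ligand.masses[ring]
    w = w / w.sum()
    tip_idx = model.layer_atom_indices(tip_layer)
    tip_com = _com(model.coords[tip_idx], model.masses[tip_idx])
    out = []
    for traj in ensemble.trajectories:
        coms = np.einsum("fai,a->fi", traj.coords[:, ring, :], w)
        out.append(np.linalg.norm(coms - tip_com, axis=1))
    return out


def axial_series(ensemble: TrajectoryEnsemble, ligand: LigandTopology,
                 axis: np.ndarray, origin: np.ndarray | None = None,
                 ) -> list[np.ndarray]:
    """Pyrazole-ring COM projected on the fibril axis, per frame."""
    ring = ligand.group_indices("pyrazole_ring")
    w = ligand.masses[ring]
    w = w / w.sum()
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    out = []
    for traj in ensemble.trajectories:
        coms = np.einsum("fai,a->fi", traj.coords[:, ring, :], w)
        out.append((coms - origin) @ axis)
    return out


# ---------------------------------------------------------------------------
# Equilibration trimming
# ---------------------------------------------------------------------------

def discard_equilibration(ensemble: TrajectoryEnsemble,
                          fraction: float = 0.25) -> TrajectoryEnsemble:
    """Drop the initial equilibration phase of every trajectory.

    Removes the first ``floor(fraction * n_frames)`` frames of each
    trajectory independently, keeping the last (1 - fraction) of the
    data (default: keep the last 75%).
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must be in [0, 1)")
    trimmed = []
    for traj in ensemble.trajectories:
        n_drop = int(np.floor(fraction * traj.n_frames))
        trimmed.append(Trajectory(times=traj.times[n_drop:],
                                  coords=traj.coords[n_drop:]))
    return replace(ensemble, trajectories=trimmed)


# ---------------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto ref
    (least squares, unweighted)."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, rc - R @ mc


@dataclass
class RmsfTable:
    """Per-residue RMSF (nm) with SEM across trajectories and strand class."""

    chain_ids: np.ndarray
    resids: np.ndarray
    layer: np.ndarray
    rmsf: np.ndarray                # (n_residues,) nm, mean over trajectories
    sem: np.ndarray                 # NaN for a single trajectory
    strand_class: np.ndarray        # "contact" | "non_contact" | "edge"

    def class_average(self, strand_class: str) -> tuple[float, float]:
        """(mean, SEM over residues) of per-residue RMSF for one class."""
        sel = self.strand_class == strand_class
        if not np.any(sel):
            raise ValueError(f"no residues in class {strand_class!r}")
        vals = self.rmsf[sel]
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 \
            else float("nan")
        return float(vals.mean()), sem


def per_atom_rmsf(coords: np.ndarray) -> np.ndarray:
    """Per-atom RMSF (nm) of a (n_frames, n_atoms, 3) coordinate array:
    root time-mean squared deviation from the time-mean position."""
    rel = coords - coords[0]  # exact zero deviations for a static input
    dev = rel - rel.mean(axis=0)
    return np.sqrt((dev ** 2).sum(axis=2).mean(axis=0))


def rmsf(ensemble: TrajectoryEnsemble, model: FibrilModel,
         superpose: bool = True, reference: np.ndarray | None = None,
         contact_layers=(), selection: np.ndarray | None = None) -> RmsfTable:
    """Per-residue RMSF with SEM across trajectories.

    The ensemble must carry fibril (protein) coordinates over the model's
    topology. Per-atom RMSF is the root time-mean squared deviation from
    the time-mean position, after optional least-squares superposition of
    the non-edge-layer backbone onto the reference (default: first frame
    of each trajectory). The per-residue value averages the residue's
    backbone heavy atoms. Strand classes: layers in ``contact_layers``
    are "contact", other non-edge layers "non_contact"; the two edge
    layers are labelled "edge" and excluded from class averages.
    """
    n_atoms = len(ensemble.atom_names)
    if n_atoms != model.n_atoms:
        raise ValueError("ensemble topology does not match the model")
    if selection is None:
        selection = np.ones(n_atoms, dtype=bool)

    edge = model.edge_layers()
    fit_mask = (np.isin(model.atom_names, BACKBONE_HEAVY)
                & ~np.isin(model.layer_index, sorted(edge)))
    if not fit_mask.any():
        fit_mask = np.isin(model.atom_names, BACKBONE_HEAVY)

    per_traj_atom = []
    for traj in ensemble.trajectories:
        coords = traj.coords
        if traj.n_frames == 1:
            warnings.warn("single-frame trajectory: RMSF is zero",
                          stacklevel=2)
            per_traj_atom.append(np.zeros(n_atoms))
            continue
        if superpose:
            ref = coords[0] if reference is None else np.asarray(reference)
            fitted = np.empty_like(coords)
            for f in range(coords.shape[0]):
                R, t = _kabsch(coords[f][fit_mask], ref[fit_mask])
                fitted[f] = coords[f] @ R.T + t
            coords = fitted
        per_traj_atom.append(per_atom_rmsf(coords))
    atom_rmsf = np.vstack(per_traj_atom)      # (n_traj, n_atoms)

    keys, rows = [], []
    for key, idx in model.residue_atom_indices().items():
        bb = idx[np.isin(model.atom_names[idx], BACKBONE_HEAVY)
                 & selection[idx]]
        if bb.size == 0:
            continue
        vals = atom_rmsf[:, bb].mean(axis=1)  # per trajectory
        keys.append(key)
        rows.append(vals)
    arr = np.array(rows)                      # (n_residues, n_traj)
    layer_of = model.layer_of_residue()
    layers = np.array([layer_of[k] for k in keys])
    contact = set(contact_layers)
    cls = np.array(["edge" if l in edge else
                    "contact" if l in contact else "non_contact"
                    for l in layers], dtype=object)
    n_traj = arr.shape[1]
    sem = (arr.std(axis=1, ddof=1) / np.sqrt(n_traj) if n_traj > 1
           else np.full(len(keys), np.nan))
    return RmsfTable(
        chain_ids=np.array([k[0] for k in keys], dtype=object),
        resids=np.array([k[1] for k in keys]),
        layer=layers,
        rmsf=arr.mean(axis=1),
        sem=sem,
        strand_class=cls)
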