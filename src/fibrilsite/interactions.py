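"""Contact detection and polar-bond (hydrogen / halogen) criteria.

Contact rules follow the two geometric definitions used for
fibril-ligand contact mapping: a generic heavy-atom contact at 0.4 nm,
and a 0.5 nm rule between the ligand pyrazole 1,2-nitrogen atoms and
protein backbone carbon/nitrogen atoms (matching the NMR isotope
labelling). A halogen bond requires Br...O(carbonyl) <= 0.36 nm and a
C-Br...O angle >= 150 deg (180 deg = linear). Hydrogen-bond presence is
geometric (donor-acceptor distance and D-H...A angle); hydrogen-bond
energies are reported through a pluggable empirical model.

Analyses assume whole (unwrapped) molecules; no minimum-image handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model_io import FibrilModel, LigandTopology, TrajectoryEnsemble


@dataclass
class ContactCriteria:
    heavy_cutoff: float = 0.40              # nm, any heavy atom pair
    nitrogen_backbone_cutoff: float = 0.50  # nm, pyrazole N vs backbone C/N
    exclude_edge_layers: bool = True
    include_ca: bool = True                 # CA counts as backbone carbon

    def __post_init__(self):
        if self.heavy_cutoff <= 0 or self.nitrogen_backbone_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


def default_hb_energy(distance: float, angle: float) -> float:
    """Smooth empirical hydrogen-bond energy surrogate (kJ/mol).

    Non-canonical: a bounded exponential-distance, cosine-squared-angle
    form, E = -V0 cos^2(180 - theta) exp(-(r - r0)/rho) clamped at -V0,
    with V0 = 20 kJ/mol, r0 = 0.28 nm, rho = 0.06 nm. Only the sign and
    rough magnitude are meaningful; binding-mode classification uses the
    geometric criteria alone, never this energy.
    """
    dev = np.deg2rad(180.0 - angle)
    radial = min(np.exp(-(distance - 0.28) / 0.06), 1.0)
    return float(-20.0 * np.cos(dev) ** 2 * radial)


@dataclass
class PolarBondCriteria:
    hb_donor_acceptor_cutoff: float = 0.35  # nm, heavy donor-acceptor
    hb_angle_min: float = 150.0             # deg, D-H...A
    xb_distance_cutoff: float = 0.36        # nm, Br...O(carbonyl)
    xb_angle_min: float = 150.0             # deg, C-Br...O at Br
    hb_energy_model: Callable[[float, float], float] = field(
        default=default_hb_energy)

    def __post_init__(self):
        for a in (self.hb_angle_min, self.xb_angle_min):
            if not (0 < a <= 180):
                raise ValueError("angle thresholds must lie in (0, 180]")
        if self.hb_donor_acceptor_cutoff <= 0 or self.xb_distance_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


# ---------------------------------------------------------------------------
# Elementary contact predicates
# ---------------------------------------------------------------------------

def heavy_atom_contact(ligand_coords: np.ndarray, ligand_elements,
                       residue_coords: np.ndarray, residue_elements,
                       cutoff: float = 0.40) -> tuple[bool, int]:
    """Heavy-atom contact between a ligand and one residue.

    Returns ``(in_contact, n_ligand_heavy_in_contact)`` where the count
    is the number of ligand heavy atoms within ``cutoff`` of any heavy
    atom of the residue (consumed by binding-mode classification).
    """
    lig_heavy = np.array([str(e).upper() != "H" for e in ligand_elements])
    res_heavy = np.array([str(e).upper() != "H" for e in residue_elements])
    lp = np.asarray(ligand_coords, dtype=float)[lig_heavy]
    rp = np.asarray(residue_coords, dtype=float)[res_heavy]
    if lp.size == 0 or rp.size == 0:
        raise ValueError("empty heavy-atom set")
    tree = cKDTree(rp)
    d, _ = tree.query(lp, k=1)
    n = int(np.sum(d <= cutoff))
    return n > 0, n


def nitrogen_backbone_contact(ligand_coords: np.ndarray,
                              ligand: LigandTopology,
                              residue_coords: np.ndarray,
                              residue_atom_names,
                              cutoff: float = 0.50,
                              include_ca: bool = True) -> bool:
    """1,2-N rule: either pyrazole nitrogen within ``cutoff`` of any
    backbone carbon or nitrogen atom (N, C and optionally CA) of the
    residue."""
    n_idx = ligand.group_indices("pyrazole_N")
    backbone = {"N", "C"} | ({"CA"} if include_ca else set())
    names = np.asarray(residue_atom_names)
    bb = np.isin(names, sorted(backbone))
    if not bb.any():
        return False
    rp = np.asarray(residue_coords, dtype=float)[bb]
    lp = np.asarray(ligand_coords, dtype=float)[n_idx]
    d = np.linalg.norm(lp[:, None, :] - rp[None, :, :], axis=2)
    return bool((d <= cutoff).any())


# ---------------------------------------------------------------------------
# Hydrogen and halogen bonds
# ---------------------------------------------------------------------------

@dataclass
class HydrogenBond:
    donor: str
    hydrogen: str
    acceptor: str
    distance: float                 # nm, donor-acceptor
    angle: float                    # deg, D-H...A
    energy: float                   # kJ/mol (empirical model)
    ligand_group: str | None = None  # "pyrazole" | "benzodioxole"
    residue: tuple[str, int] | None = None
    protein_atom: str | None = None


@dataclass
class HalogenBond:
    halogen: str
    oxygen: str
    distance: float                 # nm, X...O
    angle: float                    # deg, C-X...O at the halogen
    residue: tuple[str, int] | None = None


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hydrogen_bonds(donors, acceptors,
                          criteria: PolarBondCriteria | None = None,
                          ) -> list[HydrogenBond]:
    """Geometric hydrogen-bond detection.

    ``donors``: iterable of (donor_xyz, hydrogen_xyz, donor_name) with
    hydrogen_xyz required (a donor without a hydrogen is an error);
    ``acceptors``: iterable of (acceptor_xyz, acceptor_name). A bond is
    formed iff the donor-acceptor distance is at most the cutoff and the
    D-H...A angle (at the hydrogen) is at least the minimum angle.
    """
    criteria = criteria or PolarBondCriteria()
    bonds = []
    for d_xyz, h_xyz, d_name in donors:
        if h_xyz is None:
            raise ValueError(f"donor {d_name!r} has no attached hydrogen")
        d_xyz = np.asarray(d_xyz, dtype=float)
        h_xyz = np.asarray(h_xyz, dtype=float)
        for a_xyz, a_name in acceptors:
            a_xyz = np.asarray(a_xyz, dtype=float)
            dist = float(np.linalg.norm(d_xyz - a_xyz))
            if dist > criteria.hb_donor_acceptor_cutoff:
                continue
            ang = _angle_deg(d_xyz, h_xyz, a_xyz)
            if ang < criteria.hb_angle_min:
                continue
            bonds.append(HydrogenBond(
                donor=d_name, hydrogen=f"H({d_name})", acceptor=a_name,
                distance=dist, angle=ang,
                energy=criteria.hb_energy_model(dist, ang)))
    return bonds


def detect_halogen_bonds(halogen_xyz, carbon_xyz, oxygens,
                         criteria: PolarBondCriteria | None = None,
                         halogen_name: str = "BR") -> list[HalogenBond]:
    """Halogen bonds of one halogen against candidate carbonyl oxygens.

    ``oxygens``: iterable of (xyz, name). XB formed iff X...O distance
    <= cutoff and the C-X...O angle at the halogen >= the minimum
    (180 deg = linear).
    """
    criteria = criteria or PolarBondCriteria()
    x = np.asarray(halogen_xyz, dtype=float)
    c = np.asarray(carbon_xyz, dtype=float)
    bonds = []
    for o_xyz, o_name in oxygens:
        o = np.asarray(o_xyz, dtype=float)
        dist = float(np.linalg.norm(x - o))
        if dist > criteria.xb_distance_cutoff:
            continue
        ang = _angle_deg(c, x, o)
        if ang < criteria.xb_angle_min:
            continue
        bonds.append(HalogenBond(halogen=halogen_name, oxygen=o_name,
                                 distance=dist, angle=ang))
    return bonds


# ---------------------------------------------------------------------------
# Ligand-protein enumeration on a frame
# ---------------------------------------------------------------------------

def _protein_polar_sites(model: FibrilModel, residues=None,
                         include_sidechains: bool = True):
    """Backbone N-H donors, carbonyl O acceptors and sidechain O/N of the
    model, grouped per residue key."""
    donors, acceptors, carbonyls = [], [], []
    res_idx = model.residue_atom_indices()
    for key, idx in res_idx.items():
        if residues is not None and key not in residues:
            continue
        names = model.atom_names[idx]
        pos = {nm: model.coords[i] for i, nm in zip(idx, names)}
        if "N" in pos and "H" in pos:
            donors.append((key, "N", pos["N"], pos["H"]))
        if "O" in pos:
            acceptors.append((key, "O", pos["O"]))
            carbonyls.append((key, "O", pos["O"]))
        if include_sidechains:
            for i, nm in zip(idx, names):
                if nm in ("N", "O", "H", "C", "CA"):
                    continue
                el = str(model.elements[i]).upper()
                if el in ("O", "N"):
                    acceptors.append((key, nm, model.coords[i]))
    return donors, acceptors, carbonyls


def _ligand_group_of(ligand: LigandTopology, atom: str) -> str | None:
    if atom in ligand.groups["pyrazole_N"] or atom in ligand.groups["pyrazole_ring"]:
        return "pyrazole"
    if atom in ligand.groups["benzodioxole_O"] \
            or atom in ligand.groups["benzodioxole_ring"]:
        return "benzodioxole"
    return None


def ligand_protein_hbonds(lig_coords: np.ndarray, ligand: LigandTopology,
                          model: FibrilModel,
                          criteria: PolarBondCriteria | None = None,
                          residues=None,
                          include_sidechains: bool = True,
                          ) -> list[HydrogenBond]:
    """All ligand-protein hydrogen bonds in one ligand frame.

    Ligand donors are the declared donor hydrogens (pyrazole N-H);
    ligand acceptors are the pyrazole nitrogens and benzodioxole
    oxygens. Protein donors/acceptors are backbone N-H and C=O plus,
    optionally, sidechain O/N acceptors.
    """
    criteria = criteria or PolarBondCriteria()
    lig_coords = np.asarray(lig_coords, dtype=float)
    p_donors, p_acceptors, _ = _protein_polar_sites(
        model, residues, include_sidechains)
    bonds: list[HydrogenBond] = []

    # ligand donor -> protein acceptor
    for d_name, h_name in ligand.donor_hydrogens.items():
        d = lig_coords[ligand.index_of(d_name)]
        h = lig_coords[ligand.index_of(h_name)]
        for key, a_name, a_xyz in p_acceptors:
            found = detect_hydrogen_bonds([(d, h, d_name)],
                                          [(a_xyz, a_name)], criteria)
            for b in found:
                b.ligand_group = _ligand_group_of(ligand, d_name)
                b.residue, b.protein_atom = key, a_name
                bonds.append(b)

    # protein donor -> ligand acceptor
    lig_acceptors = [(a, lig_coords[ligand.index_of(a)])
                     for a in (*ligand.groups["pyrazole_N"],
                               *ligand.groups["benzodioxole_O"])]
    for key, d_name, d_xyz, h_xyz in p_donors:
        for a_name, a_xyz in lig_acceptors:
            found = detect_hydrogen_bonds([(d_xyz, h_xyz, d_name)],
                                          [(a_xyz, a_name)], criteria)
            for b in found:
                b.ligand_group = _ligand_group_of(ligand, a_name)
                b.residue, b.protein_atom = key, d_name
                bonds.append(b)
    return bonds


def ligand_protein_xbonds(lig_coords: np.ndarray, ligand: LigandTopology,
                          model: FibrilModel,
                          criteria: PolarBondCriteria | None = None,
                          residues=None) -> list[HalogenBond]:
    """All ligand-protein halogen bonds (Br vs carbonyl O) in one frame."""
    criteria = criteria or PolarBondCriteria()
    lig_coords = np.asarray(lig_coords, dtype=float)
    _, _, carbonyls = _protein_polar_sites(model, residues, False)
    hal = ligand.groups["halogen"][0]
    carbon = ligand.groups["halogen_bonded_carbon"][0]
    x = lig_coords[ligand.index_of(hal)]
    c = lig_coords[ligand.index_of(carbon)]
    bonds = []
    for key, o_name, o_xyz in carbonyls:
        found = detect_halogen_bonds(x, c, [(o_xyz, o_name)], criteria,
                                     halogen_name=hal)
        for b in found:
            b.residue = key
            bonds.append(b)
    return bonds


# ---------------------------------------------------------------------------
# Contact probabilities over an ensemble
# ---------------------------------------------------------------------------

def _considered_residues(model: FibrilModel, exclude_edge: bool):
    layer_of = model.layer_of_residue()
    edge = model.edge_layers() if exclude_edge else set()
    return [k for k, l in layer_of.items() if l not in edge]


def contact_probabilities(ensemble: TrajectoryEnsemble,
                          model: FibrilModel, ligand: LigandTopology,
                          criteria: ContactCriteria | None = None,
                          definition: str = "heavy",
                          bond_criteria: PolarBondCriteria | None = None,
                          ) -> pd.DataFrame:
    """Per-residue contact probabilities averaged over time, then over
    the individual trajectories.

    ``definition`` selects the contact rule: ``heavy`` (0.4 nm
    heavy-atom), ``nitrogen_backbone`` (0.5 nm pyrazole-N vs backbone
    C/N), ``hb`` (>=1 hydrogen bond to the residue) or ``xb`` (>=1
    halogen bond). Edge layers are excluded when the criteria say so.
    For polar definitions the map also resolves the backbone atom kind
    (amide N vs carbonyl O) of the protein partner.

    Returns a DataFrame with columns chain, residue, layer, atom_kind,
    probability, sem, n_frames.
    """
    criteria = criteria or ContactCriteria()
    bond_criteria = bond_criteria or PolarBondCriteria()
    if definition not in ("heavy", "nitrogen_backbone", "hb", "xb"):
        raise ValueError(f"unknown contact definition {definition!r}")
    residues = _considered_residues(model, criteria.exclude_edge_layers)
    res_idx = model.residue_atom_indices()
    layer_of = model.layer_of_residue()
    kinds = {"heavy": ("any",), "nitrogen_backbone": ("any",),
             "hb": ("any", "amide_N", "carbonyl_O"),
             "xb": ("any", "carbonyl_O")}[definition]
    kpos = {k: j for j, k in enumerate(kinds)}

    lig_heavy = ligand.heavy_mask
    n_idx = ligand.group_indices("pyrazole_N")
    backbone_cn = {"N", "C"} | ({"CA"} if criteria.include_ca else set())

    per_traj = []
    total_frames = 0
    for traj in ensemble.trajectories:
        if traj.n_frames == 0:
            raise ValueError("empty trajectory after trimming")
        total_frames += traj.n_frames
        hits = np.zeros((len(residues), len(kinds)))
        for frame in traj.coords:
            if definition == "heavy":
                lp = frame[lig_heavy]
                tree = cKDTree(lp)
                for ri, key in enumerate(residues):
                    idx = res_idx[key]
                    heavy = idx[model.heavy_mask[idx]]
                    if tree.query_ball_point(
                            model.coords[heavy],
                            criteria.heavy_cutoff,
                            return_length=True).sum() > 0:
                        hits[ri, 0] += 1
            elif definition == "nitrogen_backbone":
                lp = frame[n_idx]
                tree = cKDTree(lp)
                for ri, key in enumerate(residues):
                    idx = res_idx[key]
                    bb = idx[np.isin(model.atom_names[idx],
                                     sorted(backbone_cn))]
                    if bb.size and tree.query_ball_point(
                            model.coords[bb],
                            criteria.nitrogen_backbone_cutoff,
                            return_length=True).sum() > 0:
                        hits[ri, 0] += 1
            elif definition == "hb":
                bonds = ligand_protein_hbonds(frame, ligand, model,
                                              bond_criteria, set(residues))
                seen: dict[tuple, set] = {}
                for b in bonds:
                    kind = "amide_N" if b.protein_atom == "N" else \
                        "carbonyl_O" if b.protein_atom == "O" else None
                    s = seen.setdefault(b.residue, set())
                    s.add("any")
                    if kind:
                        s.add(kind)
                for ri, key in enumerate(residues):
                    for k in seen.get(key, ()):
                        hits[ri, kpos[k]] += 1
            else:  # xb
                bonds = ligand_protein_xbonds(frame, ligand, model,
                                              bond_criteria, set(residues))
                seen = {}
                for b in bonds:
                    seen.setdefault(b.residue, set()).update(
                        ("any", "carbonyl_O"))
                for ri, key in enumerate(residues):
                    for k in seen.get(key, ()):
                        hits[ri, kpos[k]] += 1
        per_traj.append(hits / traj.n_frames)

    stack = np.stack(per_traj)  # (n_traj, n_res, n_kinds)
    prob = stack.mean(axis=0)
    sem = (stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
           if stack.shape[0] > 1 else np.full_like(prob, np.nan))
    rows = []
    for ri, key in enumerate(residues):
        for k in kinds:
            rows.append({
                "chain": key[0], "residue": key[1],
                "layer": layer_of[key], "atom_kind": k,
                "probability": prob[ri, kpos[k]],
                "sem": sem[ri, kpos[k]],
                "n_frames": total_frames})
    return pd.DataFrame(rows)
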