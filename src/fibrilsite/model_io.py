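"""Structures, trajectories, ligand topologies and NMR peak tables.

Internal length unit is the nanometre throughout the package (all
geometric criteria of the analyses are stated in nm); PDB and XYZ I/O
convert from/to Angstrom at the boundary. Residue numbering is taken
verbatim from input files and never rewritten.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import MDAnalysis as mda

A_PER_NM = 10.0

#: standard atomic masses (u) for the elements that occur in fibril/ligand work
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "BR": 79.904, "CL": 35.45, "F": 18.998, "I": 126.904,
    "SE": 78.971,
}

VALID_NUCLEI = ("HN", "N", "CA", "CB")


def element_from_name(name: str) -> str:
    """Infer the element symbol from an atom name (PDB conventions).

    Two-letter halogens/metals are recognised by prefix; otherwise the
    first alphabetic character is the element.
    """
    stripped = name.strip().lstrip("0123456789").upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    for two in ("BR", "CL", "SE"):
        if stripped.startswith(two):
            return two
    return stripped[0]


def mass_of(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {element!r}")


# ---------------------------------------------------------------------------
# FibrilModel
# ---------------------------------------------------------------------------

@dataclass
class FibrilModel:
    """A stacked-layer protofilament model.

    Atom arrays are parallel; coordinates are in nm. ``layer_index`` is
    per-atom and ``-1`` until :func:`assign_layers` has run. A residue is
    identified by its (chain_id, residue_number) pair; every residue
    belongs to exactly one layer.
    """

    atom_names: np.ndarray          # (n,) str
    elements: np.ndarray            # (n,) str
    resids: np.ndarray              # (n,) int
    chain_ids: np.ndarray           # (n,) str
    coords: np.ndarray              # (n, 3) float, nm
    layer_index: np.ndarray = None  # (n,) int, -1 = unassigned
    resnames: np.ndarray = None     # (n,) str

    def __post_init__(self):
        n = len(self.atom_names)
        if self.layer_index is None:
            self.layer_index = np.full(n, -1, dtype=int)
        if self.resnames is None:
            self.resnames = np.full(n, "UNK", dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValueError("coordinate array must be (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in model")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def heavy_mask(self) -> np.ndarray:
        """Heavy atoms selected by element, not by name."""
        return np.array([e.upper() != "H" for e in self.elements])

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])

    @property
    def layer_count(self) -> int:
        assigned = self.layer_index[self.layer_index >= 0]
        return 0 if assigned.size == 0 else int(assigned.max()) + 1

    @property
    def residue_range(self) -> tuple[int, int]:
        return int(self.resids.min()), int(self.resids.max())

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain, resid) pairs in order of first appearance."""
        seen, keys = set(), []
        for c, r in zip(self.chain_ids, self.resids):
            k = (c, int(r))
            if k not in seen:
                seen.add(k)
                keys.append(k)
        return keys

    def residue_atom_indices(self) -> dict[tuple[str, int], np.ndarray]:
        out: dict[tuple[str, int], list[int]] = {}
        for i, (c, r) in enumerate(zip(self.chain_ids, self.resids)):
            out.setdefault((c, int(r)), []).append(i)
        return {k: np.array(v) for k, v in out.items()}

    def layer_of_residue(self) -> dict[tuple[str, int], int]:
        out = {}
        for key, idx in self.residue_atom_indices().items():
            layers = set(self.layer_index[idx].tolist())
            if len(layers) != 1:
                raise ValueError(f"residue {key} spans layers {sorted(layers)}")
            out[key] = layers.pop()
        return out

    def layer_atom_indices(self, layer: int) -> np.ndarray:
        idx = np.where(self.layer_index == layer)[0]
        if idx.size == 0:
            raise ValueError(f"layer {layer} has no atoms "
                             f"(layer_count={self.layer_count})")
        return idx

    def layer_centroid(self, layer: int, mass_weighted: bool = True) -> np.ndarray:
        idx = self.layer_atom_indices(layer)
        if mass_weighted:
            w = self.masses[idx]
            return np.average(self.coords[idx], axis=0, weights=w)
        return self.coords[idx].mean(axis=0)

    def edge_layers(self) -> set[int]:
        lc = self.layer_count
        return {0, lc - 1} if lc >= 2 else set(range(lc))


# ---------------------------------------------------------------------------
# LigandTopology
# ---------------------------------------------------------------------------

REQUIRED_GROUPS = (
    "pyrazole_ring", "pyrazole_N", "benzodioxole_ring", "benzodioxole_O",
    "bromophenyl_ring", "halogen", "halogen_bonded_carbon",
)


@dataclass
class LigandTopology:
    """Named atom groups of the ligand.

    ``donor_hydrogens`` maps a donor heavy atom to its covalent hydrogen
    (the pyrazole N-H for anle138b). ``reference_coords`` is an optional
    rigid geometry (nm) used by the synthetic trajectory generator.
    """

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    groups: dict[str, tuple[str, ...]]
    donor_hydrogens: dict[str, str] = field(default_factory=dict)
    reference_coords: np.ndarray | None = None

    def __post_init__(self):
        names = set(self.atom_names)
        if len(names) != len(self.atom_names):
            raise ValueError("duplicate atom names in ligand topology")
        for g in REQUIRED_GROUPS:
            if g not in self.groups:
                raise ValueError(f"ligand topology missing group {g!r}")
        for g, members in self.groups.items():
            missing = [m for m in members if m not in names]
            if missing:
                raise ValueError(f"group {g!r} references unknown atoms {missing}")
        if len(self.groups["pyrazole_N"]) != 2:
            raise ValueError("pyrazole_N group must contain exactly 2 atoms")
        if len(self.groups["halogen"]) != 1:
            raise ValueError("halogen group must contain exactly 1 atom")
        if len(self.groups["halogen_bonded_carbon"]) != 1:
            raise ValueError("halogen_bonded_carbon group must contain exactly 1 atom")
        hal = self.groups["halogen"][0]
        for ring in ("pyrazole_ring", "benzodioxole_ring", "bromophenyl_ring"):
            if hal in self.groups[ring]:
                raise ValueError(f"halogen atom {hal!r} must not be part of {ring}")
        for d, h in self.donor_hydrogens.items():
            if d not in names or h not in names:
                raise ValueError(f"donor pair ({d}, {h}) references unknown atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e.upper() != "H" for e in self.elements])

    @property
    def n_heavy(self) -> int:
        return int(self.heavy_mask.sum())

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])

    def index_of(self, name: str) -> int:
        return self.atom_names.index(name)

    def group_indices(self, group: str) -> np.ndarray:
        return np.array([self.index_of(a) for a in self.groups[group]])


def _ring(center: np.ndarray, radius: float, n: int, phase: float) -> np.ndarray:
    ang = phase + 2 * np.pi * np.arange(n) / n
    return center + radius * np.column_stack(
        [np.cos(ang), np.sin(ang), np.zeros(n)])


def anle138b_topology() -> LigandTopology:
    """Topology of anle138b, 3-(1,3-benzodioxol-5-yl)-5-(3-bromophenyl)-1H-pyrazole.

    21 heavy atoms (16 C, 2 N, 2 O, 1 Br) plus the pyrazole N-H hydrogen.
    The attached reference geometry is a synthetic, planar, roughly
    bond-length-scaled layout used only as a rigid body by the trajectory
    generator; it is not a chemically optimised conformer.
    """
    atoms: list[tuple[str, str, np.ndarray]] = []

    # pyrazole: N1-N2=C3-C4=C5, C3 carries benzodioxole, C5 bromophenyl
    pyr_names = ("N1", "N2", "C3", "C4", "C5")
    pyr = _ring(np.zeros(3), 0.115, 5, np.pi / 2)
    for nm, xyz in zip(pyr_names, pyr):
        atoms.append((nm, element_from_name(nm), xyz))
    n1 = pyr[0]
    atoms.append(("HN1", "H", n1 + 0.101 * n1 / np.linalg.norm(n1)))

    def fused_hexagon(attach: np.ndarray, prefix: str) -> list[np.ndarray]:
        u = attach / np.linalg.norm(attach)
        center = attach + 0.25 * u
        phase = np.arctan2(-u[1], -u[0])  # first vertex faces the pyrazole
        return [center, *_ring(center, 0.14, 6, phase)]

    # benzodioxole off C3: 6 aromatic C, two O and the methylenedioxy C
    bz_center, *bz = fused_hexagon(pyr[2], "B")
    bz_names = ("C1B", "C2B", "C3B", "C4B", "C5B", "C6B")
    for nm, xyz in zip(bz_names, bz):
        atoms.append((nm, "C", xyz))
    u34 = [(p - bz_center) / np.linalg.norm(p - bz_center) for p in (bz[3], bz[4])]
    o1 = bz[3] + 0.135 * u34[0]
    o2 = bz[4] + 0.135 * u34[1]
    atoms.append(("O1", "O", o1))
    atoms.append(("O2", "O", o2))
    mid = 0.5 * (o1 + o2)
    out = (mid - bz_center) / np.linalg.norm(mid - bz_center)
    atoms.append(("C7B", "C", mid + 0.11 * out))

    # bromophenyl off C5; Br on the meta carbon
    ph_center, *ph = fused_hexagon(pyr[4], "P")
    ph_names = ("C1P", "C2P", "C3P", "C4P", "C5P", "C6P")
    for nm, xyz in zip(ph_names, ph):
        atoms.append((nm, "C", xyz))
    u_br = (ph[2] - ph_center) / np.linalg.norm(ph[2] - ph_center)
    atoms.append(("BR", "BR", ph[2] + 0.19 * u_br))

    names = tuple(a[0] for a in atoms)
    elements = tuple(a[1] for a in atoms)
    coords = np.array([a[2] for a in atoms])
    groups = {
        "pyrazole_ring": pyr_names,
        "pyrazole_N": ("N1", "N2"),
        "benzodioxole_ring": bz_names + ("O1", "O2", "C7B"),
        "benzodioxole_O": ("O1", "O2"),
        "bromophenyl_ring": ph_names,
        "halogen": ("BR",),
        "halogen_bonded_carbon": ("C3P",),
    }
    return LigandTopology(names, elements, groups,
                          donor_hydrogens={"N1": "HN1"},
                          reference_coords=coords)


# ---------------------------------------------------------------------------
# TrajectoryEnsemble
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """One time-stamped coordinate series (times in ns, coords in nm)."""

    times: np.ndarray               # (n_frames,) ns
    coords: np.ndarray              # (n_frames, n_atoms, 3) nm

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != self.times.size:
            raise ValueError("coords must be (n_frames, n_atoms, 3) matching times")
        if self.times.size < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass
class TrajectoryEnsemble:
    """Independent trajectories over one shared topology."""

    atom_names: tuple[str, ...]
    elements: tuple[str, ...]
    trajectories: list[Trajectory]
    frame_interval: float = 0.1     # ns; snapshots every 100 ps by default

    def __post_init__(self):
        n = len(self.atom_names)
        for i, t in enumerate(self.trajectories):
            if t.coords.shape[1] != n:
                raise ValueError(
                    f"trajectory {i} has {t.coords.shape[1]} atoms, topology has {n}")

    @property
    def n_trajectories(self) -> int:
        return len(self.trajectories)

    @property
    def masses(self) -> np.ndarray:
        return np.array([mass_of(e) for e in self.elements])


# ---------------------------------------------------------------------------
# PeakTable
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """Per-residue, per-nucleus chemical shifts and intensities.

    Backed by a DataFrame with columns
    ``residue, nucleus, shift_ppm, intensity``. At most one row per
    (residue, nucleus); intensities non-negative; nuclei restricted to
    HN, N, CA, CB.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = ["residue", "nucleus", "shift_ppm", "intensity"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"peak table missing columns {missing}")
        df = self.data[required].copy()
        df["residue"] = df["residue"].astype(int)
        df["nucleus"] = df["nucleus"].astype(str)
        bad = sorted(set(df["nucleus"]) - set(VALID_NUCLEI))
        if bad:
            raise ValueError(f"unknown nucleus values {bad}; expected {VALID_NUCLEI}")
        if (df["intensity"] < 0).any():
            raise ValueError("negative intensity in peak table")
        dup = df.duplicated(subset=["residue", "nucleus"])
        if dup.any():
            pairs = df.loc[dup, ["residue", "nucleus"]].values.tolist()
            raise ValueError(f"duplicate (residue, nucleus) rows: {pairs}")
        self.data = df.sort_values(["residue", "nucleus"]).reset_index(drop=True)

    @property
    def residues(self) -> np.ndarray:
        return np.unique(self.data["residue"].to_numpy())

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# Structure and trajectory I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _universe_elements(u: "mda.Universe") -> np.ndarray:
    if hasattr(u.atoms, "elements"):
        els = [e if e else element_from_name(n)
               for e, n in zip(u.atoms.elements, u.atoms.names)]
    else:
        els = [element_from_name(n) for n in u.atoms.names]
    return np.array([e.upper() for e in els], dtype=object)


def _universe_chains(u: "mda.Universe") -> np.ndarray:
    if hasattr(u.atoms, "chainIDs"):
        ch = [c if c.strip() else "A" for c in u.atoms.chainIDs]
    elif hasattr(u.atoms, "segids"):
        ch = [c if str(c).strip() else "A" for c in u.atoms.segids]
    else:
        ch = ["A"] * u.atoms.n_atoms
    return np.array(ch, dtype=object)


def read_structure(pdb_source: str | os.PathLike) -> FibrilModel:
    """Read a PDB file into a :class:`FibrilModel` (coordinates in nm).

    Layer indices are left unassigned; call :func:`assign_layers` next.
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(pdb_source))
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise ValueError(f"failed to parse PDB {pdb_source!r}: {exc}") from exc
    if u.atoms.n_atoms == 0:
        raise ValueError(f"no atoms in {pdb_source!r}")
    return FibrilModel(
        atom_names=np.array(u.atoms.names, dtype=object),
        elements=_universe_elements(u),
        resids=np.array(u.atoms.resids, dtype=int),
        chain_ids=_universe_chains(u),
        coords=u.atoms.positions.astype(float) / A_PER_NM,
        resnames=np.array(u.atoms.resnames, dtype=object)
        if hasattr(u.atoms, "resnames") else None,
    )


def _model_to_universe(model: FibrilModel) -> "mda.Universe":
    keys = model.residue_keys()
    key_index = {k: i for i, k in enumerate(keys)}
    atom_resindex = np.array(
        [key_index[(c, int(r))] for c, r in zip(model.chain_ids, model.resids)])
    chains = sorted({k[0] for k in keys})
    seg_index = {c: i for i, c in enumerate(chains)}
    residue_segindex = np.array([seg_index[k[0]] for k in keys])
    u = mda.Universe.empty(
        n_atoms=model.n_atoms, n_residues=len(keys), n_segments=len(chains),
        atom_resindex=atom_resindex, residue_segindex=residue_segindex,
        trajectory=True)
    u.add_TopologyAttr("names", list(model.atom_names))
    u.add_TopologyAttr("elements", [str(e) for e in model.elements])
    u.add_TopologyAttr("resids", [k[1] for k in keys])
    u.add_TopologyAttr("resnames", [
        str(model.resnames[model.residue_atom_indices()[k][0]]) for k in keys])
    u.add_TopologyAttr("segids", chains)
    u.add_TopologyAttr("chainIDs", [str(c) for c in model.chain_ids])
    u.atoms.positions = model.coords * A_PER_NM
    return u


def write_structure(model: FibrilModel, path: str | os.PathLike) -> None:
    """Write a model as PDB (nm converted to Angstrom)."""
    u = _model_to_universe(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def read_trajectory(sources, topology: LigandTopology | None = None,
                    frame_interval: float = 0.1,
                    atom_names: tuple[str, ...] | None = None,
                    elements: tuple[str, ...] | None = None,
                    ) -> TrajectoryEnsemble:
    """Read one or more multi-model PDB / multi-frame XYZ files.

    Frame times are ``i * frame_interval`` (ns) unless the format stores
    them. When a :class:`LigandTopology` is given, atom counts and names
    are validated against it.
    """
    if isinstance(sources, (str, os.PathLike)):
        sources = [sources]
    trajectories = []
    ref_names: tuple[str, ...] | None = (
        tuple(topology.atom_names) if topology is not None else atom_names)
    ref_elements = tuple(topology.elements) if topology is not None else elements
    for src in sources:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u = mda.Universe(str(src))
        except Exception as exc:  # noqa: BLE001
            raise ValueError(f"failed to parse trajectory {src!r}: {exc}") from exc
        if u.atoms.n_atoms == 0:
            raise ValueError(f"no atoms in {src!r}")
        names = tuple(str(n) for n in u.atoms.names)
        if ref_names is not None and len(names) != len(ref_names):
            raise ValueError(
                f"{src!r}: {len(names)} atoms per frame, expected {len(ref_names)}")
        if ref_names is None:
            ref_names = names
        if ref_elements is None:
            ref_elements = tuple(str(e) for e in _universe_elements(u))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory])
        trajectories.append(Trajectory(
            times=np.arange(frames.shape[0]) * frame_interval,
            coords=frames.astype(float) / A_PER_NM))
    return TrajectoryEnsemble(ref_names, ref_elements, trajectories,
                              frame_interval=frame_interval)


def write_trajectory(ensemble: TrajectoryEnsemble, paths) -> None:
    """Write each trajectory of the ensemble to its own file (PDB or XYZ)."""
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    if len(paths) != ensemble.n_trajectories:
        raise ValueError("need one output path per trajectory")
    n = len(ensemble.atom_names)
    for traj, path in zip(ensemble.trajectories, paths):
        u = mda.Universe.empty(n_atoms=n, trajectory=True)
        u.add_TopologyAttr("names", list(ensemble.atom_names))
        u.add_TopologyAttr("elements", [str(e).capitalize()
                                        for e in ensemble.elements])
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("resnames", ["LIG"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with mda.Writer(str(path), n_atoms=n, multiframe=True) as w:
                for frame in traj.coords:
                    u.atoms.positions = frame * A_PER_NM
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# Peak table and ligand topology I/O
# ---------------------------------------------------------------------------

def read_peak_table(csv_source) -> PeakTable:
    """Read a peak table CSV with header residue,nucleus,shift_ppm,intensity."""
    df = pd.read_csv(csv_source)
    return PeakTable(df)


def write_peak_table(table: PeakTable, path: str | os.PathLike | io.IOBase) -> None:
    table.data.to_csv(path, index=False)


def write_ligand_topology(top: LigandTopology, path: str | os.PathLike) -> None:
    doc = {
        "atoms": [{"name": n, "element": e}
                  for n, e in zip(top.atom_names, top.elements)],
        "groups": {g: list(m) for g, m in top.groups.items()},
        "donor_hydrogens": dict(top.donor_hydrogens),
    }
    if top.reference_coords is not None:
        doc["reference_coords_nm"] = [
            [round(float(v), 6) for v in xyz] for xyz in top.reference_coords]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_ligand_topology(path: str | os.PathLike) -> LigandTopology:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    names = tuple(a["name"] for a in doc["atoms"])
    elements = tuple(a["element"] for a in doc["atoms"])
    groups = {g: tuple(m) for g, m in doc["groups"].items()}
    ref = doc.get("reference_coords_nm")
    return LigandTopology(
        names, elements, groups,
        donor_hydrogens=dict(doc.get("donor_hydrogens", {})),
        reference_coords=np.array(ref, dtype=float) if ref is not None else None)


# ---------------------------------------------------------------------------
# Layer assignment
# ---------------------------------------------------------------------------

def _long_axis(coords: np.ndarray) -> np.ndarray:
    """Principal axis of the coordinate cloud (unit vector, arbitrary sign)."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    return v[:, np.argmax(w)]


def assign_layers(model: FibrilModel, layer_spec="chain") -> FibrilModel:
    """Assign each residue to a beta-strand layer (rung of the stack).

    ``layer_spec`` is either the string ``"chain"`` (each chain is one
    layer — resolved N-terminal segments inherit the layer of their
    chain), or a mapping ``chain_id -> group``, or a mapping
    ``(chain_id, resid) -> group``. Groups are relabelled 0..L-1 by
    increasing centroid position along the structure's long axis.
    """
    keys = model.residue_keys()
    raw: dict[tuple[str, int], int] = {}
    if isinstance(layer_spec, str):
        if layer_spec != "chain":
            raise ValueError(f"unknown layer_spec {layer_spec!r}")
        chains = list(dict.fromkeys(model.chain_ids.tolist()))
        cmap = {c: i for i, c in enumerate(chains)}
        raw = {k: cmap[k[0]] for k in keys}
    else:
        for k in keys:
            if k in layer_spec:
                raw[k] = int(layer_spec[k])
            elif k[0] in layer_spec:
                raw[k] = int(layer_spec[k[0]])
            else:
                raise ValueError(
                    f"layer_spec does not cover residue {k[1]} (chain {k[0]})")

    res_idx = model.residue_atom_indices()
    groups = sorted(set(raw.values()))
    axis = _long_axis(model.coords)
    centroids = {}
    for g in groups:
        idx = np.concatenate([res_idx[k] for k in keys if raw[k] == g])
        centroids[g] = float(model.coords[idx].mean(axis=0) @ axis)
    order = sorted(groups, key=lambda g: centroids[g])
    relabel = {g: i for i, g in enumerate(order)}

    layer_index = np.empty(model.n_atoms, dtype=int)
    for k in keys:
        layer_index[res_idx[k]] = relabel[raw[k]]
    return replace(model, layer_index=layer_index)
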