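"""Synthetic fibrils, hopping trajectories and NMR peak tables.

This module provides ground-truth-bearing inputs for every analysis
stage: a toy stacked-layer protofilament whose backbone N-H and C=O
groups line an axial channel, a ligand performing a continuous-time
Markov jump process between layer-registered sites (with thermal
jitter), Boltzmann-distributed insertion depths under an arbitrary
piecewise-linear potential, and paired free/bound NMR peak tables with
region-localised shift perturbation and attenuation.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import GAS_CONSTANT_KJ, DwellEvent, DwellEventSet
from .model_io import (FibrilModel, LigandTopology, PeakTable, Trajectory,
                       TrajectoryEnsemble)

#: cross-beta stacking rise (nm), the canonical ~4.8 A strand spacing
DEFAULT_RISE = 0.48


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class HoppingSpec:
    """Markov-jump translation of the ligand along the cavity axis."""

    n_sites: int = 8
    site_spacing: float = DEFAULT_RISE      # nm, one layer per site
    rate_up: float = 0.25                   # 1/ns
    rate_down: float = 0.25                 # 1/ns
    jitter_sigma: float = 0.05              # nm, isotropic thermal jitter
    n_frames: int = 2000
    frame_interval: float = 0.1             # ns (snapshots every 100 ps)
    n_trajectories: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.rate_up < 0 or self.rate_down < 0:
            raise ValueError("rates must be non-negative")
        if self.site_spacing <= 0:
            raise ValueError("site_spacing must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")
        if self.n_sites < 1 or self.n_frames < 1 or self.n_trajectories < 1:
            raise ValueError("n_sites, n_frames, n_trajectories must be >= 1")


@dataclass
class PotentialSpec:
    """Piecewise-linear free-energy profile G(x) with temperature."""

    breakpoints: tuple[tuple[float, float], ...]  # (x nm, G kJ/mol)
    temperature: float = 300.0

    def __post_init__(self):
        x = np.array([p[0] for p in self.breakpoints], dtype=float)
        g = np.array([p[1] for p in self.breakpoints], dtype=float)
        if x.size < 2 or not np.all(np.diff(x) > 0):
            raise ValueError("breakpoint x values must be strictly increasing"
                             " (need at least two)")
        if not np.all(np.isfinite(g)):
            raise ValueError("breakpoint G values must be finite")
        self._x, self._g = x, g

    @property
    def domain(self) -> tuple[float, float]:
        return float(self._x[0]), float(self._x[-1])

    def G(self, x) -> np.ndarray:
        """Linear interpolation of the potential (kJ/mol)."""
        return np.interp(x, self._x, self._g)


@dataclass
class PerturbationSpec:
    """Region-localised CSP and attenuation for paired peak tables."""

    perturbed_residues: frozenset[int] = frozenset()
    csp_ppm: dict = field(default_factory=lambda: {
        "HN": 0.02, "N": 0.2, "CA": 0.1, "CB": 0.08})
    attenuation_factor: float = 0.5
    noise_sd: dict = field(default_factory=lambda: {
        "HN": 0.0, "N": 0.0, "CA": 0.0, "CB": 0.0})
    intensity_noise_cv: float = 0.0
    glycine_residues: frozenset[int] = frozenset()  # residues without CB
    seed: int = 0

    def __post_init__(self):
        self.perturbed_residues = frozenset(int(r)
                                            for r in self.perturbed_residues)
        self.glycine_residues = frozenset(int(r)
                                          for r in self.glycine_residues)
        if not (0.0 <= self.attenuation_factor <= 1.0):
            raise ValueError("attenuation_factor must be in [0, 1]")
        if any(v < 0 for v in self.noise_sd.values()) \
                or self.intensity_noise_cv < 0:
            raise ValueError("noise parameters must be non-negative")


# ---------------------------------------------------------------------------
# Toy fibril
# ---------------------------------------------------------------------------

def build_toy_fibril(n_layers: int = 10, residues_per_layer: int = 8,
                     rise: float = DEFAULT_RISE, cavity_radius: float = 0.5,
                     seed: int | None = None) -> FibrilModel:
    """Toy cross-beta protofilament with a linear axial cavity.

    Layers are translated copies stacked along +z at spacing ``rise``;
    each layer is one chain. Each residue carries N, H, CA, C, O and a
    sidechain pseudo-atom (CB); backbone amide N-H vectors point along
    +z and the amide N and carbonyl O sit on a circle of radius
    ``cavity_radius`` so they line the channel. With a seed, sidechain
    pseudo-atoms get a small reproducible placement jitter.
    """
    if n_layers < 2:
        raise ValueError("need at least two layers")
    if rise <= 0 or cavity_radius <= 0:
        raise ValueError("rise and cavity_radius must be positive")
    rng = np.random.default_rng(seed) if seed is not None else None

    names, elements, resids, chains, layer_idx, coords, resnames = \
        [], [], [], [], [], [], []
    chain_labels = [chr(ord("A") + (k % 26)) + ("" if k < 26 else str(k // 26))
                    for k in range(n_layers)]
    for k in range(n_layers):
        z = k * rise
        for j in range(residues_per_layer):
            theta = 2 * np.pi * j / residues_per_layer
            u = np.array([np.cos(theta), np.sin(theta), 0.0])
            # tangential direction for the carbonyl placement
            v = np.array([-np.sin(theta), np.cos(theta), 0.0])
            n_xyz = cavity_radius * u + np.array([0, 0, z])
            atoms = {
                "N": n_xyz,
                "H": n_xyz + np.array([0, 0, 0.101]),
                "CA": (cavity_radius + 0.15) * u + np.array([0, 0, z + 0.05]),
                "C": (cavity_radius + 0.10) * u + 0.12 * v
                     + np.array([0, 0, z + 0.10]),
                "O": cavity_radius * u + 0.12 * v + np.array([0, 0, z + 0.12]),
                "CB": (cavity_radius + 0.30) * u + np.array([0, 0, z + 0.05]),
            }
            if rng is not None:
                atoms["CB"] = atoms["CB"] + rng.normal(0.0, 0.01, 3)
            for nm, xyz in atoms.items():
                names.append(nm)
                elements.append("H" if nm == "H" else nm[0])
                resids.append(j + 1)
                chains.append(chain_labels[k])
                layer_idx.append(k)
                coords.append(xyz)
                resnames.append("GLY")
    return FibrilModel(
        atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resids=np.array(resids, dtype=int),
        chain_ids=np.array(chains, dtype=object),
        coords=np.array(coords),
        layer_index=np.array(layer_idx, dtype=int),
        resnames=np.array(resnames, dtype=object))


# ---------------------------------------------------------------------------
# Hopping trajectories
# ---------------------------------------------------------------------------

def _gillespie_sites(spec: HoppingSpec, rng: np.random.Generator,
                     t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Jump times and the site occupied from each time on (reflecting
    boundaries). Starts in the middle site at t = 0."""
    jump_times = [0.0]
    sites = [spec.n_sites // 2]
    t = 0.0
    while True:
        s = sites[-1]
        k_up = spec.rate_up if s < spec.n_sites - 1 else 0.0
        k_down = spec.rate_down if s > 0 else 0.0
        k_tot = k_up + k_down
        if k_tot == 0.0:
            break
        t += rng.exponential(1.0 / k_tot)
        if t >= t_end:
            break
        step = 1 if rng.random() < k_up / k_tot else -1
        jump_times.append(t)
        sites.append(s + step)
    return np.array(jump_times), np.array(sites, dtype=int)


def simulate_hopping(spec: HoppingSpec, ligand: LigandTopology,
                     fibril: FibrilModel,
                     ) -> tuple[TrajectoryEnsemble, DwellEventSet]:
    """Markov-jump hopping of the ligand along the fibril cavity axis.

    The ligand centre (pyrazole-ring COM) performs a continuous-time
    Markov jump process over ``n_sites`` lattice sites spaced
    ``site_spacing`` apart along +z, sampled exactly (Gillespie) with
    reflecting boundaries, discretised at ``frame_interval`` and dressed
    with isotropic Gaussian jitter of the rigid ligand body. Jitter is
    applied after the jump-state discretisation, so the returned ground
    truth dwell events are exact by construction: the sum of all dwell
    durations (censored tails included) equals the trajectory length.

    Returns the ligand-coordinate ensemble and the ground-truth
    :class:`DwellEventSet` (first/last dwells flagged censored).
    """
    if ligand.reference_coords is None:
        raise ValueError("ligand topology carries no reference geometry")
    zs = fibril.coords[:, 2]
    extent = zs.max() - zs.min()
    span = (spec.n_sites - 1) * spec.site_spacing
    if span > extent + 1e-9:
        raise ValueError(
            f"site lattice span {span:.3f} nm exceeds fibril extent "
            f"{extent:.3f} nm")
    origin_z = zs.min() + 0.5 * (extent - span)
    center_xy = fibril.coords[:, :2].mean(axis=0)

    # rigid template centred on the pyrazole-ring COM
    ring = ligand.group_indices("pyrazole_ring")
    w = ligand.masses[ring]
    template = ligand.reference_coords - np.average(
        ligand.reference_coords[ring], axis=0, weights=w)

    rng = np.random.default_rng(spec.seed)
    t_end = (spec.n_frames - 1) * spec.frame_interval
    frame_times = np.arange(spec.n_frames) * spec.frame_interval

    trajectories, events = [], []
    for tid in range(spec.n_trajectories):
        jump_times, sites = _gillespie_sites(spec, rng, t_end)
        # ground-truth dwell events, clipped to the observation window
        seg_ends = np.append(jump_times[1:], t_end)
        for k, (t0, t1, s) in enumerate(zip(jump_times, seg_ends, sites)):
            if t1 <= t0:
                continue
            events.append(DwellEvent(
                trajectory_id=tid, site_index=int(s),
                start=float(t0), duration=float(t1 - t0),
                censored=(k == 0 or k == len(sites) - 1)))
        # frame-wise site: state at each frame time (right-continuous)
        frame_site = sites[np.searchsorted(jump_times, frame_times,
                                           side="right") - 1]
        centers = np.column_stack([
            np.full(spec.n_frames, center_xy[0]),
            np.full(spec.n_frames, center_xy[1]),
            origin_z + frame_site * spec.site_spacing])
        if spec.jitter_sigma > 0:
            centers = centers + rng.normal(0.0, spec.jitter_sigma,
                                           centers.shape)
        coords = centers[:, None, :] + template[None, :, :]
        trajectories.append(Trajectory(times=frame_times, coords=coords))

    ensemble = TrajectoryEnsemble(
        atom_names=tuple(ligand.atom_names),
        elements=tuple(ligand.elements),
        trajectories=trajectories,
        frame_interval=spec.frame_interval)
    truth = DwellEventSet(events, site_spacing=spec.site_spacing,
                          origin=origin_z)
    return ensemble, truth


# ---------------------------------------------------------------------------
# Boltzmann depth sampling
# ---------------------------------------------------------------------------

def sample_boltzmann_depths(spec: PotentialSpec, n: int,
                            seed: int | None = None,
                            grid_points: int = 4096) -> np.ndarray:
    """Draw insertion depths with density proportional to exp(-G(x)/RT).

    Inverse-CDF sampling on a fine grid over the breakpoint domain;
    composing this with the Boltzmann-inversion profile analysis
    recovers the input potential.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = spec.domain
    x = np.linspace(lo, hi, grid_points)
    RT = GAS_CONSTANT_KJ * spec.temperature
    g = spec.G(x)
    w = np.exp(-(g - g.min()) / RT)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                           * np.diff(x))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, x)


# ---------------------------------------------------------------------------
# Paired peak tables
# ---------------------------------------------------------------------------

def generate_peak_tables(n_residues: int, spec: PerturbationSpec,
                         first_residue: int = 1,
                         ) -> tuple[PeakTable, PeakTable]:
    """Paired free/bound peak tables with known perturbations.

    The free table carries plausible backbone shifts (per-nucleus
    baseline plus reproducible residue-to-residue scatter) and unit-scale
    intensities. Bound shifts add the configured CSP offsets on the
    perturbed residues plus per-nucleus Gaussian noise everywhere; bound
    intensities are scaled by the attenuation factor on perturbed
    residues and by multiplicative lognormal noise with the configured
    CV. Glycine-like residues omit their CB rows in both tables.
    """
    residues = np.arange(first_residue, first_residue + n_residues)
    bad = spec.perturbed_residues - set(residues.tolist())
    if bad:
        raise ValueError(f"perturbed residues {sorted(bad)} outside "
                         f"{first_residue}..{residues[-1]}")
    rng = np.random.default_rng(spec.seed)
    baseline = {"HN": 8.3, "N": 119.0, "CA": 55.0, "CB": 35.0}
    scatter = {"HN": 0.4, "N": 4.0, "CA": 2.5, "CB": 4.0}

    free_rows, bound_rows = [], []
    for r in residues:
        nuclei = [n for n in ("HN", "N", "CA", "CB")
                  if not (n == "CB" and r in spec.glycine_residues)]
        perturbed = r in spec.perturbed_residues
        for nuc in nuclei:
            shift = baseline[nuc] + rng.normal(0.0, scatter[nuc])
            intensity = rng.uniform(80.0, 120.0)
            free_rows.append((int(r), nuc, shift, intensity))
            b_shift = shift + (spec.csp_ppm.get(nuc, 0.0) if perturbed else 0.0)
            sd = spec.noise_sd.get(nuc, 0.0)
            if sd > 0:
                b_shift += rng.normal(0.0, sd)
            b_int = intensity * (spec.attenuation_factor if perturbed else 1.0)
            if spec.intensity_noise_cv > 0:
                sigma = np.sqrt(np.log1p(spec.intensity_noise_cv ** 2))
                b_int *= rng.lognormal(-0.5 * sigma ** 2, sigma)
            bound_rows.append((int(r), nuc, b_shift, b_int))

    cols = ["residue", "nucleus", "shift_ppm", "intensity"]
    return (PeakTable(pd.DataFrame(free_rows, columns=cols)),
            PeakTable(pd.DataFrame(bound_rows, columns=cols)))
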