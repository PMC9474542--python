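"""End-to-end orchestration from a single structured config.

Stage order: trim -> geometry (depth series) -> contacts/bonds -> modes
-> profile/dwell -> RMSF (protein trajectories, optional) -> NMR branch
(optional). Every stage writes CSV; a manifest records the config hash,
seed, package version and completed stages so a run can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import detect_dwell_events, dwell_time_summary, \
    free_energy_profile
from .geometry import AxisDefinition, depth_series, discard_equilibration, \
    rmsf
from .interactions import ContactCriteria, PolarBondCriteria, \
    contact_probabilities
from .model_io import anle138b_topology, assign_layers, read_ligand_topology, \
    read_peak_table, read_structure, read_trajectory
from .modes import classify_ensemble, mode_populations
from .nmr import perturbation_table


@dataclass
class RunConfig:
    """Validated run configuration (paths, criteria, analysis knobs).

    Every geometric constant of the analyses is a named key with its
    standard value as default: heavy-atom cutoff 0.4 nm, pyrazole-N
    backbone cutoff 0.5 nm, XB 0.36 nm / 150 deg, HB 0.35 nm / 150 deg,
    temperature 300 K, equilibration fraction 0.25 (keep last 75%),
    smoothing window 2 residues.
    """

    output_dir: str = "fibrilsite_out"
    seed: int = 0
    fibril_pdb: str | None = None
    ligand_topology: str = "anle138b"       # path or the built-in name
    trajectories: list = field(default_factory=list)
    protein_trajectories: list = field(default_factory=list)
    free_peaks: str | None = None
    bound_peaks: str | None = None

    frame_interval: float = 0.1             # ns
    discard_fraction: float = 0.25
    heavy_cutoff: float = 0.40              # nm
    nitrogen_backbone_cutoff: float = 0.50  # nm
    exclude_edge_layers: bool = True
    hb_cutoff: float = 0.35                 # nm
    hb_angle_min: float = 150.0             # deg
    xb_cutoff: float = 0.36                 # nm
    xb_angle_min: float = 150.0             # deg
    temperature: float = 300.0              # K
    bin_width: float = 0.05                 # nm
    site_spacing: float = 0.48              # nm
    core_fraction: float = 0.5
    min_residence_frames: int = 1
    dwell_origin: float | None = None
    tip_layer: int = 0
    axis_start_residue: int = 36
    axis_stride: int = 2
    axis_span: tuple = (36, 56)
    smooth_window: int = 2
    contact_layers: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not (0 <= self.discard_fraction < 1):
            raise ValueError("discard_fraction must be in [0, 1)")
        for p in [self.fibril_pdb, self.free_peaks, self.bound_peaks,
                  *self.trajectories, *self.protein_trajectories]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.ligand_topology != "anle138b" \
                and not Path(self.ligand_topology).exists():
            raise FileNotFoundError(
                f"ligand topology not found: {self.ligand_topology}")

    def contact_criteria(self) -> ContactCriteria:
        return ContactCriteria(
            heavy_cutoff=self.heavy_cutoff,
            nitrogen_backbone_cutoff=self.nitrogen_backbone_cutoff,
            exclude_edge_layers=self.exclude_edge_layers)

    def bond_criteria(self) -> PolarBondCriteria:
        return PolarBondCriteria(
            hb_donor_acceptor_cutoff=self.hb_cutoff,
            hb_angle_min=self.hb_angle_min,
            xb_distance_cutoff=self.xb_cutoff,
            xb_angle_min=self.xb_angle_min)

    def config_hash(self) -> str:
        doc = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in asdict(self).items()}
        blob = json.dumps(doc, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_ligand(cfg: RunConfig):
    if cfg.ligand_topology == "anle138b":
        return anle138b_topology()
    return read_ligand_topology(cfg.ligand_topology)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict.

    A stage failure is recorded in the manifest (completed stages keep
    their outputs) and re-raised.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    from importlib.metadata import version as _dist_version
    try:
        pkg_version = _dist_version("fibrilsite")
    except Exception:  # noqa: BLE001 - not installed as a distribution
        pkg_version = "unknown"
    manifest = {
        "package_version": pkg_version,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }

    def done(stage: str, *files: Path):
        manifest["stages"].append(stage)
        for f in files:
            manifest["outputs"].setdefault(stage, []).append(str(f))

    try:
        ligand = _load_ligand(config)
        model = None
        if config.fibril_pdb:
            model = read_structure(config.fibril_pdb)
            model = assign_layers(model, "chain")
            done("load_structure")

        if config.trajectories and model is not None:
            ens = read_trajectory(config.trajectories, topology=ligand,
                                  frame_interval=config.frame_interval)
            ens = discard_equilibration(ens, config.discard_fraction)
            done("trim")

            depths = depth_series(ens, ligand, model,
                                  tip_layer=config.tip_layer)
            rows = [{"trajectory_id": i, "time_ns": t, "x_nm": x}
                    for i, (traj, d) in enumerate(zip(ens.trajectories,
                                                      depths))
                    for t, x in zip(traj.times, d)]
            f = out / "depth_series.csv"
            pd.DataFrame(rows).to_csv(f, index=False)
            done("geometry", f)

            crit, bcrit = config.contact_criteria(), config.bond_criteria()
            files = []
            for definition in ("heavy", "nitrogen_backbone", "hb", "xb"):
                cmap = contact_probabilities(ens, model, ligand, crit,
                                             definition, bcrit)
                f = out / f"contacts_{definition}.csv"
                cmap.to_csv(f, index=False)
                files.append(f)
            done("contacts", *files)

            labels = classify_ensemble(ens, model, ligand, crit, bcrit)
            lab_rows = [{"trajectory_id": i, "time_ns": lab.frame_time,
                         "major": lab.major,
                         "sub": "|".join(sorted(lab.sub))}
                        for i, seq in enumerate(labels) for lab in seq]
            f1 = out / "mode_labels.csv"
            pd.DataFrame(lab_rows).to_csv(f1, index=False)
            f2 = out / "mode_populations.csv"
            mode_populations(labels).to_csv(f2, index=False)
            done("modes", f1, f2)

            profile = free_energy_profile(depths, config.bin_width,
                                          config.temperature)
            f = out / "free_energy_profile.csv"
            pd.DataFrame({
                "bin_center_nm": profile.bin_centers,
                "G_kJmol": profile.G,
                "sem_kJmol": profile.sem,
                "count": profile.counts,
                "masked": ~profile.mask,
            }).to_csv(f, index=False)
            origin = (config.dwell_origin if config.dwell_origin is not None
                      else float(np.concatenate(depths).min()))
            events = detect_dwell_events(
                depths, config.site_spacing, origin,
                core_fraction=config.core_fraction,
                min_residence_frames=config.min_residence_frames,
                times=[t.times for t in ens.trajectories])
            f2 = out / "dwell_events.csv"
            pd.DataFrame([{
                "trajectory_id": e.trajectory_id, "site": e.site_index,
                "start_ns": e.start, "duration_ns": e.duration,
                "censored": e.censored} for e in events.events]
            ).to_csv(f2, index=False)
            files = [f, f2]
            uncensored = events.durations(exclude_censored=True)
            if uncensored.size:
                s = dwell_time_summary(events)
                f3 = out / "dwell_summary.csv"
                pd.DataFrame({
                    "bin_right_edge_ns": s.bin_edges[1:],
                    "cumulative_count": s.cumulative,
                }).to_csv(f3, index=False)
                manifest["dwell_mean_ns"] = s.mean
                manifest["dwell_sem_ns"] = s.sem
                files.append(f3)
            done("profile_dwell", *files)

        if config.protein_trajectories and model is not None:
            pens = read_trajectory(config.protein_trajectories,
                                   frame_interval=config.frame_interval)
            pens = discard_equilibration(pens, config.discard_fraction)
            table = rmsf(pens, model,
                         contact_layers=set(config.contact_layers))
            f = out / "rmsf.csv"
            pd.DataFrame({
                "chain": table.chain_ids, "residue": table.resids,
                "layer": table.layer, "class": table.strand_class,
                "rmsf_nm": table.rmsf, "sem_nm": table.sem,
            }).to_csv(f, index=False)
            done("rmsf", f)

        if config.free_peaks and config.bound_peaks:
            free = read_peak_table(config.free_peaks)
            bound = read_peak_table(config.bound_peaks)
            pert = perturbation_table(free, bound,
                                      smooth_window=config.smooth_window)
            f = out / "perturbation.csv"
            pert.to_csv(f)
            done("nmr", f)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
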