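"""Occupancy-derived free-energy profiles and dwell-time kinetics.

The free-energy profile along the ligand insertion depth x is obtained
by Boltzmann inversion of the binned occupancy: with p_i the fraction of
frames in bin i, G_i = -RT ln p_i (T = 300 K by default), shifted so the
minimum over populated bins is zero. Dwell events are extracted from the
depth (or axial-projection) series by registering the ligand to a
lattice of sites one layer spacing apart, with a hysteresis (core-zone)
rule so that thermal jitter at a cell boundary does not generate
spurious transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: molar gas constant, kJ/(mol K)
GAS_CONSTANT_KJ = 8.314462618e-3

#: RT at 300 K in kJ/mol
RT_KJ_PER_MOL = GAS_CONSTANT_KJ * 300.0


@dataclass
class FreeEnergyProfile:
    """Binned G(x) in kJ/mol with SEM across trajectories.

    ``G`` is NaN on masked (zero-count) bins; the minimum over populated
    bins is zero. ``sem`` is NaN where fewer than two trajectories
    populate a bin.
    """

    bin_edges: np.ndarray           # (n_bins + 1,) nm
    G: np.ndarray                   # (n_bins,) kJ/mol, NaN = masked
    sem: np.ndarray                 # (n_bins,) kJ/mol
    counts: np.ndarray              # (n_bins,) pooled counts
    temperature: float = 300.0      # K

    @property
    def RT(self) -> float:
        return GAS_CONSTANT_KJ * self.temperature

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mask(self) -> np.ndarray:
        """True on populated bins."""
        return self.counts > 0

    def barrier(self) -> float:
        """Highest G between the two outermost populated minima's flanks.

        Returns the maximum of G over populated bins (the minimum is 0 by
        construction, so this is the largest barrier seen anywhere in the
        profile).
        """
        return float(np.nanmax(self.G))


@dataclass
class DwellEvent:
    trajectory_id: int
    site_index: int
    start: float                    # ns
    duration: float                 # ns
    censored: bool


@dataclass
class DwellEventSet:
    """Time-ordered, non-overlapping residence events at lattice sites."""

    events: list[DwellEvent]
    site_spacing: float             # nm
    origin: float = 0.0             # nm, position of site 0

    def __post_init__(self):
        by_traj: dict[int, list[DwellEvent]] = {}
        for e in self.events:
            if e.duration <= 0:
                raise ValueError(f"non-positive dwell duration {e.duration}")
            by_traj.setdefault(e.trajectory_id, []).append(e)
        for tid, evs in by_traj.items():
            for a, b in zip(evs, evs[1:]):
                if b.start < a.start + a.duration - 1e-9:
                    raise ValueError(
                        f"overlapping dwell events in trajectory {tid}")

    def durations(self, exclude_censored: bool = True) -> np.ndarray:
        evs = self.events if not exclude_censored else [
            e for e in self.events if not e.censored]
        return np.array([e.duration for e in evs])

    def n_transitions(self) -> int:
        """Committed site changes = events beyond the first, per trajectory."""
        by_traj: dict[int, int] = {}
        for e in self.events:
            by_traj[e.trajectory_id] = by_traj.get(e.trajectory_id, 0) + 1
        return sum(max(n - 1, 0) for n in by_traj.values())

    def __len__(self) -> int:
        return len(self.events)


# ---------------------------------------------------------------------------
# Free-energy profile
# ---------------------------------------------------------------------------

def free_energy_profile(depth_series, bin_width: float = 0.05,
                        temperature: float = 300.0,
                        bin_range: tuple[float, float] | None = None,
                        ) -> FreeEnergyProfile:
    """Boltzmann-invert pooled insertion-depth samples into G(x).

    Parameters
    ----------
    depth_series : sequence of 1-d arrays
        Insertion depths (nm), one array per independent trajectory.
        Samples are pooled for the profile; per-trajectory profiles are
        used only for the SEM.
    bin_width : float
        Bin width in nm. Default 0.05 nm (about a tenth of the cross-beta
        layer spacing, resolving per-layer minima).
    temperature : float
        Temperature in K for RT.
    bin_range : optional (lo, hi)
        Explicit binning domain; defaults to the pooled data range.

    The pooled profile is G_i = -RT ln(n_i / n_total), shifted so its
    minimum over populated bins is zero. Zero-count bins are masked
    (NaN), never reported as G = 0. The SEM per bin is computed across
    per-trajectory profiles referenced to the pooled minimum bin, using
    only trajectories that populate both bins.
    """
    series = [np.asarray(s, dtype=float).ravel() for s in depth_series]
    series = [s for s in series if s.size > 0]
    if not series:
        raise ValueError("no depth samples provided")
    pooled = np.concatenate(series)
    if bin_range is None:
        lo, hi = float(pooled.min()), float(pooled.max())
    else:
        lo, hi = map(float, bin_range)
    if hi <= lo:
        hi = lo + bin_width
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)

    RT = GAS_CONSTANT_KJ * temperature
    counts, _ = np.histogram(pooled, bins=edges)
    total = counts.sum()
    with np.errstate(divide="ignore"):
        G = -RT * np.log(counts / total)
    G[counts == 0] = np.nan
    ref_bin = int(np.nanargmin(G))
    G = G - G[ref_bin]

    # SEM across trajectories, each referenced to the pooled minimum bin
    per_traj = []
    for s in series:
        c, _ = np.histogram(s, bins=edges)
        with np.errstate(divide="ignore"):
            g = -RT * np.log(c / c.sum())
        g[c == 0] = np.nan
        g = g - g[ref_bin] if c[ref_bin] > 0 else np.full_like(g, np.nan)
        per_traj.append(g)
    stack = np.vstack(per_traj)
    n_ok = np.sum(np.isfinite(stack), axis=0)
    sem = np.full(n_bins, np.nan)
    multi = n_ok >= 2
    if np.any(multi):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            sem[multi] = (np.nanstd(stack[:, multi], axis=0, ddof=1)
                          / np.sqrt(n_ok[multi]))

    return FreeEnergyProfile(bin_edges=edges, G=G, sem=sem, counts=counts,
                             temperature=temperature)


# ---------------------------------------------------------------------------
# Dwell-time extraction
# ---------------------------------------------------------------------------

def _site_track(x: np.ndarray, site_spacing: float, origin: float,
                core_fraction: float, min_residence_frames: int) -> np.ndarray:
    """Committed site index per frame under the hysteresis rule.

    A transition to a new site is committed only once the signal lies
    within the inner ``core_fraction`` of the new site's cell for at
    least ``min_residence_frames`` consecutive frames; until then the
    previous committed site is retained.
    """
    nearest = np.rint((x - origin) / site_spacing).astype(int)
    in_core = np.abs(x - (origin + nearest * site_spacing)) \
        <= 0.5 * core_fraction * site_spacing
    committed = np.empty_like(nearest)
    current = nearest[0]
    committed[0] = current
    run_site, run_len = None, 0
    for i in range(1, x.size):
        cand = nearest[i]
        if cand != current and in_core[i]:
            if cand == run_site:
                run_len += 1
            else:
                run_site, run_len = cand, 1
            if run_len >= min_residence_frames:
                current = cand
                run_site, run_len = None, 0
        else:
            run_site, run_len = None, 0
        committed[i] = current
    return committed


def detect_dwell_events(series, site_spacing: float, origin: float = 0.0,
                        core_fraction: float = 0.5,
                        min_residence_frames: int = 1,
                        times=None, frame_interval: float = 0.1,
                        trajectory_id: int = 0) -> DwellEventSet:
    """Extract dwell events from one or more depth/axial series.

    ``series`` is a 1-d array or a sequence of 1-d arrays (one per
    trajectory). Site index = nearest integer of (x - origin) / spacing,
    committed under the core-zone hysteresis rule. The first and last
    dwell of each trajectory are flagged censored (their true extent is
    cut by the observation window).
    """
    if site_spacing <= 0:
        raise ValueError("site_spacing must be positive")
    if not (0 < core_fraction <= 1):
        raise ValueError("core_fraction must be in (0, 1]")
    first = np.asarray(series[0]) if len(series) else None
    multi = first is not None and first.ndim >= 1 and np.ndim(series[0]) != 0
    series_list = [np.asarray(s, dtype=float) for s in series] if multi \
        else [np.asarray(series, dtype=float)]
    if times is not None and not multi:
        times = [times]

    events: list[DwellEvent] = []
    for tid, x in enumerate(series_list):
        t = (np.asarray(times[tid], dtype=float) if times is not None
             else np.arange(x.size) * frame_interval)
        if x.size != t.size:
            raise ValueError("times and series length mismatch")
        track = _site_track(x, site_spacing, origin, core_fraction,
                            min_residence_frames)
        change = np.nonzero(np.diff(track))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change, [x.size - 1]])
        for k, (a, b) in enumerate(zip(starts, ends)):
            # dwell extends to the frame where the next site is committed
            t_end = t[b + 1] if b + 1 < x.size else t[-1]
            duration = t_end - t[a]
            if duration <= 0:
                duration = frame_interval  # single-frame dwell at the tail
            events.append(DwellEvent(
                trajectory_id=trajectory_id + tid,
                site_index=int(track[a]),
                start=float(t[a]), duration=float(duration),
                censored=(k == 0 or k == len(starts) - 1)))
    return DwellEventSet(events, site_spacing=site_spacing, origin=origin)


@dataclass
class DwellSummary:
    mean: float                     # ns
    sem: float                      # ns, NaN for a single event
    n_events: int
    bin_edges: np.ndarray           # ns
    cumulative: np.ndarray          # counts with duration <= right edge


def dwell_time_summary(events: DwellEventSet, exclude_censored: bool = True,
                       n_bins: int = 30, log_bins: bool = False,
                       ) -> DwellSummary:
    """Cumulative dwell-time histogram plus mean and SEM over events."""
    d = events.durations(exclude_censored=exclude_censored)
    if d.size == 0:
        if exclude_censored:
            raise ValueError(
                "no uncensored dwell events; pass exclude_censored=False "
                "to include window-truncated dwells")
        raise ValueError("no dwell events")
    if log_bins:
        lo = max(d.min(), 1e-6)
        edges = np.geomspace(lo, d.max() * (1 + 1e-12), n_bins + 1)
    else:
        edges = np.linspace(0.0, d.max() * (1 + 1e-12), n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    sem = float(d.std(ddof=1) / np.sqrt(d.size)) if d.size > 1 else float("nan")
    return DwellSummary(mean=float(d.mean()), sem=sem, n_events=int(d.size),
                        bin_edges=edges, cumulative=np.cumsum(counts))
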