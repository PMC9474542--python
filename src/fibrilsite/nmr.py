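"""Chemical-shift perturbation and signal attenuation between peak tables.

CSP per residue is the unweighted mean of absolute shift differences
over the nuclei present in both states among HN, N, CA and CB (no
nucleus-specific scaling by default; a weighted variant is available).
Signal attenuation is the bound/free intensity ratio per matched peak,
averaged over nuclei; a bound peak that has disappeared while the free
peak exists counts as ratio 0 (attenuated beyond detection, indicating
increased local dynamics), not as missing data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .model_io import PeakTable, VALID_NUCLEI

#: commonly used per-nucleus CSP weights (relative to 1H); optional
DEFAULT_NUCLEUS_WEIGHTS = {"HN": 1.0, "N": 0.2, "CA": 0.3, "CB": 0.3}


def _pivot(table: PeakTable, value: str) -> pd.DataFrame:
    return table.data.pivot(index="residue", columns="nucleus", values=value)


def csp_per_residue(free: PeakTable, bound: PeakTable,
                    weights: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-residue chemical-shift perturbation (ppm).

    Returns a DataFrame indexed by residue with columns ``csp_ppm`` and
    ``n_nuclei_used``. Residues absent from either table, or with no
    shared nuclei, get NaN (with a warning for the latter). When
    ``weights`` is given, per-nucleus |delta| values are scaled before
    averaging (non-default).
    """
    f = _pivot(free, "shift_ppm")
    b = _pivot(bound, "shift_ppm")
    residues = sorted(set(f.index) | set(b.index))
    f = f.reindex(index=residues, columns=VALID_NUCLEI)
    b = b.reindex(index=residues, columns=VALID_NUCLEI)
    delta = (b - f).abs()
    if weights is not None:
        for nuc, w in weights.items():
            if nuc in delta.columns:
                delta[nuc] = delta[nuc] * w
    n_used = delta.notna().sum(axis=1)
    both_present = f.notna().any(axis=1) & b.notna().any(axis=1)
    no_shared = both_present & (n_used == 0)
    if no_shared.any():
        warnings.warn(
            f"residues {sorted(delta.index[no_shared])} share no nuclei "
            f"between the two tables; CSP is undefined there", stacklevel=2)
    csp = delta.mean(axis=1, skipna=True)
    csp[n_used == 0] = np.nan
    return pd.DataFrame({"csp_ppm": csp, "n_nuclei_used": n_used.astype(int)},
                        index=pd.Index(residues, name="residue"))


def intensity_ratio(free: PeakTable, bound: PeakTable) -> pd.DataFrame:
    """Per-residue bound/free intensity ratio (signal attenuation).

    Per matched nucleus the ratio is I_bound / I_free; a missing bound
    peak with an existing free peak contributes 0; a missing or zero
    free peak makes that nucleus (and, if none remain, the residue)
    undefined, with a warning for zero intensities. Nucleus ratios are
    averaged per residue.
    """
    f = _pivot(free, "intensity")
    b = _pivot(bound, "intensity")
    residues = sorted(set(f.index) | set(b.index))
    f = f.reindex(index=residues, columns=VALID_NUCLEI)
    b = b.reindex(index=residues, columns=VALID_NUCLEI)
    zero_free = (f == 0)
    if zero_free.any().any():
        warnings.warn("zero free-state intensities encountered; the affected "
                      "peaks are excluded from the ratio", stacklevel=2)
    f = f.mask(zero_free)
    ratio = b / f
    ratio = ratio.where(~(f.notna() & b.isna()), 0.0)  # disappearance -> 0
    n_used = (ratio.notna() & f.notna()).sum(axis=1)
    mean_ratio = ratio.mean(axis=1, skipna=True)
    mean_ratio[n_used == 0] = np.nan
    return pd.DataFrame(
        {"intensity_ratio": mean_ratio, "n_nuclei_used": n_used.astype(int)},
        index=pd.Index(residues, name="residue"))


def moving_average(series: pd.Series, window: int = 2) -> pd.Series:
    """Missing-aware trailing moving average over consecutive residues.

    The value at residue i is the mean of the defined values at residues
    i .. i+window-1 (reported at the first residue of the window);
    windows whose values are all missing stay missing. The index must be
    integer residue numbers; gaps count as missing residues.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window == 1:
        return series.copy()
    residues = np.arange(int(series.index.min()),
                         int(series.index.max()) + 1)
    dense = series.reindex(residues).to_numpy(dtype=float)
    out = np.full(residues.size, np.nan)
    for i in range(residues.size):
        win = dense[i:i + window]
        if np.isfinite(win).any():
            out[i] = np.nanmean(win)
    return pd.Series(out, index=pd.Index(residues, name=series.index.name)
                     ).reindex(series.index)


def perturbation_table(free: PeakTable, bound: PeakTable,
                       smooth_window: int = 2,
                       weights: dict[str, float] | None = None,
                       ) -> pd.DataFrame:
    """Combined per-residue CSP and attenuation table with smoothing.

    Columns: csp_ppm, csp_smooth, intensity_ratio, ratio_smooth,
    n_nuclei_csp, n_nuclei_ratio; indexed by residue.
    """
    csp = csp_per_residue(free, bound, weights=weights)
    ratio = intensity_ratio(free, bound)
    out = pd.DataFrame({
        "csp_ppm": csp["csp_ppm"],
        "csp_smooth": moving_average(csp["csp_ppm"], smooth_window),
        "intensity_ratio": ratio["intensity_ratio"],
        "ratio_smooth": moving_average(ratio["intensity_ratio"],
                                       smooth_window),
        "n_nuclei_csp": csp["n_nuclei_used"],
        "n_nuclei_ratio": ratio["n_nuclei_used"],
    })
    out.index.name = "residue"
    return out
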