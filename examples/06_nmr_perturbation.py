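"""Per-residue chemical-shift perturbation and signal attenuation.

Paired free/bound peak tables are generated with a known perturbation on
residues 80-88 (CSP offsets averaging 0.1 ppm over HN/N/CA/CB, bound
intensities halved) plus mild noise, then analysed back: CSP per residue
is the mean absolute shift change over the nuclei observed in both
states, attenuation is the bound/free intensity ratio, and a 2-residue
moving average smooths both.
"""

from fibrilsite import (PerturbationSpec, generate_peak_tables,
                        perturbation_table)

spec = PerturbationSpec(
    perturbed_residues=frozenset(range(80, 89)),
    csp_ppm={"HN": 0.02, "N": 0.2, "CA": 0.1, "CB": 0.08},
    attenuation_factor=0.5,
    noise_sd={"HN": 0.005, "N": 0.02, "CA": 0.01, "CB": 0.01},
    intensity_noise_cv=0.05,
    seed=6)
free, bound = generate_peak_tables(64, spec, first_residue=33)

table = perturbation_table(free, bound, smooth_window=2)
region = table.loc[78:90, ["csp_ppm", "csp_smooth", "intensity_ratio",
                           "ratio_smooth"]]
print(region.round(3).to_string())
print(f"\nperturbed-region mean CSP: "
      f"{table.loc[80:88, 'csp_ppm'].mean():.3f} ppm (input 0.1)")
print(f"perturbed-region mean attenuation: "
      f"{table.loc[80:88, 'intensity_ratio'].mean():.3f} (input 0.5)")
print("Residues outside 80-88 stay near CSP 0 and ratio 1; values "
      "inside flag the cavity-lining region the ligand perturbs.")
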