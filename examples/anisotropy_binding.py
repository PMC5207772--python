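"""Kd from a steady-state fluorescence anisotropy titration.

A 0.2 µM fluorophore-labeled alpha subunit (0.0023 mol% of the bicelle
lipid) is titrated with an unlabeled beta subunit; binding slows tumbling
and raises the anisotropy from r_free toward r_bound.  Concentrations are in
mol% — the natural unit for association confined to a membrane mimetic.
"""

from bicellefit import (
    AnisotropyDesign,
    AnisotropyTruth,
    fit_anisotropy,
    simulate_anisotropy,
)

TRUE_KD = 0.07  # mol%: an avid heterodimer

titration = simulate_anisotropy(AnisotropyTruth(kd=TRUE_KD),
                                AnisotropyDesign(seed=21))
result = fit_anisotropy(titration)

print(f"labeled species U0 : {titration.labeled_conc:.4f} mol%")
print(f"generating Kd      : {TRUE_KD} mol%")
print(f"fitted Kd          : {result.kd:.3f} +/- {result.kd_stderr:.3f} mol% "
      f"({result.bound_flag})")
print(f"r_free / r_bound   : {result.per_peak['r_free'].value:.3f} / "
      f"{result.per_peak['r_bound'].value:.3f}")
print("-> the titration saturates, so Kd is quantifiable rather than a "
      "lower bound.")
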