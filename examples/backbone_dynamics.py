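"""Secondary structure and backbone dynamics from chemical shifts and decays.

Builds a synthetic helix on a random-coil baseline and calls it by
chemical-shift index; computes water hydrogen-exchange ratios along a frayed
helix; and fits per-residue R2 rates from CPMG decay curves.
"""

import numpy as np
import pandas as pd

from bicellefit import (
    ShiftTable,
    cleanex_ratio,
    csi_secondary_structure,
    fit_r2,
    simulate_r2_decay,
)

# --- CSI: a 3 ppm downfield CA stretch over residues 732-765 ---
residues = np.arange(719, 799)
coil = pd.DataFrame({"residue": residues, "ca": 56.0, "cb": 32.0, "co": 176.0})
shifts = coil.copy()
helix = (residues >= 732) & (residues <= 765)
shifts.loc[helix, "ca"] += 3.0
shifts.loc[helix, "co"] += 1.5
frame, segments = csi_secondary_structure(ShiftTable(frame=shifts), coil)
print(f"CSI helix segments  : {segments}")

# --- CLEANEX: exchange protection fading along the frayed helix end ---
ref = pd.Series(100.0, index=residues)
protection = np.clip((residues - 757) / 12.0, 0.0, 1.0)  # frays past the TM
mix = pd.Series(100.0 * protection, index=residues)
ratios = cleanex_ratio(mix, ref)
print(f"CLEANEX I/I0        : {ratios.loc[757]:.2f} at 757 (protected) -> "
      f"{ratios.loc[775]:.2f} at 775 (exchanging)")

# --- R2: rigid TM (high R2) vs mobile tail (low R2) ---
truth = np.where(helix, 35.0, 8.0)
decay = simulate_r2_decay(truth, noise_sd=0.03, seed=11, first_residue=719)
fitted = fit_r2(decay).set_index("residue")
print(f"median R2 in helix  : {fitted.loc[732:765, 'r2'].median():.1f} /s (truth 35)")
print(f"median R2 in tail   : {fitted.loc[766:, 'r2'].median():.1f} /s (truth 8)")
print("-> high R2 + exchange protection mark the rigid membrane-embedded helix.")
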