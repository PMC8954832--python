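"""DD-SIMCA distances and the acceptance plot for a training library.

Fits the distance model (PCA + score/orthogonal distances), prints the
estimated degrees of freedom and critical full-distance limits, and counts
samples per acceptance zone.  FD ~ chi-squared(Nh + Nq): regular samples sit
inside the green (1 - alpha) limit, outliers beyond the red limit.
"""

import numpy as np

from isolocal import acceptance_coordinates, default_config, fit_ddsimca, generate_library

lib = generate_library(default_config(seed=1))
model = fit_ddsimca(lib, pc=2, alpha=0.05, gamma=0.01)

print(f"SD0 = {model.SD0:.3f}  OD0 = {model.OD0:.3f}")
print(f"degrees of freedom: Nh = {model.Nh}, Nq = {model.Nq}")
print(f"mean training FD = {model.train_FD.mean():.3f} (equals Nh + Nq by construction)")
print(f"regular limit (green): FD <= {model.fd_crit_regular:.2f}")
print(f"outlier limit (red):   FD >  {model.fd_crit_outlier:.2f}")

zones = [z for _, _, z in acceptance_coordinates(model, lib.values)]
for zone in ("regular", "extreme", "outlier"):
    print(f"{zone:>8}: {zones.count(zone):>3} of {len(lib)}")
print(f"\nAbout {100 * (1 - model.alpha):.0f}% of training samples should be "
      "regular if the chi-squared calibration holds.")
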