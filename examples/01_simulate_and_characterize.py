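"""Generate a synthetic lamb isotope library and characterize it.

Draws a 93-sample training-style library at the study conditions (two
classes, four banners), prints per-isotope descriptive statistics and the
Welch t-test between PGI and non-PGI lamb.  Small p-values mean the two
classes carry distinguishable isotope profiles — the premise of the whole
authentication workflow.
"""

from isolocal import characterize, default_config, generate_library

lib = generate_library(default_config(seed=1))
print(f"library: {len(lib)} samples, "
      f"{sum(g == 'PGI' for g in lib.groups)} PGI / "
      f"{sum(g == 'nonPGI' for g in lib.groups)} non-PGI")

report = characterize(lib)
print(f"\n{'isotope':>8} {'mean':>9} {'sd':>7} {'min':>9} {'max':>9} {'p (Welch)':>11}")
for iso in ("d13C", "d15N", "d2H", "d18O"):
    print(f"{iso:>8} {report.mean[iso]:>9.2f} {report.sd[iso]:>7.2f} "
          f"{report.minimum[iso]:>9.2f} {report.maximum[iso]:>9.2f} "
          f"{report.p_value[iso]:>11.2e}")
print("\np < 0.05 on every isotope: the groups differ significantly, "
      "so origin discrimination is feasible.")
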