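"""Recovery coefficients and the log-linear partial-volume model.

For each 1 cm³ cubic well, RC = (measured - background) / known compares
image-measured activity against the well-counter truth.  Across wells, RC
follows RC = a ln(CD x SA) + c with cell density CD (10⁶ cells/mL) and
specific activity SA (kBq/10⁶ cells); inverting the fitted law answers
"how dense must the cells be for full signal recovery?".
"""

import petlimit as pl
from petlimit.recovery import RCModelFit
from petlimit.study import analyze_recovery, quantify_study

wells = quantify_study(pl.generate_study(pl.StudyConfig(seed=1)))
res = analyze_recovery(wells)
obs = res["observations"]

print(f"cubic-well RC range: {obs.rc.min():.2f}-{obs.rc.max():.2f} "
      f"over CD*SA = {(obs.cell_density * obs.specific_activity).min():.3f}"
      f"-{(obs.cell_density * obs.specific_activity).max():.1f} kBq/mL")
print(f"fitted model: RC = {res['slope']:.3f} ln(CD*SA) + {res['intercept']:.3f}"
      f"  (method: {res['fit'].method})")
print(f"per-scanner offsets: "
      + ", ".join(f"{k}: {v:+.3f}" for k, v in res['scanner_offsets'].items()))

# Inverting the published fit RC = 0.11 ln(CD*SA) + 0.57 at full recovery
# (RC = 1) for a specific activity of 5.3 kBq/1e6 cells:
published = RCModelFit(slope=0.11, intercept=0.57)
cd = pl.density_for_rc(published, target_rc=1.0, specific_activity=5.3)
print(f"\ncell density for RC = 1 at SA = 5.3 (published fit): "
      f"{cd:.2f} x 1e6 cells/mL")

# The synthetic study reproduces the direction of the effect (RC rises with
# cell density); the published coefficients give ~9.4e6 cells/mL for full
# recovery at the detection-limit specific activity.
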