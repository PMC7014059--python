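"""The full study: infiltration vs implant-surface contact angle.

Runs the coarse-preset 3 s scenario at all five contact angles
(5, 30, 50, 70, 100 degrees; ~20 min of wall time), then prints the 3 s
mean infiltration table, the stage-average ratio table and the
rate-correlation summary — the package's analogue of the study's
headline analysis.  Equivalent CLI:

    implantflow sweep --angles 5,30,50,70,100 --scale coarse --out runs/sweep
"""

import dataclasses

from implantflow import run_sweep, scaled_scenario

cfg = scaled_scenario(5.0, "coarse")
cfg = dataclasses.replace(cfg, outdir="runs/example_sweep")
report = run_sweep(cfg, [5, 30, 50, 70, 100], progress=True)

print("\n3 s means per contact angle:")
print(report["means"].to_string(index=False,
      float_format=lambda x: f"{x:9.2f}"))
print("\nStage averages as ratios to the 5-degree run:")
print(report["ratio_table"].to_string(index=False,
      float_format=lambda x: f"{x:9.2f}"))
print("\nFibrinogen-rate vs plasma-rate correlation per angle:")
for angle, c in sorted(report["correlations"].items()):
    print(f"  {angle:5.0f} deg: R = {c.R:+.4f}  (p = {c.p_value:.2g}, n = {c.n})")
print("\nHydrophilic surfaces (small angles) draw more fibrinogen and")
print("plasma into the threads; the two rates stay uncorrelated (|R| < 0.5).")
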