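"""Gaussian-kernel KPLS regression of clinical outcomes on the marker panel.

With the generator's optional marker-SPPB linkage switched on, the SPPB
model should achieve a clearly positive cross-validated Q2 while age stays
near zero (markers and age are independent in the generator).
"""

from frailmark import DCVConfig, SyntheticConfig, generate_cohort, run_dcv_regression

table = generate_cohort(SyntheticConfig(sppb_marker_link=0.6), seed=2)
cfg = DCVConfig(repetitions=5, seed=2, lv_grid=(1, 2, 3, 4, 5))

for outcome in ("age", "bmi", "alm", "sppb"):
    res = run_dcv_regression(table, outcome, config=cfg)
    shown = max(res.mean, 0.0)
    print(f"{outcome:>5}: outer-loop Q2 = {res.mean:+.3f} (reported as {shown:.2f})")

print()
print(
    "Q2 is computed from outer-DCV held-out predictions (1 - PRESS/TSS); "
    "values near or below zero mean the marker profile carries no "
    "information about that outcome, as for age/bmi/alm here. The kernel "
    "width is tuned per training fold on a log grid around the median "
    "pairwise distance."
)
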