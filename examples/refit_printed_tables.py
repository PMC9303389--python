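"""Refit the headline kinetic constants from the embedded data tables.

Runs the Bell torque-law fits (with and without RapA), the zero-torque
extrapolations, the barrier-reduction estimate, and both Michaelis-Menten
concentration fits, printing computed values next to the published ones.
"""

from stallkin import barrier_reduction, extrapolate_zero_torque, fit_bell, fit_mm
from stallkin.paper_data import (
    bell_points_no_rapa,
    bell_points_rapa,
    mm_points_atp,
    mm_points_rapa,
)

fit_no = fit_bell(bell_points_no_rapa())
fit_with = fit_bell(bell_points_rapa())

print("Bell torque law: ln k(Gamma) = ln k0 + (theta/kBT)*Gamma")
print(
    f"  without RapA: slope {fit_no.slope:.4f} +/- {fit_no.slope_se:.4f} "
    f"rad/pN*nm  (published 0.11 +/- 0.02), theta ~ {fit_no.theta_deg:.0f} deg"
)
print(
    f"  with RapA:    slope {fit_with.slope:.4f} +/- {fit_with.slope_se:.4f} "
    f"rad/pN*nm  (published 0.09 +/- 0.01), theta ~ {fit_with.theta_deg:.0f} deg"
)
print(
    f"  zero-torque residence: {extrapolate_zero_torque(fit_no):.3g} s without "
    f"(~9e5), {extrapolate_zero_torque(fit_with):.0f} s with (~2800)"
)

red = barrier_reduction(fit_no, fit_with)
print(
    f"  barrier reduction: {red.delta_kbt:.2f} kBT = "
    f"{red.delta_kcal_per_mol:.2f} kcal/mol  (published ~5.8 kBT, ~3.4 kcal/mol)\n"
)

mm_r = fit_mm(mm_points_rapa(), substrate="RapA")
mm_a = fit_mm(mm_points_atp(), substrate="ATP")
print("Michaelis-Menten saturation of the removal rate")
print(
    f"  Km(RapA) = {mm_r.Km:.2f} +/- {mm_r.Km_se:.2f} nM (published 7.2 +/- 0.7), "
    f"kcat = {mm_r.kcat:.2e} s^-1 (published 1.1e-3)"
)
print(f"  Km(ATP)  = {mm_a.Km:.0f} +/- {mm_a.Km_se:.0f} uM (published 160 +/- 35)")

print(
    "\nThe near-identical slopes say the same bubble-rewinding step limits"
    "\ndissociation with and without the enzyme; the ~330-fold drop in the"
    "\nzero-torque residence time is the enzyme's catalytic effect."
)
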