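"""Full-chain consistency check: simulate dwell times, refit the model.

Draws censored residence times at five torques from a known Bell law,
estimates each condition's mean by censored maximum likelihood, refits the
torque dependence, and compares recovered parameters with the truth.
"""

import numpy as np

from stallkin import KineticParams, fit_bell, fit_exponential_mle, simulate_dwells

truth = KineticParams(k0=3e-4, theta0_over_kBT=0.1)
torques = (12.0, 18.0, 22.0, 27.0, 30.0)

print("torque (pN*nm)   true <t> (s)   MLE <t> (s)   n   censored")
points = []
for i, gamma in enumerate(torques):
    true_mean = 1.0 / (truth.k0 * np.exp(truth.theta0_over_kBT * gamma))
    dwells = simulate_dwells(
        truth, gamma, rapa=0.0, atp=0.0, n=200, censor_time=4 * true_mean, seed=40 + i
    )
    fit = fit_exponential_mle(dwells)
    points.append((gamma, fit))
    print(
        f"{gamma:14.0f}   {true_mean:12.0f}   {fit.mean_lifetime:11.0f}"
        f"   {fit.n_events:3d}   {fit.n_censored:8d}"
    )

bell = fit_bell(points)
print(
    f"\nrecovered theta/kBT = {bell.slope:.4f} rad/pN*nm (truth 0.1000), "
    f"k0 = {bell.k0:.2e} s^-1 (truth 3.00e-04)"
)
print(
    "\nEach row simulates one force condition of the force-cycling assay;"
    "\nthe refit recovers the torque sensitivity and the zero-torque rate"
    "\nfrom censored data, validating the whole measurement chain."
)
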