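# stallkin

Kinetic analysis of stalled RNA polymerase removal from supercoiled DNA.

A transcription elongation complex that stalls mid-gene is one of the most
stable road-blocks in molecular biology: on torsionally relaxed DNA the
polymerase stays put for on the order of 10⁶ s. Magnetic-trap experiments
show that positive torque on the DNA accelerates its dissociation, and that
the SWI/SNF-family ATPase RapA catalyses removal — by ratcheting the
polymerase into a backtracked state from which it diffuses off the
template. `stallkin` implements the full measurement and modelling chain of
such experiments for single-molecule biophysicists:

* **mechanics** — torque on plectonemic DNA, Γ = √(2ξ·k_BT·F), with the
  product 2ξ·k_BT calibrated against the experiments' eight printed
  (force, torque) operating points;
* **survival** — censored single-exponential dwell-time estimation
  (total-time-on-test MLE, histogram fit, Wilson removal fractions);
* **inference** — the Bell/Boltzmann torque law
  k_RDe(Γ) = k_RDe(0)·exp(Γθ/k_BT) fitted as OLS of ln k on Γ, zero-torque
  extrapolation, barrier reduction ΔΔG = ln(t₀,₋/t₀,₊), and
  Michaelis–Menten fits k(c) = k_cat·c/(K_m + c) in [RapA] and [ATP];
* **synthetic_traces** — seeded simulation of recycling and force-cycling
  extension-vs-time traces (scrunching ≈ −100 nm, stalling ≈ −50 nm,
  removal back to baseline) and of censored dwell samples;
* **trace_analysis** — median-filter segmentation of noisy traces into
  states and censored dwell extraction;
* **backtrack_model** — first-passage simulation of the ratchet-then-
  diffuse removal mechanism, with exact Markov-chain hitting times as
  oracle;
* **paper_data** — the experiments' four summary tables embedded as
  checksummed TSV fixtures, plus `reproduce_all()`.

## Worked example

```python
from stallkin import barrier_reduction, extrapolate_zero_torque, fit_bell
from stallkin.paper_data import bell_points_no_rapa, bell_points_rapa

fit_no = fit_bell(bell_points_no_rapa())    # 3 torque points, no enzyme
fit_with = fit_bell(bell_points_rapa())     # 5 torque points, 100 nM RapA
print(f"{fit_no.slope:.4f} {fit_with.slope:.4f}")
print(f"{extrapolate_zero_torque(fit_no):.3g} {extrapolate_zero_torque(fit_with):.0f}")
print(f"{barrier_reduction(fit_no, fit_with).delta_kbt:.2f}")
```

prints

```
0.1133 0.0953
9.84e+05 3031
5.78
```

— the torque sensitivities θ/k_BT of dissociation without and with the
enzyme (rad per pN·nm; published as 0.11 ± 0.02 and 0.09 ± 0.01), the
zero-torque residence times in seconds (≈11 days without RapA versus ≈50
minutes with it), and the ≈5.8 k_BT (≈3.4 kcal/mol) by which the enzyme
lowers the dissociation barrier. The near-equality of the two slopes is the
mechanistic punchline: the same transcription-bubble rewinding
(θ ≈ 25°, slightly under one base pair) limits dissociation in both cases.

Longer narrative scripts live in `examples/` — one per capability
(torque calibration, table refits, simulate-and-recover, trace
segmentation, backtracking walk); each prints its numbers with a short
explanation. A thin CLI mirrors the basics:
`stallkin torque --force 0.7 --sign +1`, `stallkin simulate ...`,
`stallkin reproduce-paper`.

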