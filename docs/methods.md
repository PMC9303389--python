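# Methods

## The system and the observable

A single DNA molecule is tethered between a glass surface and a magnetic
bead, held at constant extending force, and over- or under-wound into the
plectonemic regime. RNA polymerase initiates at a promoter on the tether,
stalls at a defined template position (nucleotide starvation at +20/+36, or
a cyclopyrimidine dimer at +83), and eventually dissociates. The observable
is the residence time of the stalled elongation complex (RDe), read from
the DNA extension signal: initiation scrunches ~2 turns of DNA into the
transcription bubble (extension drop ≈100 nm), elongation to the stall site
relaxes part of that (≈50 nm below baseline), and dissociation restores the
baseline. Residence times at a fixed condition are exponential; their mean
⟨t_RDe⟩ gives the dissociation rate k_RDe = 1/⟨t_RDe⟩.

## Torque on plectonemic DNA

For interwound plectonemes at force F the torque is Γ = √(2ξ·k_BT·F), with
ξ the persistence length. Neither ξ nor the temperature entering this
formula is independently pinned down by the experimental description, so the
package treats the product 2ξ·k_BT as a single calibration constant fixed by
grid search against the eight integer (F, Γ) operating points of the
experiments: the feasible interval is [444.08, 451.56) pN²·nm² and the
default is its midpoint, 447.8 pN²·nm² (ξ ≈ 52.6 nm at 307.15 K). Exactness
against the experiments' own operating points was preferred over a textbook
ξ. Reported torques are rounded half-up to integer pN·nm, matching how the
operating points are printed. The square-root law is only claimed in the
plectonemic regime; callers are responsible for staying in it.

Thermodynamic conversions use k_BT at the 34 °C reaction temperature
(4.2587 pN·nm; 0.610 kcal/mol per k_BT). The 298 K factor (0.592) is
exposed as a constant. Note the published θ values (22°, 18°) are not
consistent with slope × k_BT for any single plausible k_BT — 0.1133 rad/pN·nm
× 4.26 pN·nm gives θ ≈ 28°, not 22° — so `BellFit` reports θ from its own
slope and the configured k_BT and does not attempt to reverse-engineer the
original conversion; the discrepancy is deliberate and documented here.

## Dwell-time estimation under censoring

Molecules still bound at the end of observation are right-censored, not
dropped: in the GreB condition roughly half the molecules are never removed
and discarding them would bias the mean low by a factor ~2. The primary
estimator is the censored exponential MLE (total time on test divided by
the number of uncensored events), with analytic SE = mean/√n. A
least-squares fit of A·exp(−t/τ) to the binned histogram (Freedman–Diaconis
by default) is provided for fidelity to how the distributions were
originally summarised; on well-sampled data the two agree within combined
standard errors, and the MLE is used everywhere downstream. An all-censored
set raises `AllCensoredError` carrying the lower bound on the mean.
Removal fractions get Wilson-score 95% intervals.

## Model fits

**Bell law.** ln k_RDe is regressed on Γ by unweighted OLS; the slope is
θ/k_BT (rad per pN·nm) and exp(intercept) the zero-torque rate. Unweighted
OLS is the default because the per-point uncertainties of the printed means
are heterogeneous in a way the original analysis does not appear to weight;
an optional 1/σ² weighting (σ_lnk = SE_t/⟨t⟩ by the delta method) is
available. The barrier reduction is ΔΔG = ln(t₀ without / t₀ with) in k_BT;
with the default conversion this gives 5.78 k_BT = 3.53 kcal/mol (the
published 3.4 kcal/mol corresponds to ≈0.59 kcal/mol per k_BT, i.e. the
298 K factor; both conversions are supported and the k_BT value is the
primary result).

**Michaelis–Menten.** The measured quantity is the lifetime, so the loss is
on ⟨t⟩(c) = (K_m + c)/(k_cat·c), not on the rate; starting values come from
the linearisation ⟨t⟩ vs 1/c and are refined by `scipy.optimize.curve_fit`.
On the embedded concentration series this yields K_m(RapA) = 7.15 nM,
k_cat = 1.02×10⁻³ s⁻¹ and K_m(ATP) = 164 μM.

**Negative torque.** Removal is never observed on negatively supercoiled
DNA, with or without the enzyme. `negative_torque_report` evaluates a
fitted Bell law at Γ = −12 pN·nm purely to expose the contradiction: the
enzymatic fit predicts dissociation in ~10⁴ s there, comparable to the
slower measured lifetimes, yet none occurs — evidence that the bubble's
energy landscape is asymmetric in supercoiling sign. It is a report, never
a fit.

## The synthetic-data generator

`synthetic_traces` is the package's stand-in for raw data. The
single-molecule removal rate composes the two fitted laws
multiplicatively,

k(Γ, c_R, c_A) = k₀·exp(θ₀Γ/k_BT) + k_cat·(c_R/(K_m,R+c_R))·(c_A/(K_m,A+c_A))·exp(θ(Γ−Γ_ref)/k_BT),

with Γ_ref = +12 pN·nm, the torque at which the concentration series were
measured — the minimal joint law that reproduces the torque fit and both
saturation fits simultaneously. The intrinsic and enzymatic pathways carry
separate torque sensitivities (defaults 0.1133 and 0.0953 rad/pN·nm, the
two fitted slopes) because no single slope can reproduce the enzyme-free
torque series, the ~9×10⁵ s relaxed-DNA residence and the ~2800 s
saturating-enzyme extrapolation at once. The rate is identically zero at
negative torque for both pathways (hard zero rather than Bell
extrapolation, per the observation above). Defaults are the fitted
constants: k₀ = 1.02×10⁻⁶ s⁻¹, K_m,R = 7.2 nM, k_cat = 1.1×10⁻³ s⁻¹,
K_m,A = 160 μM.

Trace generation is event-driven: exponential waits for initiation (lumped
binding + promoter escape, default 0.01 s⁻¹, consistent with the ~400 s
low-force hold of the protocol), a scrunched intermediate (default exit
rate 0.1 s⁻¹ — the data constrain only its existence, not its dwell), then
the stalled level until removal. GreB anti-backtracking rescue is modelled
as a competing transition at `greb_rescue_rate` that locks the complex for
the rest of the trace, reproducing the direction of the inhibition (fewer
molecules removed, censored cycles) without claiming its microscopic
mechanism. Gaussian iid noise (default 10 nm at 30 Hz; chosen to make
segmentation non-trivial but reliable, no noise figure being given for the
original data) is added per sample. The force-cycling protocol suppresses
initiation above 0.9 pN (a config threshold, not derived) and maps the
low-force baseline to a fixed 0.75 fraction of the high-force baseline — a
schematic two-level force–extension mapping, deliberately not a worm-like-
chain calculation. Force-cycle dwells are recorded the way the assay
measures them: from the force step to dissociation.

What the generator does **not** emulate: bead Brownian dynamics and camera
blur, drift, the buckling transition and the full rotation–extension curve,
torque-dependent extension changes, and sequence-dependent kinetics. Tests
passing on these synthetics therefore validate the estimators and the
internal consistency of the kinetic laws, not instrument-specific
artefacts.

Every stochastic operation takes an explicit seed and is bit-reproducible
under it.

## Trace segmentation

Median filter (window a free parameter, default 0.5 s), nearest-level
assignment among the three configured extension levels, and merging of runs
shorter than 3 samples to suppress noise flickers. Levels closer than twice
the level tolerance are refused as unresolvable. Dwells are measured from
entry into the stalled level to the return to baseline — the stalled
complex's residence, not the full cycle — and a final unterminated stall is
censored at the trace end. At 5 nm noise and 50 nm level separations the
extracted dwells match the simulator's event log within one sampling
interval.

## Backtracking first-passage model

The removal mechanism is modelled as a continuous-time random walk on
integer template positions: step attempts at `step_rate`, upstream with
probability `bias` (0.5 = unbiased diffusion), a reflecting boundary at the
stall site (downstream attempts there are null events), and absorption —
dissociation — at a promoter-proximal position once the entire RNA has
threaded back. The enzyme's ratchet step is the walk's first upstream move.
Monte-Carlo means are verified against the exact expected hitting times of
the chain (linear solve). The model makes qualitative claims only: mean
removal time grows ≈quadratically with stall-site distance (the observed
superlinearity), degrading the RNA (absorption one step upstream) collapses
the distance dependence, and blocking upstream threading (bias → 0)
lengthens removal enormously, mirroring the oligo-hybridisation experiment.
The step rate is not constrained by the summary data and is left as a free
parameter; no quantitative distance-series reproduction is claimed.

## Embedded tables and reproduction

The four summary tables ship as TSV fixtures, checksummed on load. The
torque-series gradient labels follow the main-text assignment (0.11
without the enzyme from 3 points, 0.09 with it from 5 points); the source
figure legend swaps the two labels, and only the main-text assignment is
consistent with the tabulated lifetimes. Two conditions appear with
slightly different rounding in different tables (983 ± 62 vs 983 ± 61.9;
1732 vs 1730 ± 343); each fixture keeps its own table's verbatim values.
`reproduce_all()` refits all thirteen headline constants and compares them
to the published values at the published uncertainties; its only stochastic
entry (the 289-event simulate-then-refit round trip) is seeded and
deterministic by default.

## Problem sizes

Stochastic checks use n = 200 dwells per condition for parameter-recovery
(slope within 15%, K_m within 30%), n = 1500–2000 walkers for first-passage
comparisons (3 SE), and three 5000 s traces at 30 Hz for the segmentation
round trip — sizes at which the assertions' tolerances are comfortably
resolved while the whole suite runs in seconds.

## Known limitations

* The joint torque×concentration rate law is an interpolation; the original
  experiments fit the two dependences separately and never measured the
  full surface.
* The GreB lock and the scrunched-state dwell are phenomenological
  placeholders with invented rates.
* Histogram fitting ignores censored records (they have no histogram bin);
  it is retained for comparison only.
* θ in degrees depends on the configured k_BT (see the conversion caveat
  above); the slope in rad/pN·nm is the robust quantity.
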