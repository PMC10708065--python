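# Methods

## The model

Solution polycondensation of lactic acid in toluene with a tin-octoate
catalyst and continuous azeotropic water removal is modeled as a reversible
step-growth reaction with chain-length-independent rate constants,

    HO-R_i-COOH + HO-R_j-COOH  <-->  HO-R_{i+j}-COOH + H2O.

Reading the reaction as an exchange between *bonds* rather than molecules
collapses the infinite population balance to three ODEs in the
concentrations of chain-end bond pairs `a` (hydroxyl side; the carboxyl
side is identical by construction), ester bonds `c`, and water `w`:

    dc/dt = k1 a^2 - k_-1 c w
    da/dt = -dc/dt
    dw/dt = dc/dt - kw * xw,        xw = w / (2a + c + w + S + C)

with constant solvent and catalyst concentrations `S`, `C`.  Water leaves
the liquid at a rate proportional to its mole fraction `xw`; the
proportionality coefficient `kw` lumps the vapor-liquid driving force of
the drying loop and is assumed constant, which is strictly valid only
while the water content varies little — in practice it spans a wide range
during the slow-growth period, and the model correspondingly overestimates
Mn there.  The number-average molecular weight is `Mn = (c/a) FW_mono`
(`FW_mono` = 72.06 g/mol): `c/a` is the number-average degree of
polymerization because every molecule carries exactly one `a`-type bond.
As written this undercounts each chain's end monomer; `corrected=True`
switches to `(c/a + 1) FW_mono`.  Both modes are provided because the
plain form is the one the fitted constants were defined with.

Model assumptions, in one place: equal reactivity of all end groups, no
autocatalysis or side reactions, perfect mixing, negligible volatility of
acid and polymer, constant liquid volume, negligible ring formation, and
removal proportional to `xw` with constant `kw`.

An optional stepwise variant emulates entanglement-limited mobility:
whenever the running Mn exceeds `me_threshold` (default 9000 g/mol, the
entanglement molecular weight of PLLA) the polymerization constant is
multiplied by `k1_reduction_factor` (default 0.1), evaluated per step with
no hysteresis — the simplest reading of a stepwise mobility loss.

### Chain-resolved oracle

The full population balance (`placond.chain`) tracks `P_1 .. P_Nmax` and
water explicitly, with combination/scission multiplicities 2 and the
`(i-1)` ester-count weighting.  Aggregating it with `a = sum P_i`,
`c = sum (i-1) P_i`, `w = W` reproduces the condensed right-hand sides
*identically* for the reaction terms (asserted to 1e-10 in tests).  The
two models print different mole-fraction denominators — bond counting
`2a + c + w + S + C` versus molecule counting `S + C + sum P_i + W` —
which differ by the total repeat-unit concentration.  The discrepancy is
inherited from the source formulas and is deliberately *not* harmonized:
each model uses its own form, so removal-on equivalence holds only
approximately, and exact-equivalence tests run closed systems (`kw = 0`).
The same convention clash appears at t = 0: the initial water `w0` is
constructed from the molecule-counting mole fraction (`xw0 =
w0/(S + C + a0 + w0)`, default 1e-5, the upper edge of the "10 ppm or
less" drying regime), and `mass_balance.initial_water_mole_fraction`
inverts exactly that form.

Chains longer than `N_max` (default 256) are dropped; the boundary
occupancy relative to the distribution peak is monitored and runs above
1e-6 are flagged.  The dropped-birth channel also leaks monomer units
(partners are consumed but the long product is never born), so unit
conservation holds to the leak level — with mean DP well below `N_max/2`
the leak is ~1e-20 and conservation is exact to rounding.  The resolved
model is an oracle and the only route to Mw and dispersity; it is not a
production distribution predictor at DP ~ 1e3–1e4.

## Initial-condition ledger

`placond.mass_balance` converts the weighed charge into three bounded
dry-acid masses: the upper bound (residual water removed), an intermediate
value (minus the lactide conversion, treated as inert mass), and a lower
bound counting *effective* moles — acid moles minus the moles of water
released by early oligomerization, which preserves the reactive-bond
budget of the real acid/oligomer mixture.  Concentrations then follow from
the recipe weight ratios and a liquid volume computed from the solvent
mass at a configurable density (default 0.867 g/mL, toluene at room
temperature).  Any fixed volume convention rescales all concentrations
uniformly and is absorbed by the fitted rate constants.  Default molar
masses: lactic acid 90.08, water 18.0, toluene 92.14, tin octoate 405.12
g/mol; all overridable.

## Integrator

Explicit Euler with per-step auto-adaptation: starting from the user base
step (default 1 s) the candidate step is halved until no variable would
change by more than `frac_threshold` (default 10%) of its magnitude, with
an absolute floor (1e-12 mol/L) so near-zero variables do not pin the
step, and a hard minimum step of 1e-10 s — if even that violates the
threshold the step is taken and flagged ("jitter" tolerated).  Samples
record the value computed during the step containing the sample time; no
interpolation.  Variables overshooting below zero are clamped to zero and
counted; a nonpositive chain-end concentration or any non-finite value
marks the run unstable, returned flagged rather than raised because the
fitting penalty path consumes it.  A `max_steps` cap (default 5e7)
guarantees termination when a degenerate right-hand side pins the step at
the minimum.  The condensed-model loop is additionally compiled with
numba; it is the same algorithm as the generic pure-Python path and the
two are asserted to agree to 1e-12.

**Step bias near quasi-equilibrium.**  The fast polymerization-
depolymerization mode has a sub-second relaxation time at the reference
concentrations, so a 1 s Euler step is linearly unstable on it.  The
adaptive threshold bounds the excursion, and the trajectory locks onto a
slightly biased quasi-fixed-point of the step map: at 300 s the default
settings give `c/a = 15.97` whereas step-converged runs (0.1 s and 0.01 s
base steps agree to four digits) give `c/a = 15.31`, consistent with the
analytic quasi-equilibrium value `sqrt(keq) = 15.26`.  Quantities read off
the early transient therefore use a 0.1 s base step.  The bias decays with
the fast-mode rate as conversion proceeds and the 200 h Mn is insensitive
to it (halving the base step changes it by <0.1%).  The same mechanism
makes the least-squares objective *rugged* at default settings — the
attractor position jumps discontinuously with the parameters — which is
why estimation runs use a 1% threshold (below).

## Fitting

The objective is `F = sum_i (Mn_model(t_i) - Mn_obs_i)^2` (Da^2), the
plain absolute sum of squares; unstable trial integrations return a large
penalty (1e6 times the worst finite objective seen, initialized at
`sum Mn_obs^2`).  Minimization is scipy's Nelder–Mead in log10-parameter
space (positivity plus the orders-of-magnitude scale spread), multi-start
with log-uniform draws over k1 in [1e-2, 1e2], keq in [10, 1e4], kw in
[1e-6, 1e-2], and bounded to the box those ranges imply — outside it the
quasi-equilibrium reading of the model breaks down (at k1 below ~1e-2 the
relaxation lag visibly distorts the trajectory shape) and only the penalty
plateau remains.  Convergence uses scipy's simplex criteria with the
function tolerance scaled to the data (`1e-8 * (1 + sum Mn_obs^2)`),
capped at 2000 iterations.  Observation times are hours and converted to
seconds internally, so no factor of 3600 can alias into the constants.

Estimation-grade integrations use a coarser base step (60 s) with a
*tighter* 1% change threshold and a 5e6 step budget: the tight threshold
shrinks the quasi-fixed-point jitter tenfold and smooths the objective
(with the default 10% threshold, Nelder–Mead reliably stalls on ~1%-scale
ruggedness even on noiseless data), the coarse base step keeps an
objective evaluation at ~6 ms, and the step budget prunes pathological
parameter corners.  Synthetic datasets used for recovery studies are
generated with the same settings, so generator and estimator share one
numerical family.

### What is identifiable

Uniform rescaling of `k1` and `k_-1` preserves `keq = k1/k_-1` and leaves
the trajectory nearly unchanged over orders of magnitude: the reaction
stays on the quasi-equilibrium manifold `c w = keq a^2` and only the
removal term `kw xw` drives the slow dynamics.  Fitted `k1`, `k_-1` are
therefore upper bounds along that ray; only `keq` and `kw` are meaningful.
Two desk-scale caveats, both established by this package's own scans and
asserted (one of them as an expected failure) in the test suite:

* On the four-point reference GPC series the *objective* is not flat to 5%
  under 1e-3 uniform scaling (it moves 15–35% depending on the mass
  scenario) even though the Mn trajectories shift by at most ~4%: the
  120 h residual is near zero, so tiny trajectory shifts change F by large
  fractions.  With a dense dataset the flatness statement holds much more
  tightly; with four points it does not.
* Under 5% multiplicative GPC noise (10 points over 200 h), `kw` is
  recovered within 20% in ~9 of 10 replicates, but `keq` lands within 15%
  in only about half: the absolute-squares objective is dominated by the
  late high-Mn points, where `keq` trades off against `kw`.  The landscape
  is also multimodal — a local shelf sits at keq ratios ~1.3–1.5, which is
  why single-start fits from far perturbations can stall and the default
  is multi-start.

## Synthetic data generator

Emulates GPC aliquot series: the condensed model is integrated at known
true constants and each observation is multiplied by an independent
lognormal factor with unit mean and coefficient of variation `noise_cv`
(default 5%, a typical GPC repeatability scale; multiplicative because
calibration errors scale with molecular weight).  Default schedule: 10
evenly spaced aliquots over 120 h (recovery studies use 200 h).  All
randomness flows from a single integer seed.  Not emulated: systematic
polystyrene-calibration bias (a smooth transform of all MWs), correlated
drift between aliquots, low-MW detector censoring.  Passing recovery tests
demonstrate estimator behavior under the stated noise model, not
robustness to those systematics.

## Problem sizes

Reference forward runs: 200 h at 1 s base step (~8e5 adaptive steps,
milliseconds when compiled).  Early-transient quantities: 300 s at 0.1 s
base step.  Chain-resolved oracle comparisons: N_max = 256, keq = 25,
2000 s closed-system runs.  Fitting and recovery: 60 s base step, 1%
threshold, 3 starts, <= 500 simplex iterations per start; the ten-replicate
recovery study completes in a few minutes on one CPU.

## Known limitations

* `kw` constant over a water content that in fact spans decades; the model
  consequently overestimates Mn during the first ~50 h.
* Mn-only: the condensed model cannot produce Mw or dispersity; use the
  chain-resolved oracle at modest DP for those.
* First-order explicit integration: accuracy is threshold-controlled, not
  order-controlled; quantities read near stiff quasi-equilibria need the
  smaller base step (convergence should be checked by step halving, as the
  test suite does).
* No temperature dependence (no Arrhenius layer) and no ring-formation,
  racemization or chain-extension chemistry.
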