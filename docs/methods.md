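# Methods

## Physical setting

A dry rectangular paper strip (length L0 = 6 cm, width L0/8 = 0.75 cm,
datasheet thickness) touches a saliva reservoir at one end. Capillary
suction imbibes the liquid; the visible dyed front is read off at 20,
40, 60, 120, 180 and 240 s. Saliva is treated as Newtonian with the
stimulated-saliva parameters used throughout: ρ = 1000 kg/m³,
μ = 0.002 Pa·s, γ = 0.072 N/m. Air fills the dry pore space
(ρ = 1 kg/m³, μ = 1.76×10⁻⁵ Pa·s). The strip lies horizontally, so
gravity is off by default (a vertical-strip gravity term is housed but
disabled).

Two surface tensions circulate in the source material: 72 mN/m in the
simulation parameter set and 52 mN/m assumed during rheometry. The
presets default to 72 mN/m because that is the value the simulation
targets were produced with; both are selectable.

## Parameters and their provenance

| Symbol | Meaning | CF4 default | Source |
| --- | --- | --- | --- |
| ε_p (por) | porosity | 0.80 | datasheet |
| R_c | capillary radius | 2.25 µm | simulation table |
| p_ec | entry capillary pressure | 47,498 Pa | simulation table |
| λ_p (lp) | pore-size-distribution index | 2 | simulation table |
| θ | contact angle | 42.07° | back-computed (below) |
| k | permeability | calibrated | wicking rate (below) |
| S₀ | initial saliva saturation | 0.01 | stated initial condition |

Quirks handled explicitly:

* **R_c policy.** The published CF4 capillary radius (2.25 µm)
  contradicts the also-published rule "R_c is half the pore diameter"
  (which would give 5.5 µm from the 11 µm pore size). The preset keeps
  the published value; `rc_policy="half_pore"` switches to the rule.
  MF1 and Fusion 5 have no published radius, so both policies halve the
  datasheet pore diameter — the midpoint of the printed 21–181 µm range
  for Fusion 5, since no selection rule is given.
* **Contact angle.** θ is never printed. It is recovered by inverting
  the printed entry-pressure expression: θ = arccos(p_ec R_c / 2γ) =
  42.07°, which makes 2γcosθ/R_c reproduce 47,498 N/m² exactly.
* **Permeability.** No value is printed anywhere. The single
  flow-rate datum available per membrane is the manufacturer wicking
  rate (s per 4 cm), so k is defined as the value that makes the chosen
  model's front reach 4 cm at exactly that time: closed-form inversion
  for Lucas–Washburn, bisection on the solver (time tolerance 0.1 s,
  with a near-exact starting bracket from the fact that the saturation
  equation scales time as 1/k). Anchoring to the datasheet rather than
  to the validation traces keeps the model–experiment comparison a
  prediction, not a fit.
* **Two porosities.** The parameter set lists both por = 0.8 and
  epsilon1 = 0.383 without stating roles; por is used as ε_p and
  epsilon1 is stored unused, as are the two diffusion coefficients
  (D1, D2) whose roles are likewise unstated.

## Lucas–Washburn model

l(t) = sqrt(2 K γ cosθ t^α / (φ μ r_a)) with α = 1 by default. The
printed form of the law is typographically ambiguous about where the
exponent sits; the square-root reading with α on t is implemented, plus
a `classic` textbook variant l = sqrt(γ r_a cosθ t / 2μ) for
sensitivity checks. Absorbed mass is ρ φ W th · min(l(t), L0): the
wetted zone fills completely and uptake saturates at the strip end.

## Two-phase saturation solver

With incompressible phases, S_w + S_n = 1 and Brooks–Corey closure
(p_c = p_ec Se^(−1/λ_p); k_rw = Se^((2+3λ_p)/λ_p);
k_rn = (1−Se)²(1−Se^((2+λ_p)/λ_p))), the phase-transport system reduces
to one scalar equation

    ε_p ∂S/∂t + ∂x(f_w(S) u_T) = ∂x(D(S) ∂x S),

with capillary diffusivity D = k·(λ_w λ_n/λ_t)(−dp_c/dS) and fractional
flow f_w = λ_w/λ_t. Brooks–Corey is used because it is the canonical
closure family parameterized by exactly the two published quantities —
an entry pressure and a pore-size-distribution index — and λ_p = 2 is
applied to both p_c and k_r. Residual saturations default to (0, 0);
S₀ = 0.01 is an initial condition, not a residual.

**Boundary conditions.** The inlet is held at S = 1 (reservoir contact;
reservoir depletion is not modelled). The outlet is open to the
atmosphere for air but impermeable to the liquid, so imbibition is
co-current: the displaced air vents ahead of the front and the total
velocity u_T is nonzero. Integrating the total-velocity Darcy relation
between reservoir (p_w = 0, p_c = p_ec) and outlet (air atmospheric)
gives the quasi-static scalar

    u_T = [p_ec + A(1) − A(S_outlet)] / R,  A(S) = ∫ f_w (−dp_c/dS) dS,
    R = ∫ dx/(k λ_t) + outlet air-path term,

and u_T shuts off automatically once the outlet region saturates and
air connectivity is lost (the strip then simply stays full, matching
the observed end-state saturation).

**Numerics.** Conservative explicit finite volumes, 240 cells over 6 cm
by default. The diffusive flux uses the Kirchhoff transform
K(S) = ∫D dS, discretized by chords: across the sharp imbibition front
D varies by orders of magnitude between neighbouring cells, and an
arithmetic face average would shut the flux off entirely (D(1) = 0 at
the saturated inlet). The advective flux is upwinded. The adaptive time
step enforces the monotonicity bound

    dt ≤ safety · ε_p · Δx / max_i(Dc_l/d_l + Dc_r/d_r + u_T·Lip(f_w)),

(chord diffusivities Dc, center distances d, default safety 0.8), under
which each update is a convex combination of neighbouring values and
the ghost value 1 — saturations stay in [S₀, 1] by construction, with
no clipping, and the discrete mass budget (storage change vs boundary
influx) closes to round-off at every step. The capillary pressure law
is capped below Se = 10⁻⁶ to regularize its divergence; the cap is
never active above the initial saturation. A hard failure triggers if
the step collapses below 10⁻⁹ s or a saturation leaves
[S₀−10⁻⁹, 1+10⁻⁹].

The visible front is the largest x where the linearly interpolated
saturation reaches 0.5 (a dyed front corresponds to substantial, not
marginal, saturation; the threshold is exposed in the config).

**Cross-check.** An independent two-pressure IMPES solver (implicit
tridiagonal pressure solve per step, explicit saturation update, phase
mobilities upwinded by the solved pressures, capillary flux through its
own chord potential ∫k λ_w(−dp_c/dS)dS) reproduces the main solver's
front positions within 3% on a 32-cell grid and conserves mass to
round-off. Grid halving (120→240 cells) moves the 60 s front by well
under 2%, and the log–log front-vs-time slope over 5–60 s is 0.50 —
the √t regime capillary-dominated imbibition must approach.

**Air viscosity.** With the liquid 113× more viscous than air, air is
the secondary phase, but it is not inert in strict 1-D: a tenfold
air-viscosity increase at fixed permeability slows the 60 s front by
roughly 14%, mostly because the total-mobility path through the
partially saturated zone rides on air co-flow. The calibrated pipeline
is insensitive to this (< 5% after re-anchoring to the wicking rate),
and the tests assert both statements separately. A 2-D strip would vent
air through its faces and weaken the fixed-k sensitivity further; that
is beyond this model.

## Model–experiment comparison

Observed front positions are transcribed from the study's running text
only (no figure digitization): all membranes at 2, 3, 4 cm for 20, 40,
60 s and 5 cm at 180 s; Fusion 5 and MF1 additionally 6 cm at 240 s;
CF4 stalled at 5 cm. Metrics are RMSE and maximum absolute/fractional
error at the observed times, with a pass/fail verdict at a default 10%
fractional tolerance — chosen to match the 0.1–0.5 cm run-to-run
scatter the bench traces showed on a 4–6 cm scale, making the study's
qualitative "comparable" claim testable. The verdict is restricted to
the freely wicking regime: once the simulated front has effectively
reached the strip end (99.5% of L0), a saturated model cannot track a
stalled or saturated experimental front, so later points are excluded
from the verdict (they remain in the trace files).

Two experimental observations are documented as outside this model
class rather than targeted: MF1 saturating only at 240 s despite the
fastest datasheet wicking rate, and the reported absorbed-mass scale of
0.7–0.8 g — the entire pore volume of the stated strip geometry holds
only ρ ε_p V ≈ 0.17 g, so those magnitudes are physically inconsistent
with the stated geometry and no mass fixtures are shipped.

## Synthetic data generator

The generator emulates the structure of the bench measurements so the
pipeline is testable end-to-end:

* **Front readings** — additive zero-mean Gaussian noise (default sd
  2 mm, consistent with the reported 0.1–0.5 cm oscillations), rounded
  to a millimetre ruler grid and clamped to [0, L0].
* **Analyte profiles** — per-1-cm-segment concentrations as a
  deterministic piecewise mean times unit-mean lognormal noise (default
  cv 10%). DNA means are pinned to the stated values: 400 ng/µL over
  the first 2 cm for CF4 and Fusion 5, a 700 ng/µL peak at the 5 cm
  segment of CF4, and at most 200 ng/µL over the first 4 cm of MF1
  (never reaching 400). No capture/elution mechanism is modelled — none
  is defined by the study — so the generator is explicitly
  phenomenological. RNA and protein levels are never printed; they are
  generated as scaled copies of the DNA profile (MF1-favoring, and
  stimulated saliva favored for RNA, matching the qualitative account)
  and flagged as unanchored.
* **Viscosity series** — 21 points (one per minute) around 2.00 mPa·s
  (stimulated) or 2.34 mPa·s (unstimulated) with multiplicative noise.

What passing tests on synthetic data do **not** show: anything about
shear-thinning rheology, pore clogging by saliva solids, evaporation,
or membrane surface chemistry — all absent from both the generator and
the transport models.

## Problem sizes in the test suite

Solver tests run at 32–120 cells with 240-cell runs reserved for the
front-prediction and grid-convergence checks; Monte-Carlo generator
checks use 10⁴ replicates of a single reading and 200 seeds for the
√t-coefficient recovery (median relative error ≈ 2% against the 5%
requirement). The full suite completes in well under a minute.

## Known limitations

* Strict 1-D: no transverse flow, no face venting of air, no 2-D strip
  geometry.
* Reservoir treated as infinite (a 100 µL reservoir against a ≈ 170 µL
  pore volume is not checked by default).
* Newtonian saliva; the measured shear-thinning is deliberately outside
  the model, as it is outside the source models.
* The Lucas–Washburn exponent reading (α on t) is one of two plausible
  interpretations of an ambiguously printed formula; the alternative
  attaches α to the pore radius and is equivalent at α = 1.
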