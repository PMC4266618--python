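# Methods

## Model

The simulator implements a go-or-grow model of glioblastoma on a 2-D grid.
Proliferative cells `P` divide and do not move; invasive cells `I` move and
do not divide; healthy brain `B` is passive; necrotic material `N`
accumulates dead cells of all three living types and is never cleared.
All densities are fractions of a shared carrying capacity, so the total
density `C = P + I + B + N` is dimensionless, as are lengths (grid-cell
edges) and times (solver steps × `dt`).

Oxygen supply is represented implicitly by the hypoxic state
`H = clamp(C/C_ref, 0, 1)`: crowding consumes oxygen, and dead material
still occupies space, so necrosis does **not** relieve the hypoxia that
caused it.  This one assumption drives most of the model's qualitative
behaviour, including growth-by-expanding-necrosis under anti-angiogenic
(AA) therapy.

Two spatially varying threshold fields of `H` organise the local kinetics.
Below `τ_h` tissue is normoxic: mitosis runs at `M_max`, invasive cells
revert to the proliferative phenotype at `β_IP`.  Between `τ_h` and `τ_l`
mitosis decays reciprocally (`M = M_max·τ_h/H`) and the P→I switch ramps up
linearly, reaching `β_PI` at `H = 1`.  Above `τ_l` rapid necrosis is
activated: every living compartment dies at `μ_max`, and mitosis stops.

Two shape decisions deserve emphasis because the obvious alternatives
silently break the dynamics:

* **Mitosis must stay positive up to and including `τ_l`** (the default
  `inverse` form).  A ramp that tends continuously to zero *at* `τ_l`
  (available as `mitotic_form="linear"`) makes the density approach the
  lethal threshold asymptotically from below, so no cell ever crosses it
  and necrosis never starts anywhere, at any parameter values: the model
  loses its necrotic core entirely.
* **Death must be a step, not a graded ramp** (the default `step` form).
  Because dead mass stays in `C`, the excess of `H` over `τ_l` after a
  crossing is a few times the Euler increment (~1e-3) and never grows.  A
  death rate proportional to that excess (available as
  `necrotic_form="linear"`) therefore kills tissue at a vanishing rate and
  the 90 %-brain-death criterion that defines the necrotic region is
  practically never met.  With the step form, crossing the lethal
  threshold kills the site over a timescale `1/μ_max`.

Angiogenesis raises both thresholds toward ceilings
(`dτ/dt = α·P·(τ_cap − τ)`), wherever proliferative cells are present —
a vascularised tumour tolerates a higher density before dying.  AA therapy
zeroes this term and (by default instantly; `relax_rate` configurable)
resets the thresholds to the avascular baselines.  The treatment protocol
re-enables angiogenesis when AA is lifted, which re-opens the gap between
`H` and `τ_l` over the whole tumour and produces the characteristic
rebound of proliferative mass.

Invasive-cell transport is by conservative finite-volume operators:
five-point flux-form diffusion with harmonic-mean face conductances (which
makes the zero-flux condition at skin/bone and at the necrotic core exact),
and donor-cell upwind advection with face velocity `γ·ΔB/h` toward higher
brain density.  Upwinding trades spatial accuracy for guaranteed
positivity and mass conservation, both of which are asserted to 1e-10
relative per step in the tests.  The operator order within a step is
reaction → threshold update → active transport → passive diffusion;
splitting differences are O(dt) and far below the tolerances the tests
probe.  The explicit time step is validated against
`0.9·min(h²/4D_max, h/(γ|∇B|_max))` at run start, and each transport
operator re-checks its own CFL bound per call.

## Parameters

All kinetic values are free parameters of the model family.  The defaults
were fixed once, as a set, so that the untreated model on the default
127×127 phantom develops the full natural history — seed → exponential
growth → hypoxic switching → necrotic core with proliferative rim and
invasive margin — within a 5000-step run, with all tissue initially
normoxic (`H(B0) = 0.5 < τ_h0 = 0.7`):

| parameter | default | meaning / rationale |
|---|---|---|
| `M_max` | 0.2 | mitotic rate; sets the basic clock (doubling ≈ 35 steps) |
| `μ_max` | 0.12 | death rate past `τ_l`; slow enough that the necrotic edge trails the proliferative rim, fast enough to complete 90 % brain death behind the front |
| `β_PI` | 0.2 | P→I switch scale; feeds the invasive wave |
| `β_IP` | 0.005 | I→P reversion in normoxia; small values keep the invasive margin ahead of the rim |
| `D0`, `κ_wm` | 0.015, 1.3 | passive diffusion, white-matter speed-up |
| `γ` | 1.8 | active transport coefficient |
| `α` | 2.0 | angiogenic threshold-rise rate; large enough that a vascularised rim reaches its ceilings before the density catches up |
| `τ_h0`, `τ_l0` | 0.7, 0.85 | avascular thresholds |
| `τ_h_cap`, `τ_l_cap` | 0.9, 0.97 | vascular ceilings |
| `B0`, `C_ref` | 0.5, 1.0 | initial brain density, crowding scale |
| `p_seed`, `i_seed` | 1e-2, 1e-3 | single-cell initial tumour |
| `dt` | 0.1 | explicit step; comfortably inside the stability bound at the defaults |

Readout conventions: a grid cell is *necrotic* when ≥ 90 % of its initial
brain density has died, *invaded* when `I ≥ 1e-4`, *proliferating* when
`P ≥ 1e-2`; percentages are over the full brain mask, including its
necrotic part.  The virtual-MRI map uses `P ≥ 0.1` for the enhancing rim
(a display choice, config-exposed; no quantitative claim attaches to it).
Layer radii are measured from the seed cell: the largest radius of any
necrotic cell, and the radii of the azimuthally averaged P and I peaks.

## Treatment scenarios

`full` never applies AA; `aa` applies it from step 0; `treatment` applies
it on [2500, 3500) and lifts it; `normalization` multiplies `α` by
`boost_factor` (default 2) for `boost_window` steps (default 500) from AA
start before AA takes hold, emulating a transient vascular-normalisation
window.  The 500-step default was chosen because the window must be long
enough for the extra vascularised growth to leave a measurable imprint on
the final necrosis and invasive mass; a much shorter window is
indistinguishable from plain AA by the end of a 5000-step run.

## Matched-mass AT-vs-PD comparison

To compare the two migration mechanisms at equal tumour burden, the
AT-only model (`D0 = 0`) at the default `γ` provides the reference final
proliferative mass and `D0` of the PD-only model (`γ = 0`) is bisected
until its final P mass matches within 5 %.  Bisection is valid because
final P mass responds monotonically to either transport coefficient up to
domain saturation (asserted on 3-point grids in the tests); the search is
capped at the largest coefficient the configured `dt` integrates stably.
The comparison is run on a 64×64 phantom at 3700 steps — late in the
tumour's course, when the active-transport ring's historically larger
footprint has converted into necrosis.  At earlier horizons the PD wave's
kill-trail is still ahead on percent necrosis even though the AT tumour
already leads on invasion; after ~4000 steps the 64×64 domain saturates
and the comparison degenerates.  The treatment-mode variant scales the AA
window proportionally ([1850, 2590)).

## Sensitivity sweep

The default sweep varies four parameter pairs (`β_PI`/`β_IP`, `γ`/`D0`,
`M_max`/`μ_max`, `α`/`τ_h0`) over 3-point grids spanning ×¼–×4 around the
defaults (thresholds move additively within their admissible range), on a
64×64 phantom for 1500 steps — 36 runs, ~25 s.  Failed runs (e.g. a grid
point violating the stability bound) keep their row with an error flag.
The necrosis–invasion association is the Spearman rank correlation over
the sweep rows, ties mid-ranked.

## Synthetic data

The **brain phantom** is an ellipse (30–70 % of the grid) with an
impermeable rim and 2–4 sinusoidal white-matter bands, fully determined by
a seed.  It reproduces the geometric features the model needs — a closed
domain, anisotropic fast tracks, anatomically plausible proportions — but
not real anatomy: no ventricles, no grey/white boundary geometry, no
hemispheric asymmetry.  Results that depend on real tract topology
(e.g. patient-specific invasion routes) are outside what passing tests
demonstrate.

The **synthetic cohort** emulates the *structure* of a recurrent-GBM
series: two groups (11 with, 12 without expanding necrosis at default
n = 23) with exponential progression-free-survival times of means 178 and
333 days respectively, ~20 % censoring, and lesion diameter triples
(tumour, necrosis, FLAIR) in which the necrosis area and the
(FLAIR − tumour) area share a positive log-scale association contaminated
with heavy-tailed outliers (15 % of records get 3×-amplified noise).  It
contains no real patient measurements; only the published group sizes,
mean PFS values and the printed age table are carried as constants.

## Clinical statistics

Lesion areas are bidimensional products of perpendicular diameters;
the invasion proxy is FLAIR area minus tumour area, clipped at zero with a
warning.  The robust polynomial fit minimises the sum of absolute
residuals by iteratively reweighted least squares (weights
`1/max(|r|, 1e-6)`, ≤ 100 iterations, stop when coefficients move < 1e-9).
Near the L1 optimum the iteration can oscillate at ~1e-7 amplitude, in
which case the last iterate is returned with a warning — the coefficients
are still accurate to far better than the measurement noise.  Default
degree is 1 (config-exposed).  Kaplan–Meier curves and the log-rank test
delegate to `lifelines`; subjects censored at an event time remain in the
risk set at that time.  The tests pin these against hand-computed
product-limit tables and an independent two-pass log-rank implementation.

## Known limitations

* 2-D only; an explicit solver (no implicit or adaptive stepping).
* Angiogenesis is implicit (threshold dynamics); no oxygen field, vessel
  network, or VEGF kinetics — so drug pharmacokinetics cannot be
  represented beyond on/off windows and the `α` boost.
* The necrotic region is absorbing for transport only once 90 % of local
  brain has died; partial necrosis does not yet impede migration.
* Percent invasion counts cells by a fixed density cutoff (1e-4), which
  makes diffusion tails and advection piles count equally; conclusions
  that depend on the *distribution* of I below that cutoff are not
  testable readouts.
* The matched-mass comparison is horizon- and domain-size-dependent
  (see above); the packaged study conditions state one defensible choice
  rather than a universal result.
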