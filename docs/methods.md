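# Methods

`radfrac` couples three models: an agent-based tumor-growth simulator on a
2D lattice, a radiation-response layer built on the linear–quadratic (LQ)
survival model, and an outcome layer that scores organ-at-risk (OAR) damage
with dose–volume histograms (DVH), generalized equivalent uniform dose
(gEUD) and the Lyman–Kutcher–Burman (LKB) complication model.  A tabular
SARSA agent chooses the daily dose of a hypofractionated schedule inside
this environment.  This note records the model equations, every tunable
that matters, the design choices made where the design was genuinely open,
and what the defaults do and do not represent.

## 1. Tumor growth model

The tissue is a 50×50 lattice.  Each pixel carries a glucose store (mg), an
oxygen store (mL), and any number of cells; healthy and cancer cells can
share a pixel.  At initialization 1000 healthy cells are scattered
uniformly at random, a single cancer cell sits at the central pixel, 100
nutrient-source pixels are drawn without replacement, and both nutrient
fields start uniform at 1e−6 per pixel.

Cells transit the mitotic cycle G1 (11 h) → S (8 h) → G2 (4 h) → M (1 h)
and divide after mitosis, so an unconstrained cell doubles every 24 h.
Each cell draws individual metabolic efficiencies at birth (normal
distributions, redrawn until positive): glucose absorption
N(3.6e−8, 1.2e−8) mg/cell/h for healthy and N(5.4e−8, 1.8e−8) for cancer
cells; oxygen consumption N(2.16e−8, 0.72e−8) mL/cell/h for both.

One simulated hour applies, in fixed order:

1. **Replenishment** — each source pixel gains `source_glucose_rate` and
   `source_oxygen_rate`.
2. **Diffusion** — one explicit 4-neighbour averaging step with mixing
   fraction `diffusion_fraction` and zero-flux boundaries.
3. **Consumption** — every cell demands its own efficiency (quiescent cells
   a fraction `quiescent_consumption_factor` of it); an under-stocked pixel
   is split pro rata by demand.
4. **Starvation and quiescence** — decisions use the per-cell *share* of
   the pre-consumption pixel store.  A pixel whose population exceeds what
   the store can sustain at the critical thresholds (3.88e−8 mL oxygen,
   6.48e−8 mg glucose per cell) loses the excess cells; within a contested
   pixel the cells with the lowest glucose uptake starve first, so cancer
   cells — drawing more avidly — displace healthy cells they have engulfed.
   Cells whose share falls below the quiescence threshold (1.037e−7 mL
   oxygen per cell) arrest reversibly and stop cycling.  The literature
   glucose quiescence level (1.728e−8) lies *below* the glucose death
   level, which would make the band unreachable; the effective quiescence
   threshold is therefore `max(quiescent, critical)` per nutrient, so in
   practice quiescence is oxygen-driven.
5. **Cycle and division** — non-quiescent cells advance their phase clock;
   a cell finishing M produces a daughter in the same pixel if the local
   density allows, otherwise in the least-crowded von-Neumann neighbour
   (ties broken by the grid's seeded generator).  Cancer cells divide up to
   `density_cap` (40) cells per pixel; healthy tissue is contact-inhibited
   at `healthy_density_cap` (2) per pixel, the standard
   cellular-automaton distinction that lets a tumor overgrow its host
   tissue.  If parent and all neighbours are full the division is skipped
   and the parent re-enters G1.  Concurrent placements into one pixel are
   capped at its free slots.

The growth phase ends when the cancer population first reaches 9000 cells;
the treatment clock then starts at zero.  Endpoints: *success* when no
cancer cell remains (checked with precedence), *failure* when fewer than 10
healthy cells remain, *timeout* past 1200 h of treatment.

**Emergent treatment-start state.**  Under the defaults the tumor reaches
the threshold after ≈740 h as a compact blob of radius ≈14 px holding
≈9450 cancer cells, embedded in ≈4480 healthy cells (the 2/px contact-
inhibition ceiling of 5000 minus the cells the tumor displaced), with a
hypoxic, partially quiescent core.

## 2. Radiation response

Survival of a cell receiving dose D follows the oxygen-modified LQ model

    SF(D) = exp[ γ_r (−α·OMF·D − β·(OMF·D)²) ],

with per-site (α, β) pairs for tumor and normal tissue (rectum
0.315/0.0662 vs 0.0484/0.0124; head-and-neck 0.330/0.029 vs 0.0341/0.0114;
lung 0.325/0.0325 vs 0.0637/0.0168; tumor α/β ≈ 10, normal ≈ 3) and
γ_r = 1 by default.  Each cell dies independently with probability 1 − SF
at its pixel's dose and oxygenation (one uniform variate per cell).

**Oxygen-modifying factor.**  The OMF form is not pinned down by the model
tables, so a saturating rational curve is used,
`OMF(p) = (OER_max·p + K)/(p + K)/OER_max`, with OER_max = 3 (the classical
maximum oxygen-enhancement ratio) and half-saturation K = `omf_halfsat`.
The input p is the cell's per-pixel oxygen share.  K = 5.5e−7 mL/cell
places the tumor core (shares ≈ 6e−7–1e−6 under the defaults) at OMF ≈
0.75–0.82, which reproduces the observed single-fraction response
(§5); far-field tissue at mL-scale shares saturates to OMF ≈ 1.

**Beam geometry.**  The plan is made once, at treatment start, like the
masks: the field is centered on the cancer centroid, delivers the nominal
dose over a disc covering *every* cancer-occupied pixel plus
`beam_margin` (0.25 px), and falls off as a Gaussian penumbra of scale
`beam_sigma` (4.2 px) beyond.  A flat field with a penumbra — rather than a
single broad Gaussian — is what keeps every tumor cell at the prescribed
dose while still exposing the near OAR, and is the closest 2D analogue of
a conformal plan.  Because the flat disc covers the full initial tumor
extent, the tumor cannot outgrow the field during a course.

**Mitotic delay.**  Surviving cells suffer radiation-induced cycle arrest:
the phase clock is set back by `arrest_hours_per_damage` hours per unit of
LQ log-kill (α·D_eff + β·D_eff²) they sustained.  Damage-proportional
arrest is standard radiobiology (G2/M arrest grows with dose and with
radiosensitivity) and is what sets the effective daily regrowth factor
between fractions: without it every surviving cell divides within 24 h and
no conventional schedule can eradicate the tumor within the 50-day limit.
The default, 13 h per unit log-kill, gives a 1.8 Gy fraction ≈7–9 h of
arrest (regrowth ≈×1.5/day) and a 4 Gy fraction ≈21–26 h (regrowth ≈×1),
which reproduces both the ≈28-fraction conventional course and the
≈8-fraction learned course.

## 3. Outcome model

The target volume (TV) is the cancer-occupancy mask at treatment start
dilated by two pixels (two passes of a 3×3 structuring element, i.e.
Chebyshev radius 2); the OAR is its complement.  Both masks are frozen for
the course.  Dose is accumulated per pixel over all fractions.

The cumulative DVH of the OAR bins the accumulated dose at
`dvh_bin_width` (0.27 Gy) resolution; `volume_fraction[i]` is the fraction
of OAR pixels receiving at least `bin_edges[i]`.

**gEUD.**  `geud(dvh, n)` evaluates `(Σ_i V_i · D_i^{1/n})^n` in log space
(1/n reaches 100 for n = 0.01).  Two conventions for V_i are provided:

- *differential* (the function's default): V_i is the volume fraction in
  bin i, giving the textbook volume-weighted power mean — equal to D for a
  uniform dose and to the mean dose at n = 1;
- *cumulative* (the reporting pipeline's default, `OutcomeConfig`): V_i is
  the cumulative ordinate itself, summed over all bins.  This convention
  treats the cumulative histogram as the weight, grows with histogram
  resolution, and can exceed the maximum dose.  The treatment-assessment
  pipeline uses it because the complication probabilities it reports are
  then on the scale of the complication probabilities reported for
  this class of in-silico models;
  with the differential convention the same treatments score one to two
  orders of magnitude lower NTCP (gEUD can never exceed the ≈51 Gy total
  dose, which the rectal TD50 of 80 Gy renders negligible).  Both
  conventions are tested; the choice is a single config switch.

**NTCP.**  The Lyman model maps the OAR gEUD through the standard normal
CDF at τ = (gEUD − TD50)/(m·TD50), evaluated with `scipy.special.ndtr`.
Endpoint parameters: rectal bleeding (TD50 80.10 Gy, m 0.150, n 0.15),
xerostomia (40.28, 0.408, 0.01), symptomatic pneumonitis (29.88, 0.400,
0.15).  The small volume-effect parameters weight hotspots heavily.

## 4. Decision process and the SARSA agent

The agent observes the grid every 24 h as the pair (healthy count, cancer
count) and picks a dose from {1, 2, 3, 4} Gy.  Counts are binned: healthy
in steps of 500 (25 bins), cancer on a near-logarithmic grid {0 | 1–10 |
11–100 | 101–500 | 501–1000 | 1000-wide steps to 20 000}, with a dedicated
bin for eradication.  The Q-table updates on-policy,

    Q(s,a) ← Q(s,a) + η [ r + γ Q(s',a') − Q(s,a) ],

with η = 0.1, γ = 0.99, and ε-greedy exploration decaying linearly from
1.0 to 0.05 over the first 70% of episodes.

**Reward.**  Each decision window scores

    r_k = −d_k/400 + (c_k − 5 h_k)/100 000,

where d_k is the dose and c_k, h_k are the cancer and healthy cells lost
over the window — measured as the net decrease of the observable counts
between decisions, clamped at zero, since the counts are precisely the
agent's state.  At episode end a terminal outcome reward is added: +1 for
eradication, −1 for healthy-tissue collapse, 0 for timeout.  The unit
terminal scale puts episode returns on a [0, 1] scale and is what makes
eradication dominant: with per-step kill rewards alone, the optimal policy
in this environment is to *farm* the tumor — hold it at equilibrium with
low doses and harvest the kill reward from regrowth indefinitely — a
degenerate optimum that tabular SARSA reliably finds.  The success bonus
prices the value of actually ending the disease; the per-step terms then
shape *how* the agent gets there (hit hard early, spare healthy tissue,
stop quickly).

**Training.**  Growing a tumor to the threshold dominates episode cost, so
training samples starting grids from a pre-grown pool (default 16;
each draw gets a fresh random stream).  Evaluation arms always grow fresh
replicates.  An optional training-only fraction-count horizon exists but
is off by default.  Learned tables are persisted as JSON together with
their binning specification, and evaluation refuses a table whose binning
differs from the runtime configuration.

Typical learned behaviour on the rectum environment: 4 Gy first (the
response is largest while the tumor is bulky), 3 Gy through the mid
course, higher doses again to finish — eradicating in ≈7 fractions and
≈23 Gy, versus ≈28 fractions and ≈51 Gy for the 1.8 Gy conventional
schedule, with OAR complication probability near zero versus ≈10–12%.

## 5. Calibration of the open constants

The model family this simulator belongs to fixes the biology constants
(§1–§3) but leaves the transport, beam and histogram-resolution
constants open.  These were calibrated — as the package's own study
conditions, fixed once — so that the default configuration reproduces the
reference statistics of this model family:

| constant | default | what it was set by |
|---|---|---|
| `source_oxygen_rate` | 3.6e−6 mL/source/h | treatment-start populations (≈4200 healthy, ≈9500 cancer) and a compact tumor |
| `source_glucose_rate` | 6.0e−6 mg/source/h | glucose never the binding global constraint; local competition only |
| `diffusion_fraction` | 0.6 | nutrient penetration into the tumor core (compactness) |
| `density_cap` / `healthy_density_cap` | 40 / 2 | tumor blob radius ≈14 px; healthy ceiling ≈5000 |
| `quiescent_consumption_factor` | 0.9 | hypoxic-core churn and post-fraction wake-up rate |
| `omf_halfsat` | 5.5e−7 mL/cell | ≈80% cancer kill by the first 4 Gy fraction |
| `beam_margin`, `beam_sigma` | 0.25 px, 4.2 px | ≈12% first-fraction healthy kill and the OAR complication levels |
| `arrest_hours_per_damage` | 13 h | ≈28-fraction conventional rectum course |
| `dvh_bin_width` | 0.27 Gy | rectal-bleeding NTCP scale under the cumulative gEUD convention |

One deliberate compromise: with a single arrest constant and a single beam
shared across sites, centering the rectum schedule (fraction count and
rectal-bleeding NTCP both at their reference means) leaves the
head-and-neck complication probability ≈2 points below its reference mean
(≈78 vs 80.4); no shared setting puts every site statistic at its exact
reference value simultaneously.

## 6. What the simulator does and does not represent

The generator emulates avascular 2D tumor growth with nutrient
competition, hypoxia, contact inhibition and stochastic radiation kill —
enough structure for fractionation *scheduling* questions: relative kill
per fraction, regrowth between fractions, collateral dose to surrounding
tissue, and outcome scoring.  It does **not** represent: 3D geometry and
volumetric dose deposition, vasculature or angiogenesis (sources are
static), intracellular signalling, immune response, cell migration,
sub-pixel dose physics (the beam is a planar idealization), or clinically
calibrated absolute time/dose scales beyond the constants listed above.
Passing tests therefore demonstrate internal consistency of the models and
reproduction of the reference in-silico statistics — not clinical validity.

## 7. Numerical and reproducibility notes

- Every stochastic component draws from a single `numpy` Generator owned
  by the grid, seeded at initialization; trajectories are bit-reproducible
  and replicate seeds are `base_seed + index`.
- Diffusion uses edge-padded neighbour averaging (zero-flux); fields are
  clipped non-negative by construction (consumption subtracts at most the
  store).
- gEUD sums are evaluated with `logsumexp`; NTCP uses the exact normal CDF
  rather than quadrature.
- Degenerate growth replicates (tumor dies out before the threshold)
  raise and are retried on a derived seed by the environment; they are
  rare (<1%) at the defaults.
- Division tie-breaks add sub-unit random jitter to integer densities, so
  ties are uniform without disturbing strict orderings.
- Test-suite problem sizes are desk-scale by design: 20 growth replicates,
  20 baselines per site, 800 training episodes from a 12-grid pool; the
  acceptance script uses 100 replicates per statistic.  Statistics at
  these sizes sit well inside the tolerances asserted.

## 8. Known limitations

- The per-pixel nutrient shares, not gradients within a pixel, drive
  starvation/quiescence; pixel scale is phenomenological.
- The cumulative gEUD convention is a reporting convention (§3); absolute
  NTCP values depend on the DVH bin width under it.
- SARSA with tabular counts-only state cannot see spatial structure
  (e.g. hypoxic-fraction differences between equally sized tumors).
- The healthy-tissue economy (contact inhibition at 2/px, fast
  repopulation) is the simplest one that yields a stable host tissue; real
  normal-tissue kinetics are slower and organ-specific.
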