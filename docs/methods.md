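# Methods

## The model

`adcycle` simulates a single neuron as a well-mixed, discrete mass-action
reaction network coupling four modules into one positive-feedback cycle:

1. **p53/Mdm2 turnover.** p53 is synthesised at a basal rate, binds the E3
   ligase Mdm2, is ubiquitinated while bound, and the ubiquitinated form is
   degraded by the proteasome. Unstressed, the total p53 pool sits at a few
   tens of copies.
2. **ROS and the DNA-damage response.** Reactive oxygen species (ROS) are
   generated basally (negligibly, by default) and by soluble amyloid-beta;
   ROS generate DNA lesions (`damDNA`), which are repaired at a first-order
   rate. Lesions drive p53 phosphorylation; phospho-p53 cannot bind Mdm2,
   so damage converts p53 from a fast-degrading to a stable, active pool.
3. **GSK3beta.** Activated (phosphorylated) p53 binds GSK3beta; the
   `GSK3b_p53` complex is the activity-carrying species: it is a modifier
   of tau phosphorylation, of amplified Abeta production, and of further
   p53 synthesis (binding raises the activity of both partners). The
   GSK3beta pool is finite (20 copies), so complex-driven fluxes saturate.
4. **Abeta and tau aggregation.** Abeta monomers are produced basally and,
   much more strongly, under GSK3b_p53/phospho-p53 drive; monomers are
   cleared at a first-order rate (the intervention target), pair into
   oligomers, and oligomer pairs deposit as plaques. Tau is phosphorylated
   under GSK3b_p53 drive, dephosphorylated at a first-order rate, and
   three phospho-tau form an irreversible tangle.

The loop Abeta → ROS → damDNA → p53 → GSK3b_p53 → Abeta has multiple entry
points. Under default conditions a cell enters it through a single
stochastic event: the chance encounter of two soluble monomers forming a
persistent oligomer. Oligomers are the ROS-potent soluble species (their
monomer counterpart's ROS coupling is negligible), so one oligomer starts
a lesion–p53–Abeta cascade that raises the monomer level and makes further
nucleation almost certain — ignition. Cells that happen not to nucleate an
oligomer within the 12-day horizon stay clean, which reproduces the
observed minority of pathology-free cells.

## Simulation algorithm

Exact stochastic simulation by the Gillespie **direct method**: the
waiting time is exponential in the total propensity and the next reaction
is chosen proportionally to its propensity. Propensities use the discrete
combinatoric convention — a reactant with stoichiometry *s* and copy
number *n* contributes C(*n*, *s*) (so *n*(*n*−1)/2 for a pair), and each
modifier multiplies the propensity by its copy number; a zero-copy
modifier silences the channel.

**Timed events** (the intervention mechanism) interrupt the waiting time:
if the sampled jump would pass the next event's fire time, no reaction
fires — the clock moves to the event, the parameter change (set or
multiply) is applied, and a fresh waiting time is drawn. Discarding the
partially elapsed exponential is exact by memorylessness, and the
parameter jump invalidates the old rate anyway.

**Recording** is piecewise-constant on a fixed grid (default step 0.05
day, ~241 points over 12 days): the value at grid time *t* is the state
after the last change at or before *t*; when an event coincides with a
grid point the post-event state is sampled. First-passage times to the
first plaque and first tangle are recorded at the exact reaction time,
not on the grid.

**Randomness.** One PCG64 generator per trajectory, seeded explicitly;
ensemble run *i* uses `base_seed + i`. Identical (model, seed, grid step)
triples give bit-identical trajectories, including across event firings.

## Parameterisation

The underlying publication of this model family does not print its rate
constants, so the defaults here are an in-code calibration to the reported
ensemble phenotypes rather than measured values. All rates are per day
(first order) or per molecule per day (second order); every value can be
overridden via `build_default_network(overrides=...)`, a YAML parameter
file on the CLI, or the SBML interface. The calibration targets, all
asserted by the test suite, are:

* a majority of unperturbed cells accumulate both plaques and tangles by
  day 12, while a nonzero minority accumulate neither;
* tangles precede plaques in the ensemble median;
* with Abeta production raised to its elevated calibration value (15×
  basal), the median first-aggregate time is within ~2–3 days;
* a 100-fold clearance boost at day 0 prevents all plaques and tangles
  and leaves total p53 at basal levels (no cell death against thresholds
  near 600);
* interventions at day 6/8 lower plaques but leave end-of-run tangle
  levels statistically indistinguishable from no intervention;
* zeroing Abeta-mediated ROS production (with a day-8 clearance boost)
  keeps damDNA, GSK3b_p53, plaques and tangles near zero;
* zeroing GSK3beta/p53 binding prevents plaques and tangles even though
  p53 still rises;
* percent-viable curves ordered day 0 ≥ 2 ≥ 4 ≥ 6 ≥ 8 ≥ none, with day 8
  giving little improvement over no intervention.

Structural choices that carry these behaviours:

* **Trimolecular tangle nucleation** (3 phospho-tau). A lone DNA lesion
  in an otherwise protected cell produces only one or two simultaneous
  phospho-tau and therefore cannot seed a tangle, while the ignited state
  (tens of phospho-tau) forms tangles within a day. Plaques are likewise
  gated twice (monomer pair → oligomer, oligomer pair → plaque).
* **Oligomers are the ROS-toxic soluble species.** Monomer-linked and
  basal ROS production are negligible by default, so the protected
  (day-0 boost) condition, whose residual monomer level is ~0.006 copies,
  generates essentially no lesions. Both Abeta→ROS parameters are zeroed
  by the ROS blockade.
* **A small GSK3beta pool (20 copies)** caps the complex count, bounding
  the runaway so that late-stage event rates, copy numbers and run times
  stay moderate.
* **Amplified p53 synthesis runs through the complex** (plus a weak
  soluble-Abeta transcription term). After a late clearance boost the
  complex persists — phospho-p53 dephosphorylates slowly (0.12/day) — so
  p53 plateaus rather than regresses, and cells parked near the apoptosis
  threshold at day 8 still cross it. This is what makes a day-8
  intervention barely better than none, while a day-2 intervention
  interrupts cascades early enough that they level off far below the
  threshold.
* **Oligomer clearance is slow (0.3/day)** relative to monomer clearance,
  so a late boost leaves a decaying oligomer legacy that lets tangle
  counts catch up toward the no-intervention level.

## Viability analysis

Cell death is post hoc, not a reaction. Each run draws an apoptosis
threshold from Normal(mean 600, **variance** 50 — i.e. sd ≈ 7.07, taken
as printed; both knobs are configurable), clipped below at 1. A cell dies
at the first recording-grid time where its total p53 pool (free +
phospho + Mdm2-bound + ubiquitinated + GSK3beta-bound) strictly exceeds
its threshold; otherwise it is censored at the horizon. Crossing is
detected on the grid rather than between reactions; at the default grid
step the difference is below the grid resolution. Thresholds come from a
stream independent of the trajectory RNG (derived from the analysis seed
and the condition label), so re-analysis never re-simulates, and full
(untruncated) trajectories enter the ensemble means regardless of death
time.

## Statistical conventions

* Ensemble summaries: per-grid-time mean and sample sd (n−1 denominator;
  0 reported for n = 1). Censored first-passage times enter medians as
  +∞; a censored median is reported as censored.
* "Close to zero" for an end-of-run ensemble mean: below one copy
  absolutely and below 2% of the no-intervention mean of the same
  observable.
* "Not significantly lower / within Monte-Carlo error": overlap of the
  95% confidence intervals of the end-of-run means.
* The test fixtures compare intervention conditions with **common random
  numbers** (the same per-run seeds across conditions). Because a timed
  intervention leaves the pre-intervention trajectory untouched, paired
  conditions are identical up to the intervention day and the comparison
  isolates the intervention effect from between-stream sampling noise.
  `run_clearance_sweep` itself derives independent per-condition seed
  offsets, so its conditions can be executed in any order or subset with
  identical results.

## Problem sizes

The headline ensembles use 100 runs of 12 days, matching the reported
protocol. The intervention-timing comparisons in the test suite use 60
runs per condition and the two blockades 40, which keeps the full test
suite around six minutes on one core while leaving the Monte-Carlo
comparisons well separated from their tolerance bounds. The SSA-exactness
checks validate ensemble means and variances of a linear production–
conversion–decay cascade against the closed-form master-equation moments
(product-Poisson law) over 1500 replicates, and the exponential waiting
time and stationary birth–death occupancy against their closed forms.

## What the generator does and does not emulate

The synthetic cells reproduce the qualitative single-cell phenomenology
this model family reports: stochastic, all-or-nothing entry into a
self-amplifying pathology cycle; tangles slightly preceding plaques;
strongly time-dependent benefit of clearance interventions; and
threshold-based commitment to apoptosis. They do not emulate spatial
effects, explicit apoptosis kinetics, immunotherapy-style plaque
disaggregation, chaperone or insulin/wnt signalling, mitochondrial
dynamics, or realistically slow (months–years) aggregation lag times —
the aggregation rates are deliberately accelerated so that a 12-day
in-silico protocol exercises the full cycle. Passing tests therefore
demonstrate internal consistency of the mechanism and its interventions,
not quantitative agreement with wet-lab kinetics.

## Known limitations

* Rate constants are calibrated, not fitted; only the reported ensemble
  behaviours constrain them, so individual parameter values should not be
  interpreted biologically.
* Copy-number scales (e.g. p53 in the thousands after ignition) are
  arbitrary up to the threshold convention; only their ordering relative
  to the 600-copy apoptosis threshold is meaningful.
* The SBML interface supports the package's own vocabulary (discrete
  amounts, mass-action products, time-triggered parameter events) and
  rejects anything else rather than approximating it.
* A censored viability run means "no death within 12 days", not survival.
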