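# Methods

## The model

`bsabqsp` simulates a bispecific T-cell engager (BsAb) that bridges CD3 on
T cells and BCMA on myeloma cells in relapsed/refractory multiple myeloma.
One virtual patient is a stiff ODE system over three compartments —
central (plasma), bone marrow (the site of action), and a peripheral
distribution compartment — with these interacting pieces:

**PK.** Subcutaneous depot absorption (`ka`), linear clearance (`CL`), and
volumetric exchange flows between compartments (`Q`, `q_BM`, in L/day).
Doses are discrete depot boluses; the integrator is stopped and restarted
at every dose so events are exact. Using flows rather than first-order
rate constants makes the drug mass balance close identically: depot + free
drug + drug in every complex + cumulatively eliminated drug equals the
cumulative administered dose (verified to 1e-5 relative over six cycles;
in practice the defect is at machine precision).

**Binding.** Mass-action kinetics in the bone marrow: the drug binds
membrane BCMA (`kon_B`/`koff_B`, default Kd 20 nM) and CD3 (`kon_C`/
`koff_C`, default Kd 150 nM — the CD3 arm of clinical T-cell engagers is
deliberately weak) to form dimers; either dimer closes into the functional
trimer with the cross-arm on-rate scaled by an avidity efficiency `chi`
(0, 1]. Soluble BCMA binds the BCMA arm in both compartments, and a
nonfunctional CD3:drug:sBCMA trimer is included behind a config flag
(default on). Thermodynamic consistency holds because `chi` scales both
closure routes.

**Effective binding ratio.** The efficacy driver is
theta = trimer / (free BCMA + BCMA dimer + trimer) — trimers per BCMA
receptor. Tumor killing is `k_max * theta^n_kill / (alpha_kill^n_kill +
theta^n_kill)`, attenuated by acquired resistance `1/(1 +
alpha_resis * t_treat)` with the clock starting at the first dose and not
decaying on dose holidays. theta(exposure) is bell-shaped: too little
drug forms few trimers; too much saturates both receptors into dimers.
With the default affinities the bell peaks near the bone-marrow exposure
of 76 mg weekly, which is what makes dose-frequency de-escalation after
deep response beneficial in the model (see below).

**Tumor and residual disease.** Logistic growth (`g`, `N_max`) minus the
trimer-driven kill. A minimal residual reservoir (`N_min`, default 1e5
cells) is shielded from killing: per-cell death is scaled by
`max(1 - N_min/N, 0)`. Without it, deep responders decay to physically
meaningless sub-cell burdens and late progression under resistance cannot
occur.

**Receptor bookkeeping.** Membrane receptor pools are tied to cell counts:
free BCMA + BCMA dimer + trimer = `rho_B` x tumor cells (converted
receptors/cell -> nM exactly once, at state assembly), and the analogous
identity for CD3 on bone-marrow T cells. Shedding is density-neutral
(synthesis instantly replaces shed receptors), dying cells release
complexed drug back into solution, and a dying trimer returns its CD3 arm
to the surviving T cell — so both identities are exact properties of the
vector field. The integrator re-projects the free-receptor slots onto the
conservation manifolds at segment boundaries (corrections are at the
solver-error scale; a drift above 1e-3 raises an integration-quality
error).

**Soluble BCMA sink.** Free membrane BCMA sheds at `k_shed` (default
10/day; the prior spans 2–40/day — membrane BCMA turns over fast). Shed
antigen exchanges between bone marrow and plasma (`q_S`) and clears
centrally (`k_cl_S`); the central drug:sBCMA complex clears with its
antigen, so shedding is a genuine continuous drug sink whose flux
(`k_shed` x membrane BCMA pool) spans the clinical dose rates
(~15–150 nmol/day). `k_cl_S` is back-solved per patient so the sampled
baseline sBCMA is an exact pre-treatment steady state; the bone-marrow
sBCMA level is back-solved from the same balance. Paraprotein production
rates (`k_M`, `k_F`) are likewise back-solved from the sampled baselines.

**IL-6 and T-cell trafficking.** Trimer formation releases IL-6 from a
depletable pool (`k_rel`, depletion `k_dep`, replenishment `k_rep`), which
slows T-cell egress from the marrow as `k_out/(1 + IL6/I50)`. Pool
depletion reproduces the attenuation of cytokine peaks across repeated
equal doses. IL-6 magnitudes are config-level only — no claim of
quantitative agreement with clinical assay values is made. T-cell counts
are conserved between compartments (no proliferation or exhaustion).

## Response scoring

The integrated paraprotein is serum M-protein when measurable at baseline
(>= 0.5 g/dL), otherwise FLC when measurable (>= 10 mg/L, configurable),
otherwise the patient is excluded from cohort summaries. Assessments run
every 4 weeks under fractionated (priming) regimens, every 3 weeks
otherwise. A biochemical responder shows >= 50% decline from baseline at
two consecutive assessments; VGPR depth is >= 90%; progression (PD) is a
>= 25% rise from the running nadir, baseline included, boundary inclusive.
The clinical absolute-increase clause for PD is deliberately omitted — the
simulated rule is relative-only. BOR is the best single-assessment change.
A "persistent responder" has confirmation by the first assessment at or
after cycle 7 day 1 (day 196 under 28-day cadence); such patients are
eligible for the QW -> Q2W switch (confirmed depth at two consecutive
assessments, the second being the trigger), and optionally Q2W -> Q4W from
cycle 13.

## Synthetic study conditions

No patient-level trial data are public, so the generator promotes the
published cohort summaries to defaults: baseline sBCMA log-normal placed
so that P(sBCMA < 100 ng/mL) = 0.70 (sigma = 1.0 -> median 59 ng/mL);
stratified response-rate targets 77% (low) / 37% (high) for the two-step
priming 76 mg QW cohort, with a monotone median trajectory reaching a 90%
decline by day ~100 and a best-response decile profile spanning +25% to
-100%. The decile profile is chosen consistent with the stratified rates
(7 of 10 deciles at or below -50%, vs a pooled rate of 65% — compatible
within one decile's width). The two lower-dose cohorts are synthetic
defaults (not published values), set after exploring the model's
cross-dose response correlation so that they are jointly attainable, and
kept strictly lower per stratum. Baseline sBCMA and tumor burden are
coupled by a Gaussian copula (Spearman 0.5 by default), reflecting sBCMA
as a burden marker.

Nine parameters vary across patients (uniform priors): `rho_B` (1–8 x10^3
BCMA/cell), `rho_C` (2–12 x10^4 CD3/cell), `n_kill` (1–4), `alpha_kill`
(1e-3–5e-2), `alpha_resis` (0–0.012/day), `g` (ln2/500–ln2/40 per day),
`k_shed` (2–40/day), `k_max` (0.3–6/day), and a bone-marrow T-cell
baseline multiplier (0.2–5). The identity of the varied set follows the
workflow's conventions; the bounds are this package's documented
stand-ins, chosen once from literature-scale reasoning: the `alpha_kill`
prior straddles the realized binding-ratio distribution so response is
genuinely heterogeneous, and the `g` prior brackets the 60–600-day
doubling-time plausibility window (itself a config-exposed stand-in for
the literature range).

What the generator does not emulate: assay noise and detection limits,
free-vs-total analyte measurement differences, correlated multi-marker
baselines beyond the single copula pair, toxicity-driven dose
modifications, and real between-trial heterogeneity. Passing tests
therefore demonstrate internal consistency of the workflow under these
idealized conditions, not fidelity to any real cohort.

## Calibration workflow

10,000 candidates by default (hundreds at desk scale): sample parameters
and baselines, keep candidates whose untreated tumor and M-protein
doubling times fall in [60, 600] days (computed from the logistic closed
form plus the linear paraprotein balance — no full ODE solve), then
simulate every plausible patient once per target regimen with progression
dropout, caching assessment-time summaries. GA selection (population 50,
generations 100, tournament 3, uniform crossover with cardinality repair,
two-swap mutation, elitism 2 — all config) then picks fixed-size member
sets; fitness is pure arithmetic on the caches. The objective sums, per
cohort and weighted by trial size, the squared stratum-BRR errors, the
mean squared median-trajectory error, and the mean squared decile error,
each normalized to unit scale (rates as fractions, percent changes / 100);
a required stratum with no members contributes a fixed penalty of 10.
Dropout patients enter trajectory medians by last observation carried
forward (a config switch can drop them instead). The calibration-recovery
checks fit the cohort whose summaries are cached, mirroring how the
workflow is exercised end to end.

## Numerical choices

LSODA with rtol 1e-6 / atol 1e-9 by default (tighter in oracle
cross-checks); output on a daily grid plus event times; integrator-noise
negatives below 1e-8 clipped to zero. The algebraic ternary-equilibrium
oracle solves the closed mass-action system by damped least squares in
log-concentration space to residuals < 1e-10 of the largest total and is
used only as an independent cross-check of the ODE path. Curve-shape
classification tolerates 2% relative wiggle to absorb solver noise; ties
break toward "bell" only on a strict interior peak.

## Problem sizes used in the shipped checks

The test-suite and acceptance runs use reduced sizes chosen as this
package's desk-scale defaults: candidate pools of 180–1,200 (plausible
pools of ~120–850), one VPop of 120 rather than ten, and a 3-year horizon
for the de-escalation study. Tolerances are never widened to compensate;
the stratified response-rate recovery is checked at +/- 5 percentage
points and the baseline split at +/- 1 point at n = 10,000.

## Known limitations

The sink-monotonicity property (more baseline sBCMA never helps) holds in
the drug-limited regime only; past the per-patient bell peak a sink moves
exposure toward the trimer optimum and can slightly raise the binding
ratio — the same physics that makes post-response de-escalation
beneficial. CD3 binding is modeled in the bone marrow only; circulating
T cells are a drug-free reservoir. Trimer-induced T-cell activation,
expansion and exhaustion are out of scope, as are CRS grading,
immunogenicity, and spatial tumor structure. The de-escalation benefit
(fewer progressions, higher trimer:tumor-cell ratio under Q2W) is an
emergent model property whose magnitude is modest at the default
parameterization; its direction, not its size, is the tested claim.
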