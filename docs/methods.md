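# Methods

## Model structure

The model evaluates screening for glaucoma in an at-risk population
(rural patients over 50 with risk factors such as diabetes, hypertension,
family history or concurrent ocular disease) from a third-party-payer
perspective. It has two layers.

**Decision layer.** Each strategy screens the whole cohort once at entry.
With prevalence $p$ and test sensitivity $se$ / specificity $sp$, the
cohort splits into four branches: true positives ($p \cdot se$) enter the
*treated* Markov arm, false negatives ($p(1-se)$) the *untreated*
(natural-history) arm, and everyone without glaucoma — true negatives
($(1-p)sp$) and false positives ($(1-p)(1-sp)$) — remains in the at-risk
branch, where false positives additionally incur one confirmatory
in-person work-up at entry. Per-patient expected cost and effectiveness
are the branch-probability-weighted totals plus the per-patient screening
cost. The standard-of-care comparator is modelled as a screening strategy
in its own right (in-person examination with its own test
characteristics and program costs); a pure no-screening arm is the
special case `test: null`, equivalent to sensitivity 0 at zero cost.

**Disease layer.** Five ordered health states — glaucoma suspect
(at-risk), mild, moderate, severe, blind — with one-year cycles over a
30-year horizon. Glaucoma is irreversible: transition matrices are
upper-triangular (no recovery) and blindness is absorbing. The reference
parameter set restricts matrices further to self-loop plus one-step
progression (adjacent states only); the engine accepts any
upper-triangular row-stochastic matrix. There is no death state: the
cohort is closed, all-cause mortality is deliberately absent, and every
report carries that limitation flag. Both strategies' Markov arms start
in the at-risk (suspect) state, so an arm trace covers the
pre-diagnostic phase of the screened cohort; the entry state is
configurable per strategy.

**Rewards.** Each state carries a utility weight (QALY per year;
at-risk 1.0 by assumption, then 0.87 / 0.79 / 0.64 / 0.50) and an annual
cost (CAD per year). A strategy's recurring service cost (annual
monitoring/program cost per participant) is added to every state's
annual cost in all of its branches. Rewards accrue on start-of-cycle
occupancy, cycles 0..30 inclusive (31 accrual points), with **no
half-cycle correction** — the default behaviour of the decision-tree
software the original analysis used when no correction is declared.
End-of-cycle accrual is available via `reward_timing: end`; the shipped
configuration records that `start` was used for calibration. Cycle-$t$
rewards are discounted by $(1+r)^{-t}$ with $r = 0.03$ per year; cycle 0
is undiscounted.

## Cost-effectiveness statistics

For reference strategy $R$ (teleglaucoma) versus comparator $C$
(in-person): incremental cost and effect are reported as $C - R$ (the
comparator row of a league table) and the headline ICER as
$(\mathrm{cost}_R - \mathrm{cost}_C)/(\mathrm{effect}_R -
\mathrm{effect}_C)$, so a reference that is cheaper *and* more effective
yields a negative ICER (savings per QALY gained) together with a
`dominated` flag on the comparator. The ICER is still reported
numerically under dominance rather than suppressed. The average
cost-effectiveness ratio (CER = cost/effect per strategy) is reported
alongside, because summary tables in this literature print both and call
both "the ICER"; here the incremental ratio is the headline. Zero
incremental effect yields an explicit undefined marker instead of a
ratio. Net monetary benefit is $\lambda \cdot \mathrm{effect} -
\mathrm{cost}$ at willingness to pay $\lambda$ (default $40{,}000$
CAD/QALY); its ranking provably agrees with the ICER-threshold decision
rule, and the tests exercise that identity.

## Calibration of the reference set

The original analysis' parameter file is not available; the shipped
configuration back-fills the unpublished values from the published
30-year summary results. Stages, in order:

1. **Teleglaucoma treated arm.** The four progression probabilities are
   fitted (bounded least squares, multi-start, analytic-free trace
   forward-propagation) so the 30-cycle occupancy matches the published
   teleglaucoma cohort row (at-risk 3.71e-5, mild 0.15, moderate 0.10,
   severe 0.09, blind 0.65, normalized to sum to one). The fit is exact
   to ~1e-6. Result: incidence (at-risk→mild) 0.287, then 0.070 / 0.167
   / 0.241 per year.
2. **Natural history.** Incidence is treatment-independent, so the
   untreated arm shares the treated arm's at-risk→mild probability; its
   three manifest-stage progressions are set by assumption to 0.45 /
   0.50 / 0.55 per year (roughly two-year mean stage residence
   untreated). No long-horizon untreated teleglaucoma cohort exists to
   fit these against; they are tagged `assumption`.
3. **In-person treated arm.** Fitted to three published/inferred
   targets: cumulative discounted reward 16.8 QALY, 30-year blindness
   0.89 (inferred from the reported 24% relative blindness reduction —
   not printed directly), and a depleted at-risk state. These are
   *jointly infeasible* for an adjacent-progression chain (a cohort
   cannot both accrue that reward and reach that blindness level), so
   this is an explicit weighted compromise favouring the structural
   blindness contrast: the shipped arm reaches blindness 0.835 (21.4%
   relative reduction vs teleglaucoma's 0.657) with cumulative reward
   16.30.
4. **Prevalence and in-person sensitivity** are then solved in closed
   form so both strategies' expected per-patient effectiveness equal the
   published 18.32 / 18.19 QALY exactly. This yields prevalence 0.48 —
   high for a general population but this is a referred, risk-enriched
   cohort, and the value is tagged `calibrated`, carries the widest
   uncertainty in the sensitivity analyses, and is the model's most
   influential parameter. In-person sensitivity solves to 0.77 with
   specificity fixed at 0.90 by assumption (in-person examination is
   less sensitive and more specific than teleglaucoma's 0.865 / 0.786).
5. **Costs.** Ten unknowns (five annual state costs, two recurring
   service costs, two per-screen costs, one confirmatory-exam cost) are
   solved by bounded linear least squares with four exact constraints —
   the two published per-arm cumulative discounted costs (1155.45 /
   4035.19 CAD) and the two published per-patient strategy costs
   (871.54 / 4441.42 CAD) — plus weak relative priors that pull the six
   under-determined directions toward plausible magnitudes (state costs
   rising with severity, cheap teleglaucoma service, expensive in-person
   service). The four identities are met to better than 1e-6 relative.

Every value is tagged in the YAML as `reported` (published), `calibrated`
(fitted here), `assumption`, or `derived`. The calibration is fully
deterministic; `analysis/01_calibrate_reference.py` regenerates the
shipped file and a benchmark-reproduction table.

**Identifiability.** Fitting progression rates to an end-of-horizon
occupancy alone is well-posed only while the occupancy still carries
information about each rate. Once the entry state is depleted before the
horizon (fast progression), or no mass ever reaches a downstream state,
distinct rate vectors match the target below any practical tolerance. A
tiny ridge (weight 1e-8) toward zero progression resolves such flat
directions deterministically without materially shifting identified
fits; parameter-recovery tests draw truths at moderate rates
(0.03–0.25/year) where the problem is identified.

## Sensitivity analyses

**One-way DSA** sweeps a single dotted-path parameter over
`base × (1 ± 20%)` (the published swing), re-evaluating both strategies
at each grid point; everything else stays at base values.

**Tornado.** Each parameter is swung to low/high bounds and the
incremental NMB at the configured WTP recorded; entries are ranked by
swing width (ties broken by name for determinism). Bounds are the
parameter's declared second-order uncertainty interval (mean ± 2 SE,
clipped to the distribution's support) when one exists, otherwise the
±20% relative default — a tornado bar should span a parameter's
plausible range, and a uniform relative swing misrepresents parameters
whose uncertainties differ by an order of magnitude. Under the reference
dispersions, prevalence carries the widest swing, followed by the
treated-arm incidence.

**PSA.** Second-order Monte Carlo, 1000 draws by default. Costs get
gamma distributions, probabilities and utilities beta distributions,
both parameterized from (mean, SE) by the method of moments
(gamma: shape $= \mu^2/\sigma^2$, scale $= \sigma^2/\mu$; beta:
$\alpha = \mu\nu$, $\beta = (1-\mu)\nu$ with $\nu = \mu(1-\mu)/\sigma^2
- 1$; infeasible beta variances are rejected before sampling). All
uncertain parameters are redrawn jointly and independently per draw — no
correlation structure is imposed — except that sampled state utilities
are monotone-rearranged (severity-sorted) per draw, since independent
draws would otherwise violate the ordering invariant; the untreated-arm
edges are addressed through a shared `natural_history.*` alias so one
draw moves both strategies' natural history coherently. Both strategies
are evaluated on the same draw. Draw $i$ uses a child generator spawned
from the run seed with spawn key $(i,)$, so results are bit-reproducible
and enlarging the sample leaves earlier draws unchanged. The CEAC
reports, on a WTP grid of 0–100,000 CAD/QALY in 2,000 steps, the
fraction of draws in which each strategy attains the higher NMB (ties
split evenly, so the two curves sum to one).

The published PSA dispersion magnitudes are not reproducible exactly
(the underlying distribution hyperparameters were never published); the
reference SEs encode the identification hierarchy — prevalence SE 0.10
(least identified), test characteristics 0.03–0.05, utilities 0.03,
calibrated transitions 5% relative, costs 20–40% relative — and were
chosen so the resulting per-strategy cost spreads are on the published
order (≈ ±100 CAD for teleglaucoma, ≈ ±1000 CAD for in-person, which is
also the published qualitative contrast: a tight teleglaucoma cloud
around $1K, a wide in-person cloud spanning $3K–8K).

## Random scenario generator

`random_scenario(seed)` emits valid configurations for property testing:
ordered utilities, non-negative severity-increasing costs, adjacent
progression with the treated arm elementwise no faster than the
untreated arm, a screening strategy plus a no-screening comparator, and
a small PSA block. It emulates the *structure* of the reference problem,
not its epidemiology: horizons, rates and costs are drawn from broad
ranges, so passing property tests demonstrates engine invariants
(row-stochasticity, blindness monotonicity, severity stochastic
dominance, microsimulation agreement, discount monotonicity) — not
fidelity to any real screening program.

## Numerical choices

- Row-stochasticity and probability-vector validation: 1e-9 absolute.
- Classification probabilities sum to 1 within 1e-12.
- Calibration acceptance: Euclidean residual ≤ 1e-3 on the occupancy
  simplex; optimizer tolerances 1e-14, progression bounds [1e-9, 0.95]
  (the upper bound keeps beta second-order distributions feasible).
- Cost-identity verification after the linear solve: 1e-6 relative.
- Degenerate PSA (all SEs zero) short-circuits to `fixed` sampling and
  reproduces the deterministic base case bit for bit.
- The cohort engine matches an independent per-individual
  microsimulation (categorical sampling per individual-year) within
  three binomial standard errors at $10^5$ individuals in the tests.

## Known limitations

- No background mortality or competing risks; QALYs and costs are per
  patient entering the pathway, not population projections.
- Single classification at entry (annual re-screening of false negatives
  is structurally possible but off by default; the published per-patient
  cost magnitudes are consistent with single classification).
- One treatment pathway; treatment heterogeneity is out of scope.
- Travel-distance savings enter only as pass-through reporting
  (visit-time savings: 37 minutes, 32.2%), not as modelled utilities.
- The calibrated values are *a* parameter set reproducing the published
  summaries, not *the* original one: the cost solve in particular is
  under-determined beyond its four exact constraints, and the in-person
  arm is a documented compromise between jointly infeasible targets.
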