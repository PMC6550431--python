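# Methods

## Model structure

The model is a discrete-time (monthly-cycle) state-transition
microsimulation of adjuvant therapy for early-stage node-negative
HER2-positive breast cancer, with six health states: adjuvant therapy (1),
low toxicity (2), hospitalization due to high toxicity (3), alive
relapse-free (4), alive with relapse (5) and death (6). All patients start
in state 1. The adjuvant sub-model runs 12 months for the trastuzumab arms
(TH, ACTH, TCH) and 6 months for no-trastuzumab (NT); afterwards patients
are followed in the relapse-free/relapse states until death, with a hard
cap at age 121 that guarantees termination (any residual survivors are
force-terminated and the one-off death cost applied; the residual mass is
~2·10⁻⁴ in the base case and is logged).

Transitions drawn during month *m* take effect in month *m + 1*:

* **Therapy state.** Competing events each month: death (age-specific
  background mortality), a high- or low-toxicity month, a toxicity month
  that ends in quitting, or continuing. Toxicity states last exactly one
  month, after which the patient resumes therapy or — if the event was a
  quit — exits to relapse-free. Toxicity months count toward the fixed 6- or
  12-month calendar; an event whose toxicity month would fall after the
  calendar resolves to completion, and a quit whose follow-up would begin
  after the planned completion counts as completion (the patient received
  the full course). The published 70/30 split of quits between high and low
  toxicity is *not* imposed; it emerges from the competing quit
  probabilities (0.00340 vs 0.00148) and is verified as an output statistic.
* **Relapse.** No relapse can occur during treatment. After completion the
  monthly relapse probability follows the arm's banded schedule indexed by
  year since treatment start (years 1–2, 3–4, 5–8, 9–10, ≥11). Patients who
  quit ramp linearly from the scheduled value at the quit month to
  0.0126/month at the planned treatment end — a discontinuation spike — and
  follow the untreated (NT) schedule thereafter. We considered holding
  quitters at 0.0126/month for life, but a 15%/year hazard sustained over
  decades implies near-certain relapse for every quitter, which is
  clinically implausible for this population and depresses the trastuzumab
  arms' life expectancy well below the published values; the
  reversion-to-untreated reading reproduces them.
* **Effect horizon.** When a finite treatment-effect horizon of *h* years is
  set, relapse probabilities revert to the untreated schedule beyond month
  12·*h* in every arm (patients are still followed for life). This models
  "the regimen has no additional benefit in reducing relapse beyond the
  horizon".
* **Relapse state.** The patient repeats her adjuvant course once (cost
  only, no second pass through the toxicity states) and remains in the
  relapse state until death. The monthly death probability there is the
  excess relapse mortality 0.02734 **added to** age-specific background
  mortality. The parameter table's mortality rows exclude the relapse
  state, which can be read either as "replaced by 0.02734" or "0.02734 on
  top"; we adopt the additive (excess-hazard) reading, which is standard in
  decision models and is the only one consistent with the published 80+
  ICER (~85k/QALY; the replacement reading gives ~95k) while changing the
  40–49 base case by under 0.2%.
* **Mortality and ageing.** Each patient starts at the lower bound of her
  age band and her attained age advances monthly; mortality, the
  relapse-free state cost and the baseline utility always follow the
  attained band. (Constant per-band mortality over a lifetime would be
  inconsistent with the published life expectancies.) The NT arm carries an
  elevated mortality override for the first 24 months.

## Outcome accrual

Events resolve at end of month. Each alive month accrues its state cost and
utility at discount factor `(1+r)^(−(m−1)/12)` (month 1 undiscounted,
r = 3%/year for both costs and QALYs); the month in which the patient is
dead accrues the one-off death cost and nothing else; a relapse-entry month
additionally accrues the full re-treatment course
(`monthly treatment cost × treatment months`). No half-cycle correction is
applied: with monthly cycles the correction is below the Monte-Carlo noise.
Life-years are **undiscounted** while costs and QALYs are discounted — the
published totals (33.77 LY vs 16.17 QALY for TH, and the ~$4,700/LY vs
~$10,600/QALY ICERs) are mutually consistent only under this reading.

**Utility model.** The quality weight of every alive month is the
age-band baseline utility *b(age)* (0.84 at 40–49 declining to 0.78 at 80+)
times a state modifier: the therapy utility (0.810/0.795/0.780 by arm),
the toxicity utilities (0.56 high, 0.85 low), the relapse utility (0.55),
and for relapse-free months `u_after / 0.90` — i.e. the published
after-therapy utility of 0.90 is an anchor at which the patient returns
fully to her age-specific baseline, and the sensitivity range [0.85, 0.95]
scales that return by ±5.6%. This construction was chosen because the
published per-arm QALY totals are reproducible only when relapse-free
months are weighted at approximately the baseline utility itself
(a least-squares fit of the four published QALY totals against per-state
discounted life-year decompositions yields an effective relapse-free weight
of 1.005 × baseline); weighting them at 0.90 × baseline understates all
QALY totals by ~9%, and using unscaled state utilities overstates them by
~19%. The residual discrepancy concentrated in the NT arm (+6.7%) would
vanish only if relapse months carried no utility at all, which we rejected
in favour of keeping the published relapse utility active.

## Parameters

All inputs live in a validated, YAML-serializable `ParameterSet`;
`builtin_base_case()` carries the published monthly transition
probabilities, 2016-USD costs and utilities. Key defaults:

| parameter | default | units / note |
|---|---|---|
| cycle length | 1 month | fixed |
| patients per arm | 10,000 | Monte-Carlo size |
| discount rate | 3%/yr | costs and QALYs; one-way scanned 0–5% |
| WTP threshold | $50,000/QALY | for net monetary benefit and the CEAC |
| treatment cost/month | 5,896.59 / 7,812.34 / 11,452.91 / 9,404.05 | NT / TH / ACTH / TCH |
| relapse-free cost/month | 286 → 425.50 | by attained age band |
| death cost | 10,000 | once |
| post-quit relapse ceiling | 0.0126/month | at planned treatment end |
| age cap | 121 years | termination guarantee |

Uncertainty follows the published Range/SD column: "x% ±" becomes a
triangular distribution with the base value as mode, bracketed ranges
become triangular on [low, high], and "Beta" entries are beta distributions
moment-matched to the mean and SD. Quantities that are one substantive
parameter shared across arms or year bands — the relapse schedule, death
from relapse, the quit probabilities, treatment cost — are sampled/scanned
with a single common multiplier, matching how the one-way analysis labels
them ("probability of relapse", "cost of adjuvant therapy"). The discount
rate is a scenario axis (scanned 0–5% in the tornado) and is excluded from
the PSA.

## Engines, common random numbers, and the oracle

Two implementations of the same process are held to agree in tests:

* the **microsimulation** advances all patients of an arm through the
  monthly process, consuming one uniform draw per patient-month from a
  matrix generated by `(seed, n)` alone. Because the matrix is independent
  of the arm, patient *i* experiences the same randomness in every arm
  (common random numbers), which removes most sampling noise from
  incremental comparisons. A scalar per-patient walk over the same event
  ordering (death, high-tox, quit-high, low-tox, quit-low, relapse, stay)
  reproduces the vectorized engine bit-for-bit and is tested against it.
* the **cohort trace** propagates state-occupancy mass exactly through the
  identical transition structure, over an expanded state space (toxicity
  months split by quit-pending status; relapse-free quitters tracked per
  quit month while the ramp rises), accruing expected cost/QALY/LY. It is
  the expectation of the microsimulation, runs in milliseconds, and backs
  the acceptance tests (agreement within Monte-Carlo error on the fixture
  and on 20 random scenarios) as well as the deterministic sensitivity
  scans. A two-state reduction reproduces the truncated-geometric life
  expectancy `(1−(1−p)^M)/(12p)` to 1e-9.

The PSA samples every uncertain parameter independently per draw
(no correlation structure), runs TH and NT with the same patient substream
within the draw, and reports the fraction of draws with positive
incremental net monetary benefit at the WTP threshold, plus a CEAC over a
WTP grid. Default scales used by the acceptance script: 10,000 patients/arm
for deterministic targets and 500 draws × 1,000 patients/arm for the PSA;
the CLI exposes both knobs.

## Synthetic scenarios

`random_scenario(seed)` draws structurally valid but otherwise arbitrary
parameter sets (monotone mortality tables, banded relapse schedules in
[5·10⁻⁵, 0.02], toxicity/quit probabilities leaving a positive residual,
utilities and costs in wide ranges). These exercise the transition kernel
and the microsim-vs-trace agreement far from the fixture. They do **not**
emulate correlated parameter uncertainty, non-monotone age effects, or
schedule shapes other than the five-band structure, so passing property
tests demonstrates internal consistency of the engines, not external
validity of any particular scenario.

## Design choices on genuinely open points

* Relapse year bands are indexed from simulation start (month 1 =
  treatment start), not from treatment end.
* Quitting is an unconditional competing monthly event from the therapy
  state (the published quit probabilities are of that magnitude); the 70/30
  split is an output check.
* Re-treatment on relapse is cost-only.
* The trailing months of a toxicity event at the calendar boundary are
  resolved as completion (see above).
* Extended dominance is implemented in the frontier ranking although the
  four-arm base case only exercises strict dominance.

## Known limitations

* No individual heterogeneity beyond age progression; relapse risk is
  age-independent by assumption.
* The post-quit hazard after the discontinuation spike, the additive
  relapse mortality, and the baseline-anchored utility model are
  reconstructions of under-documented conventions, selected for
  consistency with the published totals; alternatives are discussed above.
* The time-horizon scan reproduces the qualitative behaviour (ICER
  monotone non-increasing in the horizon, 6-year ICER ≪ $100k/QALY) but
  rises more shallowly at very short horizons than the published figure
  suggests; our reversion mechanism preserves gains from relapses already
  avoided before the horizon.
* Strategy-level cost orderings under TH-cost scaling cross at ×1.25
  (vs TCH) and ×1.51 (vs ACTH) in our reconstruction versus the published
  ×1.2 / ×1.5 — a consequence of ~1% per-arm cost residuals with opposite
  signs.
* No value-of-information analysis and no correlated PSA sampling.
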