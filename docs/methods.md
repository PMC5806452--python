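# Methods

## Scope and data model

`impquant` scores the implementation of a protocolized multi-component
intervention from four kinds of records: a protocol (components, planned
per-participant sessions with durations and success criteria, a
team-representation schedule), a roster (participants → teams → workplaces,
with a trial step per participant), per-session deliverer logbooks
(success-criterion ratings, quality items, training intensity, group
motivation, attendance lists) and an end-of-intervention participant
questionnaire (satisfaction, social support). Sessions are scheduled for
*delivery units* — a team, a merged working group, or a training group —
because unit membership defines who can attend; the trial step is a property
of the participant's randomization group and is inherited by that group's
sessions.

The reference protocol shipped with the package has 19 sessions / 27 h:
participatory ergonomics (PE, 5 sessions / 9 h), physical training (PT, 12 ×
1 h) and cognitive behavioural training (CBT, 2 × 3 h), with 55 success
criteria in total. Within PE, the published material fixes only the component
totals; the split used here — kick-off 1 h, two workshops 3 h each, two
evaluation meetings 1 h each, and criteria counts 4/4/4/3/3 (PE), 2 per PT
session, 6+7 (CBT) — is a package convention chosen to sum to the published
totals.

## Scoring rules

All ordinal items are rescored to 0–100 before aggregation: 5-point scales as
100/100/50/0/0 from most to least positive; the 4-point criterion scale as
0/50/100/100 (in-depth delivery is not rewarded beyond complete delivery);
self-rated performance 0–10 as 0–4→0, 5–7→50, 8–10→100; PT intensity 0–10 as
0–3→0, 4–5→50, 6–7→75, 8–10→100. Indexes are available-item means; an index
with no answered item is missing, and missingness propagates rather than
raising. Scores are carried at full float precision; rounding to whole
percent (half away from zero) happens only at the reporting boundary.

Delivery: content is the mean of a session's scored criteria (intensity
enters the mean as one extra element with the same weight as each criterion —
the minimal reading of "the criteria fulfilment also considered intensity",
and a deliberate single point of change); quality is the mean of the
understanding index, contribution index and performance; fidelity is
`(C+Q)/2`. Held sessions without a logbook count toward dose but are missing
for fidelity means by default (`missing_logbook="as_zero"` is the documented
alternative): absence of measurement is not zero fidelity.

Receipt: individual-mode presence is 0/1 attendance. Team-mode PE sessions
are scored per team with a required-representative quota (<5 workers → 2,
5–9 → 3, 10–14 → 4, 15–19 → 5, ≥20 → 6): the participation score is the
duration-weighted mean over held team-mode sessions of
`min(attending members / quota, 1)`, the continuity score is the number of
members present at every held team-mode session over the quota (capped at 1;
`max_missed` relaxes "every" and defaults to 0), and the combined score — the
mean of the two — becomes each member's presence for those sessions,
modelling the intended spill-over to non-attending team members. Ratios are
capped at 1 throughout so no score exceeds 100.

Responsiveness is the mean of the available sub-indexes: satisfaction (six
items), support (four items) and motivation. Motivation is measured at group
level in the logbook; it is assigned to individuals as the duration-weighted
mean over the sessions they *personally* attended (not the broadcast team
presence). Component-level responsiveness uses the component's satisfaction
item plus the three overall items, reuses the support index unchanged, and
restricts motivation to the component's sessions. Participants without a
questionnaire have missing responsiveness and implementation but full
participation and exposure; no imputation is attempted.

Exposure and implementation: `E_s = F_s × P_s`, `I_s = E_s × R` with R
constant per participant (it is measured once, at the end); totals are sums
over planned sessions, with canceled sessions contributing zero presence. A
held session whose fidelity is unknown contributes zero exposure, since the
fidelity actually received cannot be asserted. Component totals re-normalize
by the component's planned hours and pair component exposure with component
responsiveness. Individual-level fidelity — reported but not defined by a
formula in the source material — is the duration-weighted mean of session
fidelity over the participant's planned held, scored sessions; this is a
package convention isolated in one place.

## Statistics

Cronbach alpha is computed on scored (not raw) item matrices with listwise
deletion, `alpha = k/(k−1) × (1 − Σ var_i / var_total)`, sample variances.
The one-way comparison is the standard ANOVA decomposition via
`scipy.stats.f_oneway`, returned together with per-group n/mean/SD. Post hoc
tests, variance-homogeneity gates and repeated-measures designs are out of
scope; the per-group summaries are exposed so external tools can run them.

## The synthetic-data generator

Defaults reproduce the published trial conditions: margins 126/146/158/164
participants per step and 172/194/57/171 per workplace (rounded to exact
margins with a largest-remainder scheme), 58 teams, and intended sessions
172 PE / 501 PT / 80 CBT. Units are 16 kick-off audiences (one per
workplace×step cell), 39 PE working groups, 42 PT groups and 40 CBT groups;
three PT instances are trimmed from the largest groups because 501 is not a
multiple of 12. Cancellation defaults to the published held counts
(171/464/78) with the canceled instances drawn at random; a per-component
cancellation probability is the alternative mode.

Behaviour propensities default to the published component-level summaries:
content 0.95/0.86/0.96 and quality 0.92/0.93/0.92 (PE/PT/CBT), motivation
0.91/0.96/0.93, attendance PT 0.38, CBT 0.48, kick-off 0.66, satisfaction
0.83, support 0.93. Team representatives (a fixed random subset of quota
size per team) attend with probability 0.835, chosen so the combined PE team
score is ≈ 0.66 and overall participation ≈ 0.50; non-representatives attend
with probability 0.02. Ratings are drawn as two-point mixtures whose expected
score equals the propensity exactly (for t ≥ 0.5: top category with
probability 2t−1, middle otherwise), so recovery tests have sharp targets
without assuming a response distribution. Questionnaire response is Bernoulli
with probability equal to the participant's participation, giving a ~50%
response rate mechanically tied to attendance, as observed in practice.

Each table (cancellation, attendance, logbook ratings, questionnaires) uses
its own stream spawned from the master seed; a seed reproduces a
byte-identical dataset. The analytic ground truth accounts for cancellation
multiplicatively and approximates PE continuity as `p_rep^4` and motivation
weighting by expected attended hours; these approximations are small relative
to the 3-Monte-Carlo-SE tolerance the recovery checks use (verified at 4–6
replicates of the full 594-participant trial, which keeps the default test
run under a minute for the recovery portion).

What the generator does *not* emulate: deliverer-specific propensities and
learning over sessions, within-team correlation of attendance, seasonal or
organizational shocks, informative missingness in logbooks, and any outcome
(effectiveness) process. Passing recovery tests therefore show that the
scoring pipeline is an unbiased map from records to scores under the stated
conditions — not that real trials behave like the generator.

## Numerical conventions and limitations

Fractions internally for ratio-type quantities, 0–100 for item-derived
scores; whole-percent rounding half away from zero only when formatting.
Sample SD (n−1) in all summary tables. Empty strata yield n=0 rows with
missing means. Dose is undefined for zero intended sessions and inconsistent
counts raise rather than clip. The organizational-vs-individual diagnostic
reports both levels and their absolute difference without asserting
closeness: the two coincide exactly only under full attendance and
responsiveness.

Known limitations: the continuity definition is the simplest reading of
"the same representatives throughout" (persistent-attendee count over quota)
and is isolated behind one function for substitution; fidelity of intended
sessions is the held-session fidelity times dose, which reproduces published
component values only approximately — the discrepancy is inherited from the
source material and intentionally not reconciled; logbook self-report is
known to overestimate delivery relative to observation, and no correction is
applied.
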