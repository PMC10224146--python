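# Methods

This note documents the models and rules the package implements, the
parameters that matter, the design choices made where the published method
leaves the design open, and what the synthetic fixtures do and do not show.

## Risk model

`RA = X + (Y × Z)` with `Y = A × B × C × D`.

- **X** (pharmacological risk) is a rubric lookup on (a.i. category, route
  class). The engine normalizes IV/IP/pediatric parenteral routes to
  `parenteral` and accepts `chemotherapeutic` as an alias of `antiblastic`.
  Only the antiblastic/parenteral cell (125) is a documented value; the other
  default cells are neutral placeholders, marked as such in
  `risk.RiskTables`, and any unmapped pair raises rather than guessing.
- **A–D** (technological risk) are each 1–5. The engine scores B, C, D from
  preparation attributes (solution → B = 1; sterile parenteral → C = 5;
  whole-process sterility → D = 5; non-qualifying cases use placeholder
  values from config) and takes `raw_A`, the operator-assessed complexity, as
  input. When dose calculations are software-assisted and the category
  qualifies (anticancer compounding), `A = max(4, raw_A − 1)` — the reduction
  never drops A below 4.
- **Z** is a step function of the previous year's preparation count;
  defaults: 1.0 from 0, 1.2 from 501 upward. Tiers are config.
- **Reductions** for a certified QAS (−30%) and experienced personnel
  (−2.5%) compose multiplicatively and sequentially:
  `RA_final = round₁(RA_raw × 0.7 × 0.975)`. Sequential composition is the
  choice that reproduces the reference computation (245 → 167.2125 → 167.2);
  an additive −32.5% would give 165.375 instead. Rounding is half-up to one
  decimal, and tier classification uses the rounded, reduced value — the
  reference scenario classifies after reduction. Because of rounding,
  `RA_final` may exceed `RA_raw` by at most 0.05 when no reduction applies.
- **Tiers** partition [0, ∞): low ≤ 50 < medium ≤ 175 < high, each carrying
  its QAS requirement text. Thresholds are config (`RiskTierConfig`).

## Added-value tree

The tree is a data structure (`added_value.DEFAULT_TREE`, YAML-replaceable):
nodes name a predicate over the context and two successors; leaves carry
(justified, legal basis, rationale). The default table encodes: an existing
industrial equivalent is only overridden by a documented personalization
need; without an equivalent the preparation is always justified and the
remaining tests (Pharmacopoeia monograph, MA in the EU) select the legal
basis (magistral pathway, L. 94/98 Art. 5 c. 1, or c. 2). The intermediate
node ordering is a reconstruction — the published figure is not transcribed —
so it ships as editable config and `validate_tree` checks any replacement
for totality and well-formedness.

## QAS self-assessment

Ten critical factors, each with one or more requirements scored N.A./1/2/3/4
from the adherence state (absent / ≤50% / >50% without complete
documentation / 100% documented). Aggregation is weakest-link: factor score
= min over non-N.A. items; the unit is fully adherent iff every factor
scores 4. Rationale: full adherence is what unlocks the RA reduction and the
7-day microbiological cap, and an average could mask a critical gap. N.A.
items are excluded from the minimum; a factor that is *entirely* N.A. must
be whitelisted (`optional_factors`) or it is flagged and blocks full
adherence — the published scale defines N.A. but not its aggregation effect,
so the conservative reading is the default. Requirements are equally
weighted; no weights are published.

## Transcoding matrix

Cells are keyed on a canonical tuple
`working-grade/background-grade/device-class/validation-state`, where device
class collapses to `closed_no_gas` vs `other` and validation state to
`all_pass` (media fill, environmental monitoring, particle counts, QAS
adherence all true) vs `not_all_pass`. Defaults expose the two documented
extremes: `A/C/closed_no_gas/all_pass → 168 h`; everything else in the A/C
family → 0 h, meaning *no extension beyond the SPC*. Combinations outside
the configured cells raise `MatrixGapError` naming the tuple — a
configuration gap must never silently pass. Whether intermediate cells
(partial adherence → 24/48 h) exist is plausible but unpublished; sites add
them in the YAML matrix, and monotonicity of any replacement can be checked
by the property tests' brute-force scan. Opened-vial leftovers receive the
same cap as preparations.

## RBPES integration

Per temperature band (room 20–25 °C, cold 2–8 °C):

- evidence is pre-filtered to level A+/A, medium-high consensus compliance,
  matching a.i., state and diluent, and a concentration range containing the
  final concentration (interval membership; an absent range matches);
- within a group of identical conditions (diluent, container), contradictory
  durations resolve to the **minimum** (restrictive); across condition
  groups the supported duration is the **maximum** — the evidence grants the
  extension it actually supports, contradictions do not;
- the result is capped at `min(micro_cap, 168 h)`. A micro cap of 0 h is
  interpreted as "SPC only", so the SPC duration becomes the ceiling;
- a record carrying the explicit `cold_instability` flag forces the cold
  band to the 24 h fallback. The flag is never inferred from durations;
- with no surviving evidence the band is `min(SPC, micro cap)`;
- a.i. listed in `StabilityPolicy.exceptions` may exceed the global cap, but
  only up to their configured evidence-backed override; the default map
  names `blinatumomab` with no value (the exception is documented to exist,
  its number is not), which keeps the global cap and records a note.

Increased-volume compounding: drug volume = dose / stock concentration;
final concentration = dose / (nominal bag volume + drug volume), checked
against the validated range. For the 128 mg / 6 mg/mL / 250 mL case this is
21.33 mL and 0.472 mg/mL.

Durations are hours internally; the table exporter renders whole multiples
of 24 h as days (the sources mix "24 h" and "7 days"). Mass is mg, volume
mL throughout; the exporter assumes these units.

## Monitoring

Verdicts are three-valued so reports can highlight growth even below limits:
`pass` (0 CFU), `pass_with_growth_below_limit` (0 < value ≤ limit), `fail`
(above the limit, or any growth where the mode is no-growth). Grade A cells
default to no-growth mode; the Grade C settle-plate 4 h cell carries 50 CFU;
remaining numeric cells are placeholders marked in `DEFAULT_LIMITS` —
regulatory numbers not published with the method are never hard-coded as
authoritative. A log check first scans for limit-table gaps and aborts with
the complete list.

The schedule anchors at the year's first Monday and emits exactly 26
biweekly environmental sessions (a two-week cadence covers the 52-week year
26 times; anchoring at a fixed weekday keeps the calendar arithmetic
deterministic and testable). Six-month events (particle counts,
requalification media fill, experienced-operator media fills) fall at the
anchor and anchor + 182 days; new hires get one triplicate campaign on three
consecutive days, as does initial qualification.

## Synthetic fixtures

`fixtures` generates every input family from one integer seed with Python's
`random.Random` — no wall clock, byte-identical reruns. The formulary always
contains the paclitaxel reference entry (80 mg/m², 6 mg/mL stock, 250 mL
NaCl 0.9% bag, A-level room-temperature evidence over 0.3–1.2 mg/mL plus a
24 h SPC record) and seed-dependent additional drugs drawn from a small
realistic pool. Monitoring logs mark each microbiological sample
contaminated i.i.d. at the configured rate with 1–3 CFU. What passing tests
on these fixtures shows: the rules, formulas and I/O behave as specified.
What they do not show: anything about real contamination dynamics (no
seasonality, no operator effects, no correlated excursions), real stability
literature coverage, or the content of any institution's formulary — the
fixtures make no statistical-realism claim.

## Problem sizes

Everything is desk-scale: the worked scenario is a single preparation,
property suites run on grids/enumerations of at most a few hundred cases,
and the full test suite plus the acceptance script complete in seconds.

## Known limitations

- Rubric cells, monitoring limits and matrix cells not published with the
  method ship as marked placeholders; a production deployment must fill them
  from the governing documents (drug-class rubric, Annex 1 tables).
- X is a rubric lookup, not a toxicological model; the matrix is a rule
  lookup, not a contamination-probability model; no degradation kinetics.
- The infusion-time column of the exported table is pass-through text.
- No drug-interaction checking, prescription management or pricing.
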