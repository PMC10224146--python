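# rbpes — risk assessment and predictive extended stability for anticancer compounding

`rbpes` is a decision-support engine for hospital centralized compounding
units (in Italy, *UFA* — Unità Farmaci Antiblastici) that prepare parenteral
anticancer therapy. For each prescribed preparation it answers, in the order
a pharmacist works:

1. **Added value** — is compounding justified at all, versus using an
   industrial product? A configurable decision tree over the regulatory
   context (industrial equivalent, Pharmacopoeia monograph, EU marketing
   authorization, personalization need) returns the decision and legal basis.
2. **Risk assessment** — the score `RA = X + (Y × Z)`, where `X` is the
   pharmacological risk (rubric on drug class and route), `Y = A·B·C·D` is
   the technological risk (complexity, form, route, process sterility, each
   1–5; software-assisted dose calculation lowers `A` by one unit, floored at
   4), and `Z` is an activity-volume multiplier (1.2 above 500
   preparations/year). A certified quality-assurance system (QAS) lowers RA
   by 30%, and >5-year-experienced personnel by a further 2.5%,
   multiplicatively. The final RA is classified into tertile tiers
   (low ≤ 50 < medium ≤ 175 < high) that set the QAS level to adopt.
3. **QAS self-assessment** — ten critical factors scored 1–4/N.A. per
   requirement, aggregated weakest-link; full adherence certifies the unit
   for the RA reduction and for extended stability.
4. **Microbiological cap** — a transcoding matrix maps the environment
   classification (GMP Annex 1 grades), medical-device class and current
   validation state (media fill, environmental monitoring, particle counts,
   QAS adherence) to the maximum microbiological shelf-life; the fully
   validated configuration (Grade A hood in Grade C room, closed systems
   without gas exchange) earns 168 h (7 days), anything less falls back to
   SPC-only.
5. **RBPES** — the risk-based predictive extended stability per preparation
   and temperature band: curated A+/A-level literature evidence can extend
   stability up to the microbiological cap, contradictory claims resolve to
   the most restrictive, documented cold instability triggers a 24 h
   fallback at 2–8 °C, and without acceptable evidence the band is
   min(SPC, cap). Results export as the unit's stability table.

It also evaluates environmental-monitoring logs (three-valued verdicts
against grade-dependent CFU limits), generates the annual control schedule
(biweekly environmental controls, 6-monthly requalification media fills and
particle counts, seniority-dependent operator media fills) and the media-fill
protocol (bottle, 10 bags, 5 syringes, mother bag, 3 satellite bags with
scalar dilutions; incubation 7 days at 20–25 °C then 7 days at 30–35 °C).

## Worked example

```sh
rbpes fixtures --seed 7 --out fx        # synthetic formulary, logs, site.yaml
rbpes assess --spec fx/prep.json --site fx/site.yaml
```

where `fx/prep.json` describes a paclitaxel bag — 80 mg/m² for a 1.6 m²
patient in 250 mL NaCl 0.9%, software-assisted calculation — with its
added-value context (no industrial equivalent, a.i. in the Pharmacopoeia).
The report prints:

```
added value: justified (magistral_default)
decision path: industrial_equivalent -> pharmacopoeia -> leaf_magistral
dose: 128 mg
X = 125, Y = 100, Z = 1.2
RA raw = 245, RA final = 167.2
risk tier: medium
QAS requirement: Complete NBP, with specific procedure and periodic quality control of the pharmaceutical form (validated procedure).
```

Reading: the dose is 80 × 1.6 = 128 mg; X = 125 because a cytotoxic drug is
given parenterally; A drops 5 → 4 under software assistance, B = 1
(solution), C = 5 (sterile parenteral), D = 5 (whole-process sterility), so
Y = 100; Z = 1.2 for a unit above 500 preparations/year; RA = 125 + 100 × 1.2
= 245, reduced by 30% (certified QAS) then 2.5% (experienced personnel) to
167.2 — a medium-risk preparation requiring the complete NBP quality system.

```sh
rbpes micro-cap --site fx/site.yaml
# matrix cell: A/C/closed_no_gas/all_pass
# max microbiological shelf-life: 168 h (7 days)
rbpes stability-table --formulary fx --site fx/site.yaml --out fx/table.csv
rbpes self-assess --sheet fx/qas_scores.csv
rbpes monitor-check --log fx/monitoring_log.csv
rbpes schedule --year 2023 --site fx/site.yaml
```

All inputs are plain CSV/JSON/YAML; every rubric, limit table, decision tree
and matrix cell is site-editable configuration.

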