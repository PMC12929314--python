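# nmpcea

Decision-tree cost-effectiveness model of **non-medical prescribing (NMP)**
by allied health professionals in the English NHS: dietitian supplementary
prescribers (D-SP) and therapeutic radiographer independent prescribers
(TR-IP), each compared with matched non-prescribers whose patients are
referred to another prescriber (e.g. a GP) when prescriptions need managing.

The package is for health economists and workforce planners who want to
rerun, audit or extend the model: every input (training-cost components,
activity profiles, unit costs, adjusted effectiveness summaries) lives in a
plain-text fixture per profession, and every stage — costing, effectiveness
adjustment, cost-effectiveness analysis, sensitivity analysis — is an
importable, tested function.

## The model

Training one prescriber costs, per trainee,

```
C_train = fee + c_day·d_employer + ½·c_day·(26 + 12) + c_day·d_personal + OOP
```

with `c_day = salary/365` the daily pay rate, 26 taught + 12 supervised
course days costed at 50% of work time (staff backfill), and out-of-pocket
(OOP) plus personal-study costs included or excluded as two scenarios.

Each arm sees `N = contacts/week × 48 weeks` patient contacts a year. A
contact costs the prescribing-consultation rate `c_rx` with probability
`p_req·p_use` (it needs prescription management *and* the professional uses
their own qualification) and the standard rate `c_std` otherwise; referrals
add `p_refer·c_ref` per contact:

```
C_year = N·[ p_req·p_use·c_rx + (1 − p_req·p_use)·c_std ] + N·p_refer·c_ref
```

Horizon totals put `C_train` in year 1 only and discount later service
years at 3.5% p.a. Effectiveness is the EQ-5D-5L utility index (scored via
a pluggable value set) over one year (QALY), plus 0–100 rescaled Likert
satisfaction/experience scores, adjusted for age, gender and general health
in a linear mixed model with a site random intercept and bootstrapped
(5,000 cluster-respecting replications) for CIs. Cost-effectiveness uses

```
ICER = ΔC/ΔE        NMB(λ) = λ·ΔE − ΔC        cost-effective ⇔ NMB > 0
```

at λ = £30,000/QALY, with a 5,000-iteration Monte-Carlo PSA (gamma costs,
beta probabilities, normal effect differences) feeding the CEAC, and a
one-way tornado analysis over every ranged input.

## Worked example

```python
from nmpcea import ModelConfig, make_paper_fixture
from nmpcea.cea_engine import deterministic_ce, run_psa

fx = make_paper_fixture("dietitian")
res = run_psa(fx, ModelConfig(profession="dietitian", rng_seed=1))
print(f"dC £{res.delta_cost:.0f}, dE {res.delta_effect} QALY, "
      f"ICER £{res.icer.value:.0f} ({res.quadrant}), "
      f"P(CE at £30k) {res.p_cost_effective:.0%}")
```

prints

```
dC £-10, dE -0.0122 QALY, ICER £820 (SW), P(CE at £30k) 36%
```

i.e. dietitian supplementary prescribing costs £10 less per patient-year
with a 0.0122 QALY deficit (south-west quadrant: cheaper but slightly less
effective; the ICER reads £820 saved per QALY lost), and only ~36% of PSA
draws are cost-effective at the NICE threshold — money-saving, but with
high decision uncertainty. The same pipeline is scripted end to end in
`analysis/01_training_costs.py` … `analysis/05_tornado.py`, which narrate
each stage and write tables under `results/`; the command-line entry point
`nmp-cea run --profession tr --horizon 5 --seed 1 --out results/tr` runs
everything at once.

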