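# escalape

Phase-I dose-escalation modelling toolkit: a two-parameter Bayesian
logistic dose–toxicity model with escalation-with-overdose-control
(EWOC), a mechanistic two-compartment PK + mass-action ligand-binding
simulator for target-engagement dose selection, noncompartmental PK
analysis, trial replay / operating-characteristics simulation, and
solid-tumor response endpoints — plus synthetic-data generators so the
whole pipeline runs with no external data.

## Modules

| module              | what it does |
|---------------------|--------------|
| `escalape.blrm`     | logit p(d) = log α + exp(log β)·ln(d/d_ref) dose–toxicity model; deterministic 2-D grid-quadrature posterior; toxicity-interval summaries (under <0.16 / target 0.16–0.33 / over ≥0.33); EWOC admissibility (P(p ≥ 0.33) < 0.25); escalation caps (+200% / +100%); next-dose recommendation; MTD declaration |
| `escalape.pkpd`     | stiff ODE simulation of two-compartment drug kinetics with reversible binding to circulating ligands (free/complex turnover); %inhibition summaries; population fraction with sustained suppression; dose-proportionality check |
| `escalape.nca`      | Cmax/Tmax, AUC0–tz (linear or linear-up/log-down), terminal half-life via best-adjusted-R² λz selection, power-model dose proportionality |
| `escalape.trial`    | deterministic replay of observed cohort tables; seeded trial simulation under an assumed dose–toxicity truth; operating characteristics |
| `escalape.endpoints`| target-lesion percent change, best-overall-response categorization (CR/PR/SD/PD/NE) with PR confirmation, duration of response |
| `escalape.synth`    | embedded study cohort fixtures and seeded generators for DLT outcomes, lognormal PK populations, noisy concentration series, lesion trajectories |

## CLI

```bash
escalape blrm fit   --cohorts cohorts.csv --design design.json --report out.json
escalape trial replay --cohorts cohorts.csv --design design.json
escalape trial oc   --scenario scenario.json --design design.json --nsims 500 --seed 7
escalape pkpd simulate --config pkpd.json --out profile.csv
escalape pkpd popfrac  --config pkpd.json --doses 360,500,720 --threshold 0.9
escalape nca        --input conc.csv --method linlog --out nca.csv
escalape synth study-fixtures --out fixtures/
```

Cohort tables are CSV with header `dose_mg,n_patients,n_dlt_patients`.
A design JSON holds the prior, escalation rules, provisional dose
levels and (optionally) intervals, MTD rule, grid spec and trial sizing
— see `tests/test_io_cli.py` for a complete example.

## Notes

* Posteriors are computed by tensor-product quadrature, so every
  decision is bit-reproducible; no MCMC is involved.
* All stochastic components (trial simulation, synthetic data,
  population PK) take explicit integer seeds.
* The PK/binding parameter set shipped in
  `escalape.pkpd.study_like_parameters()` is illustrative, not an
  estimate: it is chosen so that sustained >90% suppression of the
  first ligand sweeps the 20–95% population range across 360–720 mg
  every-3-weeks, while the second, more potently bound ligand stays
  >90% suppressed even at the lowest dose.
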