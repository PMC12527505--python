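# agtkit

Simulation, hierarchical Bayesian modelling and group statistics for
effort-based decision-making on the **Apple Gathering Task (AGT)**.

## The scientific problem

Motivational dysfunction — a reduced willingness to exert effort for
reward — is a core feature of depression and of apathy syndromes more
broadly. The AGT measures it directly: on each of 80 trials a participant
sees an offer of reward (3, 6, 9 or 12 apples) for a required grip force
(20–80 % of their individually calibrated maximum voluntary contraction,
MVC) and chooses to accept or refuse. Outcomes are deterministic; every
reward × effort combination appears five times; the exertion phase is
omitted on a quarter of accepted trials to limit fatigue.

Raw acceptance rates confound several latent processes. `agtkit`
implements a computational decomposition: the decision value of an offer
with coded reward *r* (apples / 12) and coded effort *e* (proportion of
MVC) is

    V(r, e) = K + LinR·r + LinE·e + E²·e²
    P(accept) = 1 / (1 + exp(−V))

where **K** is the acceptance bias (the overall tendency to accept,
independent of the offer), **LinR** the linear reward sensitivity,
**LinE** the linear effort sensitivity and **E²** the quadratic effort
sensitivity (negative values make effort disproportionately costly at
high force). Because LinE and E² trade off strongly on this design, the
package's default "winning" model clamps LinE at the constant −15
(`constrained_winning_spec()`), leaving K, LinR and E² free.

Subject-level parameters are estimated by hierarchical (partial-pooling)
Bayesian inference: θᵢₚ ~ Normal(μ₍g₎ₚ, σ₍g₎ₚ), with prior-sharing schemes
for case–control designs (`pooled`, `split_on(parameter)`, `split_all`).
Candidate models over the term family {K, LinR, R², LinE, E², R×E} are
compared by PSIS-LOO. Because no participant data are distributable, the
package ships a first-class generative simulator whose cohorts reproduce
the empirical structure of the task: wide between-subject acceptance
spread (below 40 % up to exactly 100 %), acceptance falling with effort
and rising with reward, a reward × effort interaction, and group
differences confined to K (the remitted/current-depression deficit,
d ≈ 0.39).

Audience: computational-psychiatry and behavioural-modelling researchers
who need a tested, fully reproducible reference pipeline for AGT-style
binary effort-discounting data.

## Worked example

```python
import numpy as np
from agtkit import (GroupSpec, constrained_winning_spec, generate_cohort,
                    fit_hierarchical, point_estimates, SamplerSettings)
from agtkit.validation import posterior_predictive_acceptance
from agtkit import stats as st

model = constrained_winning_spec()          # V = K + LinR*r - 15*e + E2*e^2
population = GroupSpec(label="HV", age_effect_on_k=0.0)
cohort = generate_cohort([population], [40], seed=7, model=model)

fit = fit_hierarchical(cohort, model,
                       settings=SamplerSettings(chains=4, warmup=500,
                                                draws=500, thin=5), seed=1)
est = point_estimates(fit)
truth = cohort.participants.set_index("participant_id")
for p in fit.free_params:
    r = np.corrcoef(est[p], truth[f"true_{p}"].loc[est.index])[0, 1]
    print(f"{p}: posterior-mean vs generating r = {r:.3f}")

ppc = posterior_predictive_acceptance(fit, cohort)
print(ppc)

table = st.aggregate_acceptance(cohort.trials)
anova = st.rm_anova(table, between=None, covariate=None)
print(anova.loc[["reward", "effort", "reward:effort"],
                ["F", "df1_gg", "df2_gg", "p_gg"]].round(3))
```

prints

```
K: posterior-mean vs generating r = 0.804
LinR: posterior-mean vs generating r = 0.792
E2: posterior-mean vs generating r = 0.802
Posterior-predictive check: n=40, Pearson r (observed vs predicted) = 0.9999
                     F  df1_gg   df2_gg  p_gg
effect
reward          52.285   1.821   71.001   0.0
effort         113.439   1.785   69.600   0.0
reward:effort    8.885   3.384  131.970   0.0
```

Reading the output: the hierarchical fit recovers the generating
subject-level parameters well at n = 40 (r ≈ 0.8 each), the fitted model
recapitulates individual differences in acceptance almost perfectly
(posterior-predictive r > 0.999), and the model-agnostic repeated-measures
ANOVA on arcsine-transformed acceptance rates shows the expected main
effects of reward and effort and their interaction, with
Greenhouse–Geisser-corrected degrees of freedom (sphericity is violated on
this 4-level design, hence df1 ≈ 1.8 rather than 3).

A command-line interface covers the same pipeline
(`agtkit simulate | fit | compare | recover | ppc | analyze | report`);
run `agtkit --help`.

## Layout

| module | contents |
| --- | --- |
| `agtkit.task_design` | offer grid, trial schedules, MVC calibration, exertion-omission scheduling |
| `agtkit.choice_models` | value function, logistic choice rule, likelihood, model family |
| `agtkit.synthetic_cohort` | generative simulator: populations, choices, exertion, questionnaires |
| `agtkit.inference` | Metropolis-within-Gibbs hierarchical fitting, prior schemes, PSIS-LOO comparison, diagnostics |
| `agtkit.validation` | parameter recovery, posterior-predictive checks |
| `agtkit.stats` | RM-ANOVA (Greenhouse–Geisser), planned contrasts, ANCOVA, EFA (Promax), correlations, power, exclusions |
| `agtkit.io` / `agtkit.config` / `agtkit.cli` | CSV exchange, YAML config, manifests, CLI |

See `docs/methods.md` for the model, sampler and simulator details.
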