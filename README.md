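# impquant

Quantifiable implementation evaluation for multi-component interventions
delivered in stepped-wedge cluster randomized trials.

Effect analyses of complex workplace interventions risk a type III error:
rejecting a program theory because the program was never implemented, not
because it does not work. `impquant` turns routine process-evaluation records
— deliverer logbooks and an end-of-intervention participant questionnaire —
into implementation scores on a 0–100 scale that can be compared across
intervention components, trial steps and settings, and carried into
effectiveness analyses.

## The model

For a protocol of planned sessions with durations summing to `H` hours:

**Delivery.** Dose `D = D_d / D_i` is the fraction of intended sessions held.
Each held session gets a content score `C` (mean of its scored success
criteria, plus the scored physical intensity for training sessions), a quality
score `Q` (mean of the deliverer's understanding index, contribution index and
self-rated performance) and fidelity

```
F = (C + Q) / 2
```

Organizational-level implementation is `(D + F) / 2`.

**Receipt.** Participation weights presence by session duration:
`P_s = presence × duration / H`. Individually received sessions use 0/1
attendance; team-received participatory-ergonomics sessions are scored per
team as the mean of a participation score (attending members over the required
representative quota, capped at 1) and a continuity score (members attending
every held session over the quota), broadcast to all team members.
Responsiveness `R` is the mean of satisfaction, intervention-related social
support and group motivation, each itself a 0/50/100-scored index.

**Exposure and implementation**, per participant and session:

```
E_s = F_s × P_s        E_all = Σ E_s
I_s = E_s × R          I_all = Σ I_s
```

so `I_all ≤ E_all ≤ participation ≤ 1`, any zero factor zeroes
implementation, and canceled sessions contribute nothing. Cronbach alpha and
one-way ANOVA across steps/workplaces complete the analysis surface.

## Worked example

No individual-level records of the motivating trial are deposited, so the
package ships a synthetic-trial generator that reproduces its published
structure (4 workplaces, 4 steps of 126/146/158/164 participants, 58 teams,
753 intended sessions across three components):

```python
from impquant import generate_trial, score_trial, percent

dataset, truth = generate_trial(seed=3)
scores = score_trial(dataset)
print(scores.delivery_summary(by="component")[["stratum", "n_intended", "n_held", "dose"]])
print(scores.summary(by="total"))
```

```
stratum  n_intended  n_held     dose  dose_pct
    CBT          80      78 0.975000        98
     PE         172     171 0.994186        99
     PT         501     464 0.926148        93
    all         753     713 0.946879        95

     level stratum_kind stratum        measure   n      mean        sd
individual        total     all       fidelity 594 91.751246  1.453833
individual        total     all       exposure 594 44.847939 10.670306
individual        total     all  participation 594 48.624621 11.421855
individual        total     all responsiveness 286 89.479235  5.105363
individual        total     all implementation 286 42.951022  9.793109
```

Reading: 713 of 753 intended sessions were held (dose 95%); sessions were
delivered with ~92% fidelity; participants were present for ~49% of the
planned intervention hours, hence exposed to ~45% of it; among the 286
questionnaire responders, responsiveness was ~89% and total implementation
~43%. Fidelity, exposure and participation are computed for everyone (n=594);
responsiveness and implementation only for responders.

The same pipeline runs from the shell:

```
impquant simulate --seed 3 --out data/
impquant validate --data data/
impquant score --data data/ --out scores/
impquant compare --scores scores/individual_scores.csv --by workplace --measure implementation
```

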