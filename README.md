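# culturesim

Agent-based simulation of cultural transmission in age-structured
populations, with tools for asking which individual-level transmission
pathways can — and cannot — be inferred from population-level patterns.

## The problem

Cultural traits (skills, beliefs, practices) spread through populations along
different pathways: **vertical** (parent to offspring at birth), **horizontal**
(between peers of the same age group), **oblique** (from older to younger
individuals, excluding one's own parent), **age-neutral** (from anyone —
unbiased drift), and **mixed** (a per-event blend of horizontal and oblique).
Empirical studies usually observe only population-level summaries — variant
frequencies, diversity indices, turnover — and try to reason backwards to the
individual-level process. `culturesim` generates the forward expectations: it
simulates a constant-size population of `N` individuals in five 10-year age
classes, each carrying one variant (of five) of a trait per transmission mode,
and tracks variant frequencies over time. From ensembles of runs it derives
the probability distributions of the standard statistics and quantifies, mode
pair by mode pair, whether those distributions can be told apart.

## Model in brief

Each time step (10 years): individuals age one class; those leaving class 5
die, the rest die with hazard `p_death`; individuals in classes 2–3 reproduce
(uniformly, with replacement) until size `N` is restored, each newborn
receiving a vertical copy of every trait; then every individual, in random
order and independently per non-vertical trait, engages in a transmission
event with probability `p_w`, adopting the variant of a random partner from
the mode's eligible set. Every copy — at birth or in life — is corrupted with
probability `mu` to a random variant. Optional conformity bias reweights
partner-variant frequencies `p_k = n*_k/N* + b (k̂ n*_k/N* − 1)`, favouring
variants above the relative majority `1/k̂`.

Per run (burn-in + 200 recorded steps) and per mode, the package computes the
joint variant frequencies, the most-common-variant frequency `p_max`, the
richness `k`, the Shannon diversity `d_s = −Σ p_k ln p_k`, and `t_max`, the
mean number of consecutive steps a variant stays the most common. Two modes
are compared through the area of overlap between the ensemble distributions
of a statistic, `O_xy = 1 − K_xy` (Kolmogorov–Smirnov distance between the
ECDFs); `O_xy < 0.2` declares the modes distinguishable. Given an observed
value `z`, posterior mode probabilities `P(y|z) = f(z|y)P(y)/f(z)` are
estimated from histogram densities or by (multinomial) logistic regression.

## Worked example

```python
from culturesim import ParameterSet, EnsembleSpec, run_ensemble
from culturesim.ensemble import pairwise_report, format_matrix

spec = EnsembleSpec(params=ParameterSet(N=50, mu=0.1, p_w=1.0),
                    n_runs=500, base_seed=0)
res = run_ensemble(spec)
print(res.summary.head(5).to_string(index=False))
print(format_matrix(pairwise_report(res, "t_max")))
```

```
 run  seed        mode  p_max  k      d_s    t_max
   0     0    vertical   0.32  5 1.461377 9.523810
   0     0  horizontal   0.60  4 1.072443 3.636364
   0     0     oblique   0.48  5 0.998773 5.000000
   0     0 age_neutral   0.30  5 1.536309 4.081633
   0     0       mixed   0.58  5 1.205697 5.000000
overlap area O_xy (* = distinguishable at O < 0.2)
                  vertical   horizontal      oblique  age_neutral        mixed
vertical             1.00         0.02*        0.30         0.00*        0.02*
horizontal           0.02*        1.00         0.17*        0.46         0.92
oblique              0.30         0.17*        1.00         0.03*        0.22
age_neutral          0.00*        0.46         0.03*        1.00         0.44
mixed                0.02*        0.92         0.22         0.44         1.00
```

Each summary row is one surviving run and one mode: at the final recorded
step this run's vertical trait had its most common variant at frequency 0.32
with all 5 variants present, while `t_max` says the vertical trait's most
common variant persisted 9.5 steps on average over the 200-step window versus
3.6 for the horizontal trait — vertical transmission changes slowest. The
matrix shows that under this high-change scenario the persistence time
separates vertical from horizontal and age-neutral transmission almost
completely (overlap ≈ 0), while vertical vs oblique (0.30) and horizontal vs
age-neutral (0.46) remain ambiguous — different individual-level processes
producing similar population-level dynamics (equifinality).

The same analyses are available from the shell:

```sh
culturesim ensemble -N 50 --mu 0.1 --p-w 1 --runs 3000 --seed 1 --out runs/
culturesim report-overlap --ensemble-dir runs/ --statistic t_max
culturesim report-posterior --ensemble-dir runs/ --modes vertical,oblique --out posterior.csv
culturesim report-conformity -N 100 --b-values 0,0.01,0.02,0.03 --runs 2000 --out conformity.csv
```

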