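# Methods

## Model

A population of fixed size `N` is divided into five age classes of 10 years
each. Each individual carries five discrete cultural traits, one per
transmission mode (vertical, horizontal, oblique, age-neutral, mixed); each
trait takes one of five neutral variants. One simulation run is a burn-in
phase followed by a recorded window (default 200 steps); a time step is a
demographic phase followed by a transmission phase.

**Demography.** Within a step: (1) every individual advances one age class;
individuals leaving class 5 are removed — i.e. class-5 members live one full
step and die on leaving; (2) each remaining individual dies independently
with hazard `p_death`; (3) parents are drawn uniformly at random *with
replacement* from survivors currently in classes 2–3 until size `N` is
restored. Newborns enter class 1 with a parent link and a vertical copy of
every trait, each copy passed through mutation. If no eligible parent exists
while the population is below `N`, the run is extinct; extinct runs are
counted and discarded from ensembles without replacement. A positive hazard
yields the expected pyramid-shaped age structure (monotone mean class sizes),
which the test suite verifies over long runs.

**Transmission.** Individuals update asynchronously: a fresh random visiting
order is drawn each step, and partner sets are evaluated against current
state, so a partner may already have updated within the same step. Per
non-vertical trait and step, an event occurs with probability `p_w`
(independently across traits). Partner sets: horizontal — same age class,
excluding self; oblique — strictly older classes, excluding the focal's
living parent (siblings are allowed; the link to a dead parent is dropped);
age-neutral — everyone but self; mixed — the event is oblique with
probability `p_mix`, else horizontal. An empty partner set makes the event a
no-op (no retry). Every copy is corrupted with probability `mu` to a variant
drawn uniformly from all five (so the retention probability is
`1 − mu + mu/5`, analytically convenient); drawing from the other four only
is available as `mutation_includes_current=False`.

**Conformity.** With bias strength `b > 0` the adoption probability of
variant k within a partner set of size `N*` is
`p_k = n*_k/N* + b (k̂ n*_k/N* − 1)`, where `k̂` counts variants present in
the whole population (a partner-set-local count is available but off by
default). The formula can produce negative weights (an absent variant gets
`−b`); weights are clamped at zero and renormalized — the minimal repair that
preserves the bias direction. If every weight clamps to zero the event is a
no-op. At uniform frequencies `1/k̂` the bias term vanishes exactly, which is
asserted as a property test.

**Initial conditions.** Founders are assigned ages uniformly across the five
classes and all carry variant 1 of every trait; the burn-in (default 100
steps, several complete population turnovers) erases both the uniform age
structure and the monomorphic start before recording begins.

## Statistics

Per run and mode: the joint variant frequencies `[p_1..p_5]`, the
most-common-variant frequency `p_max`, the richness `k`, and the Shannon
diversity `d_s = −Σ p_k ln p_k` are taken from a single snapshot at the final
recorded step (one sample per run; composition statistics describe a point in
time). `t_max` — the mean number of consecutive steps a variant stays the
most common — uses the whole recorded window: the most-common series (ties
broken to the lowest variant label, deterministic and label-stable) is split
into maximal constant runs and the mean run length returned, *including* the
window-censored first and last runs, so `t_max` = window length / number of
runs. Censoring biases `t_max` slightly downward for slow modes, negligibly
at 200 steps. Diversity uses natural logarithms; the base cancels from all
overlap comparisons.

Within-age-group diversity applies the same Shannon index to each age class's
members separately (empty classes give missing values). The one-step
mutant-spread distribution — the probability that a variant introduced at
frequency 1 by an individual of a given age class has frequency 0..N after
one full time step — is estimated by Monte Carlo (background ages drawn as at
initialization); for N ≤ 6 the test suite checks the transmission phase
against exhaustive enumeration over all visiting orders and partner choices.

## Distinguishability and inference

For a scalar statistic, the area of overlap between two modes' ensemble
distributions is `O_xy = 1 − K_xy` with `K_xy = sup_z |F_x(z) − F_y(z)|`
evaluated over the pooled sample points (right-continuous ECDFs; on ties the
lowest attaining `z` is reported). The identity is exact for densities with a
single crossing, the typical case here. Modes are declared distinguishable
when `O_xy < 0.2` (the conventional 80% power cut-off); the threshold is
configurable. For the joint variant-frequency distribution the one-crossing
identity does not generalize, so count vectors are sorted descending
(removing the label exchangeability created by symmetric mutation) and the
overlap coefficient `Σ_cells min(f̂_x, f̂_y)` — equal to 1 minus the
total-variation distance — is computed over exact cells of the discrete
simplex. This is a documented substitute for an unspecified multivariate
binning and tends to read lower than a smoothed estimate at moderate
ensemble sizes.

Posterior mode probabilities `P(y|z) = f(z|y)P(y) / Σ_γ f(z|γ)P(γ)` use
uniform priors by default. The histogram method estimates `f(z|y)` on a
common grid with `⌈√(smallest sample size)⌉` bins over the pooled range; a
`z` outside every estimated support returns the priors with an
`in_support=False` flag. The logistic method fits an unpenalized
(multinomial) logistic regression of mode on `z`, with samples weighted to
the priors; with default regularization the curves flatten badly, hence pure
maximum likelihood. The two methods agree within 0.05 over the central 90%
of values on well-sampled problems (tested).

## Parameters

| name | meaning | default | notes |
|---|---|---|---|
| `N` | population size | 50 | explored 25/50/100 |
| `mu` | mutation per transmission event | 0.1 | explored 0.01/0.05/0.1 |
| `p_w` | per-step interaction probability | 1.0 | explored 0.5/0.75/1; lifetime events = 5·p_w |
| `p_mix` | oblique share of mixed events | 0.5 | |
| `b` | conformity strength | 0 | explored 0–0.03 |
| `p_death` | per-step hazard, pre-terminal classes | 0.1 | not derivable from the published description; chosen a priori as a flat adult hazard per 10-year step and held fixed |
| `burn_in_steps` | discarded steps | 100 | ≥ several turnovers |
| `recorded_steps` | recorded window | 200 | |

Ensembles default to 3,000 runs (the reference analyses used 30,000; at
3,000 the Monte-Carlo error on an overlap area is ≈0.01–0.02, adequate for
desk-scale work and reachable upward by configuration). Per-run seeds are
`base_seed + run index`; one run carries all five traits, so every mode's
sample in an ensemble shares demographic histories within runs.

## Implementation notes

The per-step update loop is numba-compiled. Partner sets are never
materialized: per-(trait, age-class, variant) count tables are maintained
incrementally, and drawing a partner uniformly then copying its variant is
replaced by drawing a variant from the set's count vector — distributionally
identical, O(variants) per event, and still asynchronous because the tables
are updated after every adoption. The compiled path is validated against
exhaustive enumeration (N ≤ 6) and closed-form calibrations (mutation
retention, binomial death counts, 5·p_w lifetime events) in the test suite.
All randomness in a run flows from one seeded generator, and runs are
bit-reproducible from `(parameters, seed)`.

## What the simulations do and do not show

The generator *is* the model under study: synthetic ensembles establish
theoretical limits to inference under the model's own assumptions — neutral
traits, constant `N`, asexual reproduction, well-mixed interaction within
partner sets, exact knowledge of the most common variant at every step. Real
cultural datasets violate several of these (fitness effects, demographic
change, network structure, sparse/irregular sampling), so a pair of modes
distinguishable here need not be distinguishable in field data; the converse
direction — modes indistinguishable even under ideal conditions — is the
robust conclusion. Known limitations: continuous-valued traits, non-neutral
traits, varying population size and network- or space-structured interaction
are out of scope; the joint-distribution overlap method is a substitute for
an unspecified multivariate procedure and its absolute values should be
compared only within this package.
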