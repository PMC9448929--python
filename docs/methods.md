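# Methods

This note documents the models, parameters and numerical choices behind
`connectotype`: a pipeline that groups populations of structural
connectivity (SC) matrices into architecture types, simulates each type's
neural dynamics with Kuramoto oscillator models, and quantifies
differential vulnerability to cumulative hub lesions.

## Data model

A subject is a symmetric, nonnegative, zero-diagonal weight matrix `W`
over a parcellation — by default 100 nodes nested in the seven canonical
cortical systems (Visual, Somatomotor, Dorsal Attention, Ventral
Attention, Limbic, Control, Default), with unequal system sizes
(14/16/13/12/10/17/18). All subjects are placed on a common scale by
rescaling so the mean unique off-diagonal weight equals a configured
target (default `1e-4`; the target is a parameter, not a physical
constant). Reparcellation averages fine edges per system pair; the
system-level matrix carries within-system means on its diagonal, and
"whole-network" edge vectors are the off-diagonal upper triangle (21
dimensions for 7 systems), so constant or within-system entries never
leak into whole-network similarity.

## Synthetic population generator

The generator emulates a population regime observed in large diffusion
cohorts: all subjects mutually very similar (system-level Pearson r near
0.9) yet separable into two architecture types. Each subject's expected
fine edge weight is

```
E[W_ij] = T_g[s(i), s(j)] * F_ij * G_g,ij
```

with three factors:

* `T_g` — the archetype's 7x7 system-level template. Archetype 2 differs
  from archetype 1 in two *independent* ways: (i) a mean-preserving
  within/between weight shift (within-system entries x(1 + shift),
  between-system x(1 − shift·b)), and (ii) a fixed mixed-sign relative
  perturbation of the between-system pattern. The distinction matters
  because Pearson similarity is scale-invariant: the uniform shift is
  invisible to whole-network similarity and instead drives the
  graph-metric and synchronization contrast, while only the pattern
  perturbation moves the across-type correlation. `shift` defaults to
  2.85x the pattern contrast, which puts archetype 2's between-system
  coupling at ~0.6x archetype 1's — the regime in which the reported
  ~1.6x critical-coupling ratio between architecture types emerges.
* `F` — a shared fine-scale heterogeneity field, lognormal with log-sd
  `fine_structure_sigma = 2.0`. Deterministic tractography weights
  (streamline counts) span orders of magnitude; this heavy tail is not
  decoration: with tame fine structure, mean-normalized coupling matrices
  are effectively mean-field and every architecture synchronizes at the
  same threshold, erasing the dynamic phenotype. `F` is normalized to
  unit mean within every system block, so it cancels exactly under
  reparcellation.
* `G_g` — archetype-specific lognormal "fingerprints" on within-system
  edges only (log-sd = contrast, unit block means). These plant the
  group signal that single within-system edge subsets carry; between-
  system subsets carry only the template pattern.

Subject-level variation is independent multiplicative lognormal noise per
unique edge (log-sd `sigma`), followed by symmetrization and rescaling.
Both sexes draw from the same two archetypes. Seeding is hierarchical:
subject `i` uses the stream `(master_seed, i)`, so enlarging a population
never reshuffles existing subjects.

**Calibration.** `contrast = 0.28` and `sigma = 0.28` were chosen by grid
search (`synth.calibrate`) so that a population's mean system-level
within-type and across-type correlations match the empirical anchors
0.942 and 0.906; realized values are 0.945 / 0.907 (3-seed average). At
zero noise a subject reparcellates exactly to its template (up to the
global rescale), because all fine factors have unit block means.

**What the generator does not emulate:** spatial autocorrelation and
distance-dependent wiring, per-subject sparsity-pattern differences (the
fine heterogeneity field is shared), hemispheric structure, and realistic
degree distributions. Passing tests therefore show the pipeline recovers
planted structure of the calibrated kind — not that it would segment any
particular empirical cohort.

## Similarity clustering

Subjects are compared by Pearson correlation of their edge vectors;
architecture types are modules of the subject-similarity matrix under
modularity maximization

```
Q(gamma) = (1/2m) * sum_jh [A_jh − gamma * s_j s_h / (2m)] * delta(sigma_j, sigma_h)
```

with the configuration null (`s` = row strengths, `2m` = total weight)
and self-pairs included, so one module at gamma = 1 scores exactly 0. We
normalize by total weight (the standard convention; it rescales Q without
moving the argmax). Negative similarities are zeroed before optimization
(entries here are ~0.9, so this is a no-op in practice); a signed option
exists. Optimization is greedy multi-level (Louvain) with 10–20 seeded
restarts; ties break toward higher Q, then fewer modules, then the
lexicographically smallest canonical labeling, making runs reproducible.

The resolution is tuned to the *minimum* grid value (default 0.5–1.5,
step 0.01) whose best partition has exactly two modules, each holding at
least 5% of subjects; an exhaustive-enumeration oracle (all set
partitions, m <= 8) backs the optimizer in tests. Robustness checks:

* **k-fold cross-validation** — per fold, the gamma search is re-run on
  the retained subjects, fold modules are matched to the whole-sample
  reference by maximal overlap (Hungarian assignment on the contingency
  table), and each withheld subject joins the module with the highest
  mean similarity to its members.
* **subset accuracy** — similarity built from one within- or
  between-system edge subset only, re-clustered and scored against the
  whole-network reference; a gamma-search failure is reported as a
  status ("no two comparable modules"), not an error.

## Graph metrics

Weights convert to lengths by `1/w`; distances are Dijkstra on the length
graph. Global efficiency is the mean inverse distance over ordered pairs
(unreachable pairs contribute 0, keeping GE defined under severe
lesioning); mean shortest path length averages reachable ordered pairs
and reports the unreachable count. Betweenness is the normalized Brandes
centrality, which for undirected graphs equals the ordered-pair
formulation `BC_j = (1/((n−1)(n−2))) * sum rho_gh(j)/rho_gh`. Clustering
coefficient defaults to the binary formula `2 t_j / (k_j (k_j − 1))` on
the `W > 0` graph (on fully dense synthetic matrices it is identically 1
— reported, not hidden); a weighted geometric-mean variant is a flag.
With inverse-weight lengths, GE scales linearly under uniform weight
scaling — this is why the common edge-mean rescale across subjects
matters, and it is asserted in tests.

## Kuramoto dynamics

Each region is a phase oscillator
`dtheta_j/dt = omega_j + K * sum_h C_jh sin(theta_h − theta_j)`, with C
the subject's SC normalized to mean off-diagonal 1 (zeros included), no
1/N factor (the normalization carries the scale), intrinsic frequencies
2*pi*Normal(60, 1) Hz in rad/s, and uniform initial phases. The order
parameter `r(t) e^{i phi(t)} = (1/N) sum_j e^{i theta_j}` yields
synchrony (time-mean of r after burn-in) and metastability (its standard
deviation).

Integration is classical fixed-step RK4 (numba-compiled; a pure-numpy
reference path is cross-checked in tests), default `dt = 1e-4` s (~170
steps per 60 Hz cycle), r(t) recorded every 1 ms. A stability guard
rejects steps where `dt * (max|omega| + K * max row sum of C)` exceeds
0.1 rad; with heavy-tailed coupling rows this caps K near 1.5 at the
default step (use `dt = 5e-5` beyond). Closed-form anchors: uncoupled
phases match `theta0 + omega t` to < 1e-6 rad over 1 s, and a two-
oscillator dyad locks exactly when `K >= |delta omega| / 2`, tested at
0.8x and 1.2x the threshold against the analytic locked order parameter.

Coupling sweeps hold omega/theta0 fixed per replicate across the K grid
(a resampling flag exists); the synchrony critical coupling is the first
grid K reaching 90% of that network's own maximum synchrony, the
metastability critical coupling the argmax-K of metastability (first on
ties), and the synchrony–coupling curve is summarized by its trapezoidal
area. Desk-scale profiles (T = 3–5 s after a 1–2 s burn-in, transition-
resolving K grids) are used throughout the tests and analysis scripts;
they resolve the K ~ 0.2–0.5 transition these networks exhibit. Group
comparisons of critical couplings use matched frequency/phase draws
across archetype pairs (common random numbers) with paired one-sided
signed-rank tests — the draw-to-draw variability otherwise dominates the
structural effect at small n.

## Lesioning

Nodes are ranked within each subject by connectivity (weighted strength
by default; binary degree is uninformative on near-dense matrices), rank
positions are averaged across the population, and the shared descending
order defines cumulative lesions at the 5/10/25/50/75% levels
(`ceil(level * n)` nodes; higher levels strictly contain lower ones).
Lesioned nodes keep their rows/columns as zeros — they remain in the
ensemble as disconnected oscillators, so N in the order parameter is
constant and severe lesions manifest as lost synchronization rather than
a smaller ensemble (a deletion flag exists). Coupling matrices are
normalized once, before lesioning, and not renormalized after (a flag
exists): renormalizing would mask the lesion's loss of total coupling.

## Statistics

Group comparisons are one-way ANOVA with module assignment as the factor,
followed by Tukey-Kramer (studentized range, valid for unequal group
sizes). Groups are then merged into *pairing classes* by transitive
closure of non-significant pairs at alpha = 0.05 — the "same color = not
distinguishable" summary tables; transitivity can chain non-adjacent
groups and is documented as such. A quantile-quantile linearity summary
(R^2 against normal quantiles) is available as a normality screen but is
logged, not enforced. ANOVA calibration is verified on 500 null
simulations (empirical type-I error within [0.03, 0.07] at alpha = 0.05).

## Problem sizes used in tests and scripts

Tests and the acceptance script run at desk scale, chosen as the package's
own study conditions: populations of 20 subjects per archetype per sex at
100 nodes for clustering and subsets; 10 subjects per archetype (one sex)
for the critical-coupling comparison at T = 3 s per coupling value;
lesion-dynamics checks on 2–6 subjects. The full 100 s simulation length
is available through the CLI/config but is not needed to resolve any
quantity the tests assert.

## Known limitations

* The two-archetype construction is low-rank: real cohorts vary along
  many axes, and the minimum-resolution rule can split 40-subject
  samples imperfectly (mean adjusted Rand ~0.94, occasionally ~0.6).
* Binary clustering coefficient is uninformative on fully dense
  matrices; the weighted variant is the meaningful one there.
* Critical couplings are grid-quantized; the reported values inherit the
  grid step.
* The delay-differential model variant, hemodynamic forward modelling,
  and biomechanically informed lesion patterns are out of scope.
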