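# connectotype

Architecture types in populations of brain structural connectomes, the
neural dynamics they generate, and their differential vulnerability to
targeted lesions.

Human white-matter wiring is subject-specific, which complicates any
attempt to reason about "the" brain's response to disease or traumatic
injury. This package implements a population-level answer: collapse each
subject's structural connectivity (SC) matrix to a system-level edge
vector, group subjects into *architecture types* by modularity
maximization on their similarity matrix, simulate each type's collective
neural dynamics with Kuramoto oscillator models, and measure how the
types diverge when network hubs are cumulatively severed — a topological
proxy for traumatic brain injury. It is written for computational
neuroscientists and network scientists who want a tested, reproducible
version of this analysis chain, with a calibrated synthetic-population
generator standing in for restricted cohort data.

## The models

**Architecture typing.** Subjects are compared by Pearson correlation of
their system-level edge vectors (7x7 parcellation, 21 unique edges),
giving a subject-by-subject similarity matrix A. Types are modules that
maximize

    Q(γ) = (1/2m) Σ_jh [A_jh − γ s_j s_h / (2m)] δ(σ_j, σ_h)

with the configuration null, at the smallest resolution γ producing two
nontrivial modules. Robustness is checked by 5-fold cross-validation and
by re-clustering from single within-/between-system edge subsets.

**Dynamics.** Each region is a phase oscillator

    dθ_j/dt = ω_j + K Σ_h C_jh sin(θ_h − θ_j),   ω_j ~ 2π·N(60, 1) Hz,

with C the subject's SC normalized to mean off-diagonal 1. The order
parameter r(t) = |mean_j e^{iθ_j}| yields *synchrony* (its time mean)
and *metastability* (its standard deviation); sweeping K locates each
network's critical couplings (first K within 10% of its maximum
synchrony; K of peak metastability).

**Lesioning.** Nodes are ranked by population-averaged strength rank and
cumulatively severed at the 5/10/25/50/75% levels; graph metrics (global
efficiency, path length, betweenness, clustering) and the oscillator
dynamics are recomputed at every level. Group differences are tested
with one-way ANOVA plus Tukey-Kramer correction, summarized as pairing
classes of statistically indistinguishable groups.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
import connectotype as ct

# a calibrated synthetic population: 2 sexes x 2 planted architecture
# types x 20 subjects, 100-node parcellation in 7 systems
spec = ct.PopulationSpec(n_per_group=20, seed=7)
subjects, labels = ct.generate_population(spec)

# cluster one sex at the system level
idx = labels.index[labels.sex == "male"]
vecs = [ct.vectorize_edges(ct.reparcellate(subjects[i], spec.coarse_parcellation))
        for i in idx]
sim = ct.similarity_matrix(vecs)
cfg = ct.ModularityConfig(n_restarts=10, seed=7)
gamma, part = ct.find_min_gamma(sim, cfg)
acc, _ = ct.crossval_accuracy(sim, 5, cfg, seed=7, reference=part)
print(gamma, part.n_modules, acc)
```

prints `1.01 2 0.95`: the first resolution that splits the 40 male
subjects yields exactly two modules, and 5-fold cross-validation
re-assigns 95% of withheld subjects to their module. The module-by-
planted-type contingency (from `analysis/02_cluster_architectures.py`)
shows the split is the planted one — 39 of 40 subjects on the diagonal —
and the generator's realized similarity levels (within-type r = 0.934,
across-type r = 0.896 for this draw) sit at the calibrated regime.

The numbered scripts under `analysis/` run the full narrative on a
generated population and print what they find at each stage:

1. `01_generate_population.py` — population + similarity levels
2. `02_cluster_architectures.py` — types per sex, cross-validation,
   subset classifiers (here the best single-system classifier assigns
   95–97.5% of subjects correctly; several between-system subsets fail
   to produce two comparable modules at all)
3. `03_graph_metrics.py` — metric distributions and their module
   dependence (mean betweenness separates the two types across both
   sexes, F = 89.5, with sexes of the same type statistically
   indistinguishable)
4. `04_coupling_sweeps.py` — synchrony/metastability vs K, critical
   couplings per module (the within-system-concentrated type
   synchronizes later in both sexes: mean synchrony critical coupling
   0.35 vs 0.26 in males, 0.32 vs 0.28 in females; ANOVA F = 8.0,
   p = 0.001)
5. `05_lesion_experiment.py` — metrics and dynamics under cumulative
   hub lesions (global efficiency decreases monotonically from
   4.4e-4 to 4e-6; peak synchrony falls 0.999 → 0.956 → 0.766 → 0.240
   at the 0/5/25/75% levels)
6. `06_group_statistics.py` — the combined ANOVA/Tukey-Kramer report:
   betweenness and the deeper-lesion efficiencies split the groups into
   the pairing classes {M1, F1} and {M2, F2} — the two architecture
   types cut across sex

A `connectotype` console script exposes the same stages
(`generate | cluster | metrics | simulate | lesion | report | run`), with
`run` driven by a YAML config.

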