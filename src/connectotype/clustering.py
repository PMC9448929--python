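"""Architecture-type discovery: subject similarity + modularity clustering.

Subjects are compared by the Pearson correlation of their edge vectors
(system-level for the whole network, fine-level for edge subsets), collected
in a subject-by-subject similarity matrix.  Architecture types are the
modules of that matrix under resolution-tuned modularity maximization

    Q(gamma) = (1/2m) * sum_jh [A_jh - gamma * s_j s_h / (2m)] delta(sig_j, sig_h)

with the configuration null P_jh = s_j s_h / (2m) (s = row strengths,
2m = total weight).  The resolution gamma is tuned to the *minimum* grid
value producing a nontrivial grouping, defined as exactly two modules each
holding at least a minimum fraction of subjects.  Robustness checks: k-fold
cross-validation of module assignment and re-clustering from single
within-/between-system edge subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
import networkx as nx
from networkx.algorithms.community import louvain_communities
from scipy.optimize import linear_sum_assignment

from .connectome import (
    ConnectomeMatrix,
    EdgeVector,
    reparcellate,
    vectorize_edges,
)
from .parcellation import Parcellation


class GammaSearchError(RuntimeError):
    """No resolution in the grid produced exactly two nontrivial modules."""


@dataclass(frozen=True)
class SimilarityMatrix:
    """Subject-by-subject Pearson correlations of edge vectors."""

    subject_ids: tuple
    S: np.ndarray = field(repr=False)

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        m = len(self.subject_ids)
        if S.shape != (m, m):
            raise ValueError("S shape does not match number of subjects")
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(np.abs(S) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        S = S.copy()
        np.fill_diagonal(S, 1.0)
        S.setflags(write=False)
        object.__setattr__(self, "S", S)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subset(self, idx) -> "SimilarityMatrix":
        idx = np.asarray(idx, dtype=int)
        return SimilarityMatrix(
            tuple(self.subject_ids[i] for i in idx), self.S[np.ix_(idx, idx)]
        )


@dataclass(frozen=True)
class ModularityConfig:
    gamma: float = 1.0
    n_restarts: int = 20
    seed: int = 0
    negative_weight_policy: str = "zero"  # or "keep"
    min_frac: float = 0.05  # minimum module size fraction for "nontrivial"
    gamma_grid: tuple = tuple(np.round(np.arange(0.5, 1.5001, 0.01), 4))

    def __post_init__(self):
        if not np.isfinite(self.gamma) or self.gamma <= 0:
            raise ValueError("gamma must be positive and finite")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.negative_weight_policy not in ("zero", "keep"):
            raise ValueError("negative_weight_policy must be 'zero' or 'keep'")


@dataclass(frozen=True)
class ModulePartition:
    """Subject -> module assignment with the resolution and Q behind it."""

    assignment: dict  # subject_id -> module label (0-based int)
    Q: float
    gamma: float

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, subject_ids) -> np.ndarray:
        return np.array([self.assignment[s] for s in subject_ids], dtype=int)

    def members(self, module) -> list:
        return [s for s, m in self.assignment.items() if m == module]


# ---------------------------------------------------------------------------
# Similarity


def similarity_matrix(vectors) -> SimilarityMatrix:
    """Pearson-correlation similarity of subjects' edge vectors."""
    if len(vectors) < 2:
        raise ValueError("need at least two subjects")
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("edge vectors differ in length")
    if lengths.pop() < 3:
        raise ValueError("edge vectors must have length >= 3")
    X = np.vstack([v.values for v in vectors])
    sd = X.std(axis=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        names = [vectors[i].subject_id for i in bad]
        raise ValueError(f"zero-variance edge vector(s) for subjects {names}")
    S = np.corrcoef(X)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(tuple(v.subject_id for v in vectors), S)


def _adjacency(sim: SimilarityMatrix, config: ModularityConfig) -> np.ndarray:
    A = np.array(sim.S, dtype=float)
    np.fill_diagonal(A, 0.0)
    if config.negative_weight_policy == "zero":
        A[A < 0] = 0.0
    return A


# ---------------------------------------------------------------------------
# Modularity


def modularity_Q(
    sim: SimilarityMatrix, assignment: dict, config: ModularityConfig
) -> float:
    """Q(gamma) with the configuration null, normalized by total weight.

    The sum runs over all ordered pairs including j == h (A_jj = 0 but the
    null term P_jj is kept), so a single module at gamma = 1 scores exactly
    0: the configuration null cancels the observed weight.
    """
    A = _adjacency(sim, config)
    s = A.sum(axis=1)
    two_m = s.sum()
    if two_m == 0:
        return 0.0
    labels = np.array([assignment[sid] for sid in sim.subject_ids])
    delta = labels[:, None] == labels[None, :]
    P = np.outer(s, s) / two_m
    return float(((A - config.gamma * P) * delta).sum() / two_m)


def _canonical(labels: np.ndarray) -> tuple:
    """Relabel modules in order of first appearance (canonical form)."""
    mapping, out = {}, []
    for l in labels:
        if l not in mapping:
            mapping[l] = len(mapping)
        out.append(mapping[l])
    return tuple(out)


def maximize_modularity(
    sim: SimilarityMatrix, config: ModularityConfig
) -> ModulePartition:
    """Greedy multi-level (Louvain-style) maximization, best of
    ``n_restarts`` randomized runs.  Deterministic given the config seed;
    ties broken by higher Q, then fewer modules, then lexicographically
    smallest canonical assignment."""
    A = _adjacency(sim, config)
    m = sim.n_subjects
    G = nx.Graph()
    G.add_nodes_from(range(m))
    iu, ju = np.nonzero(np.triu(A, 1))
    G.add_weighted_edges_from(
        (int(i), int(j), float(A[i, j])) for i, j in zip(iu, ju)
    )
    best = None
    for r in range(config.n_restarts):
        comms = louvain_communities(
            G,
            weight="weight",
            resolution=config.gamma,
            seed=int(config.seed) * 10007 + r,
        )
        labels = np.empty(m, dtype=int)
        for k, com in enumerate(comms):
            labels[list(com)] = k
        canon = _canonical(labels)
        assignment = dict(zip(sim.subject_ids, canon))
        Q = modularity_Q(sim, assignment, config)
        key = (-Q, len(set(canon)), canon)
        if best is None or key < best[0]:
            best = (key, assignment, Q)
    return ModulePartition(best[1], best[2], config.gamma)


def exhaustive_max_modularity(
    sim: SimilarityMatrix, config: ModularityConfig
) -> ModulePartition:
    """Brute-force search over all set partitions (oracle; m <= ~10)."""

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] + [head]] + part[k + 1 :]
            yield [[head]] + part

    ids = list(sim.subject_ids)
    best = None
    for part in partitions(ids):
        assignment = {s: k for k, block in enumerate(part) for s in block}
        labels = _canonical(np.array([assignment[s] for s in ids]))
        assignment = dict(zip(ids, labels))
        Q = modularity_Q(sim, assignment, config)
        key = (-Q, len(part), labels)
        if best is None or key < best[0]:
            best = (key, assignment, Q)
    return ModulePartition(best[1], best[2], config.gamma)


def find_min_gamma(
    sim: SimilarityMatrix, config: ModularityConfig, gamma_grid=None
):
    """Smallest grid resolution whose partition has exactly two modules,
    each holding at least ``min_frac`` of subjects.

    Returns ``(gamma_star, ModulePartition)``; raises
    :class:`GammaSearchError` if no grid value qualifies.
    """
    grid = tuple(gamma_grid) if gamma_grid is not None else config.gamma_grid
    if len(grid) == 0:
        raise ValueError("gamma grid is empty")
    min_size = max(1, int(np.ceil(config.min_frac * sim.n_subjects)))
    for gamma in grid:
        part = maximize_modularity(sim, replace(config, gamma=float(gamma)))
        sizes = pd.Series(list(part.assignment.values())).value_counts()
        if part.n_modules == 2 and sizes.min() >= min_size:
            return float(gamma), part
    raise GammaSearchError(
        f"no resolution in [{grid[0]}, {grid[-1]}] produced two nontrivial "
        "modules; widen the grid"
    )


# ---------------------------------------------------------------------------
# Module matching and validation


def match_modules(
    reference: ModulePartition, other: ModulePartition, subject_ids
) -> dict:
    """Map ``other``'s module labels onto ``reference``'s by maximal overlap
    (Hungarian assignment on the contingency table over shared subjects)."""
    shared = [s for s in subject_ids if s in other.assignment]
    ref = reference.labels_for(shared)
    oth = other.labels_for(shared)
    ref_labels = np.unique(ref)
    oth_labels = np.unique(oth)
    cont = np.zeros((oth_labels.size, ref_labels.size))
    for i, a in enumerate(oth_labels):
        for j, b in enumerate(ref_labels):
            cont[i, j] = np.sum((oth == a) & (ref == b))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {int(oth_labels[i]): int(ref_labels[j]) for i, j in zip(rows, cols)}
    # unmatched extra modules keep fresh labels
    nxt = int(max(ref_labels.max(), oth_labels.max())) + 1
    for a in oth_labels:
        if int(a) not in mapping:
            mapping[int(a)] = nxt
            nxt += 1
    return mapping


def assign_by_mean_similarity(
    sim: SimilarityMatrix, subject: str, partition: ModulePartition
) -> int:
    """Module of ``partition`` whose members have the highest mean
    similarity to ``subject`` (ties: lower module label)."""
    i = sim.subject_ids.index(subject)
    best_label, best_score = None, -np.inf
    for label in sorted(set(partition.assignment.values())):
        members = [s for s in partition.members(label) if s != subject]
        idx = [sim.subject_ids.index(s) for s in members]
        score = float(np.mean(sim.S[i, idx])) if idx else -np.inf
        if score > best_score + 1e-15:
            best_label, best_score = label, score
    return best_label


def crossval_accuracy(
    sim: SimilarityMatrix,
    k: int,
    config: ModularityConfig,
    seed: int = 0,
    reference: ModulePartition = None,
    gamma_grid=None,
):
    """k-fold cross-validated module-assignment accuracy.

    Each fold re-runs the full gamma search on the retained subjects, maps
    the fold's modules onto the whole-sample reference by maximal overlap,
    assigns each withheld subject to the module with the highest mean
    similarity to its members, and scores agreement with the reference.
    Folds whose gamma search fails are skipped and reported.
    """
    m = sim.n_subjects
    if m < 2 * k:
        raise ValueError("need at least 2k subjects for k folds")
    if reference is None:
        _, reference = find_min_gamma(sim, config, gamma_grid)
    rng = np.random.default_rng(seed)
    order = rng.permutation(m)
    folds = np.array_split(order, k)
    accs, skipped = [], []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx)
        sub = sim.subset(np.sort(train_idx))
        try:
            _, part = find_min_gamma(sub, config, gamma_grid)
        except GammaSearchError:
            skipped.append(f)
            continue
        mapping = match_modules(reference, part, sub.subject_ids)
        mapped = ModulePartition(
            {s: mapping[l] for s, l in part.assignment.items()},
            part.Q,
            part.gamma,
        )
        hits = 0
        for t in test_idx:
            sid = sim.subject_ids[t]
            label = assign_by_mean_similarity(sim, sid, mapped)
            hits += int(label == reference.assignment[sid])
        accs.append(hits / len(test_idx))
    if not accs:
        raise GammaSearchError("gamma search failed in every fold")
    return float(np.mean(accs)), {"skipped_folds": skipped, "fold_acc": accs}


@dataclass(frozen=True)
class SubsetResult:
    subset_spec: object
    status: str  # "ok" or "no-two-modules"
    accuracy: float = None
    gamma: float = None
    partition: ModulePartition = None


def subset_accuracy(
    population,
    subset_spec,
    reference: ModulePartition,
    config: ModularityConfig,
    gamma_grid=None,
) -> SubsetResult:
    """Re-cluster from a single edge subset and score agreement with the
    whole-network reference partition.

    Failure of the gamma search (no two comparable modules from this
    subset) is reported as a status, not an exception.
    """
    if len(set(reference.assignment.values())) != 2:
        raise ValueError("reference partition must have exactly two modules")
    vectors = [vectorize_edges(cm, subset_spec) for cm in population]
    try:
        sim = similarity_matrix(vectors)
        gamma, part = find_min_gamma(sim, config, gamma_grid)
    except (GammaSearchError, ValueError):
        return SubsetResult(subset_spec, "no-two-modules")
    mapping = match_modules(reference, part, sim.subject_ids)
    hits = sum(
        int(mapping[part.assignment[s]] == reference.assignment[s])
        for s in sim.subject_ids
    )
    return SubsetResult(
        subset_spec, "ok", hits / len(vectors), gamma,
        ModulePartition(
            {s: mapping[l] for s, l in part.assignment.items()},
            part.Q, part.gamma,
        ),
    )


def representative_matrix(
    population, partition: ModulePartition, level: str = "coarse",
    coarse: Parcellation = None,
):
    """Entrywise mean SC matrix of each module's members.

    ``level='coarse'`` averages reparcellated matrices (requires
    ``coarse``); ``level='fine'`` averages the fine matrices directly.
    """
    by_id = {cm.subject_id: cm for cm in population}
    out = {}
    for label in sorted(set(partition.assignment.values())):
        members = partition.members(label)
        if not members:
            raise ValueError(f"module {label} is empty")
        mats = []
        for s in members:
            cm = by_id[s]
            if level == "coarse":
                cm = reparcellate(cm, coarse)
            mats.append(cm.W)
        mean = np.mean(mats, axis=0)
        proto = reparcellate(by_id[members[0]], coarse) if level == "coarse" \
            else by_id[members[0]]
        out[label] = proto.with_weights(
            mean, subject_id=f"module-{label}-mean"
        )
    return out
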