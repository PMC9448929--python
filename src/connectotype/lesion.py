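"""Population-consistent targeted hub lesioning.

Traumatic injury is emulated by cumulatively severing the most connected
nodes.  To lesion the *same* anatomical nodes in every subject, nodes are
ranked within each subject by connectivity (weighted strength by default;
binary degree optional), the rank positions are averaged across the
population, and the population-mean ranking defines one shared deletion
order.  A lesion at level p zeroes the rows and columns of the top
ceil(p * n) ranked nodes — lesioned nodes remain in the matrix as
disconnected oscillators, so the order-parameter ensemble size is
unchanged.  Higher levels strictly contain lower levels' lesioned sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import ConnectomeMatrix, normalize_for_km
from .graph_metrics import compute_metrics
from .kuramoto import coupling_sweep

DEFAULT_LEVELS = (0.05, 0.10, 0.25, 0.50, 0.75)


@dataclass(frozen=True)
class LesionPlan:
    """Shared deletion order (descending population-mean connectivity)."""

    ranked_nodes: tuple  # most-connected first
    levels: tuple = DEFAULT_LEVELS
    measure: str = "strength"

    def __post_init__(self):
        n = len(self.ranked_nodes)
        if sorted(self.ranked_nodes) != list(range(n)):
            raise ValueError("ranked_nodes must be a permutation of 0..n-1")
        lv = tuple(float(l) for l in self.levels)
        if any(not (0 < l <= 1) for l in lv) or list(lv) != sorted(lv):
            raise ValueError("levels must be ascending fractions in (0, 1]")
        object.__setattr__(self, "levels", lv)

    def lesioned_nodes(self, level: float) -> tuple:
        """Node set severed at ``level`` (top ceil(level * n) ranked)."""
        if not 0 <= level <= 1:
            raise ValueError("level must lie in [0, 1]")
        k = int(np.ceil(level * len(self.ranked_nodes)))
        return tuple(self.ranked_nodes[:k])


def rank_nodes(population, measure: str = "strength") -> LesionPlan:
    """Rank nodes by population-mean within-subject connectivity rank.

    Per subject, nodes are ranked 1 = most connected (``strength`` = row sum
    of weights, or ``binary_degree``); rank positions are averaged across
    subjects; nodes are ordered by ascending mean rank (descending
    connectivity), ties broken by lower node index.
    """
    if measure not in ("strength", "binary_degree"):
        raise ValueError("measure must be 'strength' or 'binary_degree'")
    parcs = {cm.parcellation.name for cm in population}
    ns = {cm.n_nodes for cm in population}
    if len(parcs) > 1 or len(ns) > 1:
        raise ValueError("all subjects must share one parcellation")
    n = ns.pop()
    ranks = np.zeros((len(population), n))
    for i, cm in enumerate(population):
        conn = cm.W.sum(axis=0) if measure == "strength" \
            else (cm.W > 0).sum(axis=0).astype(float)
        # rank 1 = highest connectivity; average ranks for exact ties
        order = pd.Series(-conn).rank(method="average")
        ranks[i] = order.to_numpy()
    mean_rank = ranks.mean(axis=0)
    ranked = tuple(int(i) for i in np.lexsort((np.arange(n), mean_rank)))
    return LesionPlan(ranked_nodes=ranked, measure=measure)


def apply_lesion(
    cm: ConnectomeMatrix, plan: LesionPlan, level: float
) -> ConnectomeMatrix:
    """Zero the rows and columns of the nodes lesioned at ``level``.

    Matrix size is unchanged; lesioned nodes become isolated.
    """
    nodes = list(plan.lesioned_nodes(level))
    W = np.array(cm.W)
    W[nodes, :] = 0.0
    W[:, nodes] = 0.0
    return cm.with_weights(W)


def apply_lesion_to_coupling(
    C: np.ndarray, plan: LesionPlan, level: float
) -> np.ndarray:
    """Same lesion applied to an already-normalized coupling matrix
    (the default: no renormalization after lesioning, so the lesion's loss
    of total coupling is preserved)."""
    nodes = list(plan.lesioned_nodes(level))
    C = np.array(C)
    C[nodes, :] = 0.0
    C[:, nodes] = 0.0
    return C


def lesion_experiment(
    population,
    plan: LesionPlan,
    levels=None,
    km_settings: dict = None,
    cc_mode: str = "binary",
    renormalize: bool = False,
    include_baseline: bool = True,
    run_dynamics: bool = True,
):
    """Graph metrics (and optionally coupling sweeps) per subject x level.

    Coupling matrices are normalized once, pre-lesion, then lesioned
    (``renormalize=True`` re-normalizes after each lesion instead).
    Returns ``(metrics_df, sweep_df)``; ``sweep_df`` is None when dynamics
    are skipped.
    """
    levels = list(plan.levels if levels is None else levels)
    if include_baseline and 0.0 not in levels:
        levels = [0.0] + levels
    km = dict(km_settings or {})
    base_seed = int(km.pop("seed", 0))
    metric_rows, sweep_rows = [], []
    for isub, cm in enumerate(population):
        C0 = normalize_for_km(cm) if run_dynamics else None
        for level in levels:
            lesioned = apply_lesion(cm, plan, level) if level > 0 else cm
            rec = compute_metrics(lesioned, cc_mode=cc_mode)
            metric_rows.append({**rec.__dict__, "level": level})
            if run_dynamics:
                if renormalize and lesioned.W.max() > 0:
                    C = normalize_for_km(lesioned)
                else:
                    C = apply_lesion_to_coupling(C0, plan, level)
                # independent frequency/phase draws per subject
                sw = coupling_sweep(
                    C, normalize=False, seed=base_seed + 977 * isub, **km
                )
                for K, s, mts in zip(sw.K_grid, sw.synchrony,
                                     sw.metastability):
                    sweep_rows.append(
                        {
                            "subject_id": cm.subject_id,
                            "level": level,
                            "K": K,
                            "synchrony": s,
                            "metastability": mts,
                        }
                    )
    metrics_df = pd.DataFrame(metric_rows)
    sweep_df = pd.DataFrame(sweep_rows) if run_dynamics else None
    return metrics_df, sweep_df
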