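"""Parcellation schemes: node-to-system maps for structural connectomes.

A parcellation assigns every node of a connectome to exactly one labelled
system.  The package ships a default fine scheme of 100 nodes nested in the
seven canonical cortical systems (Visual, Somatomotor, Dorsal Attention,
Ventral Attention, Limbic, Control, Default), which is the resolution pair
used throughout the analysis: fine matrices for dynamics and lesioning,
coarse (system-level) averages for subject similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

YEO7_SYSTEMS = (
    "Visual",
    "Somatomotor",
    "DorsalAttention",
    "VentralAttention",
    "Limbic",
    "Control",
    "Default",
)

# Node counts per system for the default 100-node fine scheme.  Sizes are
# deliberately unequal, mimicking the uneven system sizes of standard
# cortical parcellations; they sum to 100.
_DEFAULT_FINE_SIZES = (14, 16, 13, 12, 10, 17, 18)


@dataclass(frozen=True)
class Parcellation:
    """A named partition of ``n_nodes`` nodes into labelled systems.

    ``system_of[i]`` is the system label of node ``i`` (0-based indices).
    """

    name: str
    system_of: tuple = field(repr=False)

    def __post_init__(self):
        labels = tuple(str(s) for s in self.system_of)
        object.__setattr__(self, "system_of", labels)
        if len(labels) == 0:
            raise ValueError("parcellation must contain at least one node")
        n_sys = len(set(labels))
        if not (1 <= n_sys <= len(labels)):
            raise ValueError("number of systems must be in [1, n_nodes]")

    @property
    def n_nodes(self) -> int:
        return len(self.system_of)

    @property
    def systems(self) -> tuple:
        """Distinct system labels in first-appearance order."""
        seen = {}
        for s in self.system_of:
            seen.setdefault(s, None)
        return tuple(seen)

    def nodes_of(self, system: str) -> np.ndarray:
        """Indices of nodes belonging to ``system``."""
        if system not in self.system_of:
            raise KeyError(f"unknown system label: {system!r}")
        return np.array(
            [i for i, s in enumerate(self.system_of) if s == system], dtype=int
        )

    def system_indices(self) -> np.ndarray:
        """Per-node integer system codes (order of :attr:`systems`)."""
        order = {s: k for k, s in enumerate(self.systems)}
        return np.array([order[s] for s in self.system_of], dtype=int)


def identity_parcellation(n_nodes: int, name: str = "identity") -> Parcellation:
    """Each node is its own system (reparcellation is then a no-op)."""
    return Parcellation(name, tuple(f"n{i}" for i in range(n_nodes)))


def coarse_parcellation(name: str = "yeo7") -> Parcellation:
    """The 7-system scheme, one node per system."""
    return Parcellation(name, YEO7_SYSTEMS)


def default_fine_parcellation(
    n_nodes: int = 100, name: str = "fine100"
) -> Parcellation:
    """Fine scheme of ``n_nodes`` nodes spread over the seven systems.

    For ``n_nodes == 100`` the per-system counts are fixed at
    ``(14, 16, 13, 12, 10, 17, 18)``; other sizes distribute nodes as evenly
    as possible (every system gets at least two nodes so that within-system
    edges exist, requiring ``n_nodes >= 14``).
    """
    if n_nodes == 100:
        sizes = _DEFAULT_FINE_SIZES
    else:
        if n_nodes < 2 * len(YEO7_SYSTEMS):
            raise ValueError("need at least 2 nodes per system (n_nodes >= 14)")
        base, extra = divmod(n_nodes, len(YEO7_SYSTEMS))
        sizes = tuple(base + (1 if k < extra else 0) for k in range(len(YEO7_SYSTEMS)))
    labels = []
    for sys_label, size in zip(YEO7_SYSTEMS, sizes):
        labels.extend([sys_label] * size)
    return Parcellation(name, tuple(labels))


def read_parcellation_map(path, name: str = "custom") -> Parcellation:
    """Read a two-column TSV ``node_index<TAB>system_label`` (0-based)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["node", "system"])
    df = df.sort_values("node")
    idx = df["node"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError("node indices must be 0..n-1 with no gaps")
    return Parcellation(name, tuple(df["system"].astype(str)))


def write_parcellation_map(parc: Parcellation, path) -> None:
    pd.DataFrame(
        {"node": np.arange(parc.n_nodes), "system": list(parc.system_of)}
    ).to_csv(path, sep="\t", header=False, index=False)
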