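"""Structural-connectivity matrices: data model, I/O and core transforms.

A :class:`ConnectomeMatrix` is one subject's symmetric, nonnegative weighted
adjacency over a parcellation.  The transforms here are the plumbing every
downstream stage relies on:

* ``scale_to_target_mean`` — put all subjects on a common edge-weight scale
  (mean of the unique off-diagonal entries equals a configured target);
* ``reparcellate`` — average fine edges into system-level (coarse) edges;
* ``vectorize_edges`` — deterministic 1-D edge vectors (whole network,
  within-system, or between-system subsets) for similarity analysis;
* ``normalize_for_km`` — rescale so the mean off-diagonal element is 1,
  the coupling convention of the oscillator model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import logging

import numpy as np
import pandas as pd

from .parcellation import Parcellation

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-9


class DegenerateInputError(ValueError):
    """Raised when a matrix is too degenerate for the requested operation."""


@dataclass(frozen=True)
class ConnectomeMatrix:
    """One subject's symmetric nonnegative SC matrix plus metadata.

    The diagonal is 0 by convention for fine-scale matrices.  Coarse
    (reparcellated) matrices carry within-system mean weights on the
    diagonal and are constructed with ``allow_diagonal=True``.
    """

    subject_id: str
    parcellation: Parcellation
    W: np.ndarray = field(repr=False)
    sex: str = "unspecified"
    allow_diagonal: bool = False

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be a square matrix")
        if W.shape[0] != self.parcellation.n_nodes:
            raise ValueError(
                f"matrix size {W.shape[0]} does not match parcellation "
                f"{self.parcellation.name} ({self.parcellation.n_nodes} nodes)"
            )
        if not np.allclose(W, W.T, atol=1e-12, rtol=0.0):
            raise ValueError("W must be symmetric (tolerance 1e-12)")
        if np.any(W < 0):
            raise ValueError("W must be nonnegative")
        if not self.allow_diagonal and np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be stored as 0")
        if self.sex not in ("male", "female", "unspecified"):
            raise ValueError(f"unknown sex label {self.sex!r}")
        W = W.copy()
        W.setflags(write=False)
        object.__setattr__(self, "W", W)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]

    def with_weights(self, W: np.ndarray, **kw) -> "ConnectomeMatrix":
        return replace(self, W=W, **kw)


@dataclass(frozen=True)
class EdgeVector:
    """Ordered vector of unique SC edges for one subject.

    ``subset_spec`` is ``"whole"``, ``("within", S)`` or
    ``("between", S, T)``.  Ordering is fixed row-major upper triangle
    (whole / within) or row-major over the S x T block (between), so vectors
    are comparable across subjects.
    """

    subject_id: str
    subset_spec: object
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# I/O


def read_sc_matrix(
    path,
    parcellation: Parcellation,
    subject_id: str,
    sex: str = "unspecified",
    header: bool = False,
) -> ConnectomeMatrix:
    """Read a dense whitespace/TSV square SC matrix file.

    Symmetrizes by ``(W + W.T) / 2`` when the asymmetry is within write
    precision (max |W - W.T| <= 1e-9) and forces the diagonal to 0; larger
    asymmetry or negative entries raise ``ValueError``.
    """
    skip = 1 if header else 0
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, skiprows=skip, dtype=str, comment="#"
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse SC matrix file {path}: {exc}") from exc
    if header:
        df = df.iloc[:, 1:]
    try:
        W = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric entries in SC matrix file {path}") from exc
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(
            f"SC matrix file {path} is not square (shape {W.shape})"
        )
    if np.any(W < 0):
        raise ValueError(f"negative edge weights in {path}")
    asym = np.max(np.abs(W - W.T)) if W.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ValueError(
            f"SC matrix in {path} is asymmetric beyond tolerance "
            f"(max |W-W.T| = {asym:.3g} > {SYMMETRY_TOL:g})"
        )
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return ConnectomeMatrix(subject_id, parcellation, W, sex=sex)


def write_sc_matrix(cm: ConnectomeMatrix, path) -> None:
    """Write a dense TSV matrix (no header), round-trippable by read_sc_matrix."""
    np.savetxt(path, cm.W, delimiter="\t", fmt="%.10g")


def read_manifest(path) -> pd.DataFrame:
    """Population manifest CSV with columns subject_id, sex, path."""
    df = pd.read_csv(path)
    missing = {"subject_id", "sex", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Transforms


def _upper_mean(W: np.ndarray) -> float:
    iu = np.triu_indices(W.shape[0], k=1)
    return float(W[iu].mean())


def scale_to_target_mean(
    cm: ConnectomeMatrix, target_mean: float
) -> ConnectomeMatrix:
    """Rescale so the mean of unique off-diagonal entries equals ``target_mean``."""
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    current = _upper_mean(cm.W)
    if current == 0.0:
        raise DegenerateInputError(
            f"subject {cm.subject_id}: all-zero matrix cannot be rescaled"
        )
    return cm.with_weights(cm.W * (target_mean / current))


def reparcellate(cm: ConnectomeMatrix, coarse: Parcellation) -> ConnectomeMatrix:
    """Average fine edges into coarse system-level edges.

    The (S, T) entry (S != T) is the mean of all fine edges between systems
    S and T; the (S, S) diagonal entry is the mean over unique fine node
    pairs inside S (0, with a warning, for systems of fewer than two nodes).
    """
    fine = cm.parcellation
    unknown = set(fine.system_of) - set(coarse.system_of)
    if unknown:
        raise ValueError(
            f"fine systems {sorted(unknown)} not present in coarse "
            f"parcellation {coarse.name}"
        )
    if coarse.n_nodes == fine.n_nodes and fine.system_of == coarse.system_of:
        # identity mapping: nothing to average
        return cm.with_weights(cm.W, parcellation=coarse)
    k = coarse.n_nodes
    out = np.zeros((k, k))
    members = [fine.nodes_of(s) if s in fine.system_of else np.array([], int)
               for s in coarse.system_of]
    for a in range(k):
        ia = members[a]
        for b in range(a, k):
            ib = members[b]
            if a == b:
                if ia.size < 2:
                    logger.warning(
                        "system %s has < 2 nodes; within-system entry set to 0",
                        coarse.system_of[a],
                    )
                    continue
                block = cm.W[np.ix_(ia, ia)]
                iu = np.triu_indices(ia.size, k=1)
                out[a, a] = block[iu].mean()
            else:
                if ia.size == 0 or ib.size == 0:
                    continue
                out[a, b] = out[b, a] = cm.W[np.ix_(ia, ib)].mean()
    return cm.with_weights(out, parcellation=coarse, allow_diagonal=True)


def _parse_subset(subset_spec):
    if subset_spec == "whole":
        return ("whole",)
    if isinstance(subset_spec, str):
        if subset_spec.startswith("within:"):
            return ("within", subset_spec.split(":", 1)[1])
        if subset_spec.startswith("between:"):
            a, b = subset_spec.split(":", 1)[1].split("/")
            return ("between", a, b)
        raise ValueError(f"unrecognized subset spec {subset_spec!r}")
    spec = tuple(subset_spec)
    if spec[0] in ("whole", "within", "between"):
        return spec
    raise ValueError(f"unrecognized subset spec {subset_spec!r}")


def vectorize_edges(cm: ConnectomeMatrix, subset_spec="whole") -> EdgeVector:
    """Extract the ordered unique-edge vector for a subset of the network.

    ``whole``: upper triangle excluding the diagonal (length n(n-1)/2);
    ``within:S``: unique node pairs inside system S;
    ``between:S/T``: every (i in S) x (j in T) entry, row-major.
    """
    spec = _parse_subset(subset_spec)
    parc = cm.parcellation
    if spec[0] == "whole":
        iu = np.triu_indices(cm.n_nodes, k=1)
        values = cm.W[iu]
    elif spec[0] == "within":
        idx = parc.nodes_of(spec[1])
        block = cm.W[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        values = block[iu]
    elif spec[0] == "between":
        ia, ib = parc.nodes_of(spec[1]), parc.nodes_of(spec[2])
        values = cm.W[np.ix_(ia, ib)].ravel()
    else:  # pragma: no cover
        raise ValueError(f"unrecognized subset spec {subset_spec!r}")
    return EdgeVector(cm.subject_id, spec, values)


def normalize_for_km(cm: ConnectomeMatrix) -> np.ndarray:
    """Coupling matrix: rescale so the mean of ALL n(n-1) off-diagonal
    elements (structural zeros included) equals 1."""
    W = np.array(cm.W, dtype=float)
    n = W.shape[0]
    off_mean = (W.sum() - np.trace(W)) / (n * (n - 1))
    if off_mean == 0.0:
        raise DegenerateInputError(
            f"subject {cm.subject_id}: all-zero matrix cannot be normalized"
        )
    C = W / off_mean
    np.fill_diagonal(C, 0.0)
    return C
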