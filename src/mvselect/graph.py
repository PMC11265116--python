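"""Weighted variable-variable graphs and their normalized Laplacians.

A :class:`GraphPrior` encodes prior knowledge that certain features of a view
interact (e.g. protein-protein interactions).  Its normalized Laplacian
``L_norm = T^{-1/2} (T - W) T^{-1/2}`` acts as a smoothing operator on the
reconstructed data so that connected features are encouraged to be selected
together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GraphPrior:
    """A weighted undirected graph over the p features of one view.

    Attributes
    ----------
    n_vertices : int
        Number of features p.
    edges : list of (int, int, float)
        Unique undirected edges (u < v, 0-based) with nonnegative weights.
    degrees : ndarray
        r_v = sum_u w(u, v).
    laplacian : ndarray
        Combinatorial Laplacian L = T - W (T = diag(degrees)).
    normalized_laplacian : ndarray
        T^{-1/2} L T^{-1/2}; entries for isolated vertices (r_v = 0) are set
        to zero so features without prior edges incur no smoothing.
        Symmetric PSD with eigenvalues in [0, 2].
    """

    n_vertices: int
    edges: list[tuple[int, int, float]]
    degrees: np.ndarray
    laplacian: np.ndarray
    normalized_laplacian: np.ndarray


def normalized_laplacian(
    edges: list[tuple], p: int, default_weight: float = 1.0
) -> GraphPrior:
    """Build a :class:`GraphPrior` from a weighted edge list.

    Parameters
    ----------
    edges : list of (u, v) or (u, v, weight)
        0-based vertex indices in [0, p); weights nonnegative (default 1).
        Self-loops are rejected; duplicate edges must agree in weight.
    p : int
        Vertex (feature) count.
    """
    W = np.zeros((p, p))
    seen: dict[tuple[int, int], float] = {}
    for e in edges:
        if len(e) == 2:
            u, v = e
            w = default_weight
        else:
            u, v, w = e
        u, v, w = int(u), int(v), float(w)
        if not (0 <= u < p and 0 <= v < p):
            raise ValueError(f"edge ({u},{v}): vertex out of range [0,{p})")
        if u == v:
            raise ValueError(f"self-loop at vertex {u} not allowed")
        if w < 0:
            raise ValueError(f"edge ({u},{v}): negative weight {w}")
        key = (min(u, v), max(u, v))
        if key in seen and seen[key] != w:
            raise ValueError(
                f"edge {key}: conflicting duplicate weights {seen[key]} and {w}"
            )
        seen[key] = w
        W[u, v] = W[v, u] = w

    degrees = W.sum(axis=0)
    L = np.diag(degrees) - W
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(degrees > 0, 1.0 / np.sqrt(np.maximum(degrees, 1e-300)), 0.0)
    Ln = inv_sqrt[:, None] * L * inv_sqrt[None, :]
    Ln = (Ln + Ln.T) / 2.0  # enforce exact symmetry
    edge_list = [(u, v, w) for (u, v), w in sorted(seen.items())]
    return GraphPrior(p, edge_list, degrees, L, Ln)


def read_edge_list(
    path: str | Path,
    p: int,
    feature_names: list[str] | None = None,
    default_weight: float = 1.0,
) -> GraphPrior:
    """Read a TSV edge list with columns (u, v[, weight]).

    Vertices are either feature names (resolved via ``feature_names``) or
    0-based integer indices.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] not in (2, 3):
        raise ValueError(f"{path}: expected 2 or 3 columns, got {df.shape[1]}")
    edges = []
    lookup = (
        {name: i for i, name in enumerate(feature_names)}
        if feature_names is not None
        else None
    )

    def resolve(x):
        if lookup is not None and str(x) in lookup:
            return lookup[str(x)]
        return int(x)

    for row in df.itertuples(index=False):
        u, v = resolve(row[0]), resolve(row[1])
        w = float(row[2]) if len(row) > 2 else default_weight
        edges.append((u, v, w))
    return normalized_laplacian(edges, p, default_weight=default_weight)


def write_edge_list(prior: GraphPrior, path: str | Path) -> None:
    pd.DataFrame(prior.edges).to_csv(path, sep="\t", header=False, index=False)
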