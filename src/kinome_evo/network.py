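"""Coexpression networks from Pearson correlation with a significance gate.

Edges connect profile pairs whose correlation passes both a magnitude
threshold (|r| strictly above 0.8 by default; 0.9 for the stricter
variant) and a two-sided significance test at alpha = 0.01.  The p-value
comes from the exact null distribution of r for bivariate-normal data,
via the t transform t = r * sqrt((n-2) / (1 - r^2)) with n-2 degrees of
freedom.  No multiple-testing correction is applied by default; a
Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionEdge",
    "pcc",
    "pcc_pvalue",
    "build_network",
    "degree_and_components",
    "DEFAULT_MIN_ABS_PCC",
    "DEFAULT_ALPHA",
]

DEFAULT_MIN_ABS_PCC = 0.8
DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class CoexpressionEdge:
    node_a: str
    node_b: str
    r: float
    p: float
    sign: str  # positive | negative

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError("edges must be stored with node_a < node_b")


def pcc(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Pearson product-moment correlation; ``None`` for constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    nx_ = np.linalg.norm(xc)
    ny_ = np.linalg.norm(yc)
    if nx_ == 0 or ny_ == 0:
        return None
    r = float(np.dot(xc, yc) / (nx_ * ny_))
    return max(-1.0, min(1.0, r))


def pcc_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the normal null.

    Uses t = r sqrt((n-2)/(1-r^2)) with n-2 degrees of freedom; |r| = 1
    maps to p = 0.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("correlation outside [-1, 1]")
    if abs(r) == 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def build_network(
    matrix: pd.DataFrame,
    min_abs_pcc: float = DEFAULT_MIN_ABS_PCC,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> list[CoexpressionEdge]:
    """All profile pairs with |r| > ``min_abs_pcc`` and p < ``alpha``.

    Both thresholds are strict, so a pair at exactly r = 0.8 is
    excluded.  Constant profiles have no defined correlation and are
    dropped with a warning.  With ``bh_correct`` the alpha gate is
    applied to Benjamini-Hochberg adjusted p-values instead.
    """
    if not (0 <= min_abs_pcc < 1):
        raise ValueError("min_abs_pcc must be in [0, 1)")
    values = matrix.to_numpy(dtype=float)
    variances = values.var(axis=1)
    constant = variances == 0
    if constant.any():
        logger.warning(
            "dropping %d constant profiles from the network", int(constant.sum())
        )
        matrix = matrix.loc[~constant]
        values = values[~constant]
    n_samples = values.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    centered = values - values.mean(axis=1, keepdims=True)
    z = centered / np.linalg.norm(centered, axis=1, keepdims=True)
    corr = np.clip(z @ z.T, -1.0, 1.0)

    names = list(matrix.index)
    candidates: list[tuple[str, str, float, float]] = []
    for i, j in combinations(range(len(names)), 2):
        r = float(corr[i, j])
        if abs(r) <= min_abs_pcc:
            continue
        p = pcc_pvalue(r, n_samples)
        a, b = sorted((names[i], names[j]))
        candidates.append((a, b, r, p))

    if bh_correct and candidates:
        pvals = np.array([c[3] for c in candidates])
        order = np.argsort(pvals)
        m = len(pvals)
        adjusted = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            idx = order[rank_pos]
            running = min(running, pvals[idx] * m / (rank_pos + 1))
            adjusted[idx] = running
        candidates = [
            (a, b, r, float(q))
            for (a, b, r, _), q in zip(candidates, adjusted)
        ]

    edges = [
        CoexpressionEdge(
            node_a=a, node_b=b, r=r, p=p, sign="positive" if r > 0 else "negative"
        )
        for a, b, r, p in candidates
        if p < alpha
    ]
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    return edges


def degree_and_components(
    edges: Sequence[CoexpressionEdge],
) -> tuple[dict[str, int], list[set[str]]]:
    """Node degrees and connected components of the edge list.

    Nodes without any edge do not appear.  Components are sorted largest
    first (ties by smallest member name).
    """
    graph = nx.Graph()
    for e in edges:
        graph.add_edge(e.node_a, e.node_b)
    degrees = {node: int(d) for node, d in sorted(graph.degree())}
    components = sorted(
        (set(c) for c in nx.connected_components(graph)),
        key=lambda c: (-len(c), min(c)),
    )
    return degrees, components
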