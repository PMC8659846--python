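"""Descriptive and rank-based inferential statistics for deviation data.

Deviation distributions from placement experiments are skewed with heavy
tails (gross freehand misplacements), so the analysis is nonparametric
throughout: five-number summaries, the Kruskal-Wallis H test (tie
corrected, chi-square reference with k-1 df), and Dunn's post-hoc pairwise
z tests on mean ranks.

Quantiles use linear interpolation between order statistics (numpy's
default), the common statistical-software convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SummaryRow",
    "KWResult",
    "DunnResult",
    "DegenerateDataError",
    "describe",
    "kruskal_wallis",
    "dunn_posthoc",
    "format_p",
]


class DegenerateDataError(ValueError):
    """All observations identical: rank statistics are undefined."""


@dataclass(frozen=True)
class SummaryRow:
    labels: dict
    min: float
    q25: float
    median: float
    q75: float
    max: float
    n: int

    def to_dict(self) -> dict:
        return {**self.labels, "min": self.min, "q25": self.q25,
                "median": self.median, "q75": self.q75, "max": self.max, "n": self.n}


@dataclass(frozen=True)
class KWResult:
    H: float
    df: int
    p: float
    tie_corrected: bool

    def to_dict(self) -> dict:
        return {"H": self.H, "df": self.df, "p": self.p, "tie_corrected": self.tie_corrected}


@dataclass(frozen=True)
class DunnResult:
    pair: tuple
    z: float
    p: float
    adjustment: str

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "z": self.z, "p": self.p, "adjustment": self.adjustment}


def describe(values, labels: dict | None = None) -> SummaryRow:
    """Five-number summary (min, Q25, Mdn, Q75, max) of one group, in mm."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("describe needs at least one value")
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])
    return SummaryRow(labels or {}, float(v.min()), float(q25), float(med),
                      float(q75), float(v.max()), int(v.size))


def _validate_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in gs):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(gs)
    if len(pooled) < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all observations are identical; ranks carry no information")
    return gs


def kruskal_wallis(groups) -> KWResult:
    """Kruskal-Wallis H over k groups, tie corrected, p from chi-square(k-1)."""
    gs = _validate_groups(groups)
    H, p = sps.kruskal(*gs)
    pooled = np.concatenate(gs)
    ties = len(np.unique(pooled)) < len(pooled)
    return KWResult(float(H), len(gs) - 1, float(p), tie_corrected=ties)


def dunn_posthoc(groups, labels=None, adjustment: str = "none") -> list[DunnResult]:
    """Dunn's pairwise post-hoc comparisons on mean ranks.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))``
    with tie term ``T = sum(t^3 - t)`` over tied value groups; p-values are
    two-sided normal, optionally Bonferroni or Holm adjusted across the
    ``k(k-1)/2`` pairs.
    """
    if adjustment not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    gs = _validate_groups(groups)
    k = len(gs)
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError("one label per group required")

    pooled = np.concatenate(gs)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = np.array([len(g) for g in gs])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array([ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)])

    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (N - 1)))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs, zs, ps = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((labels[i], labels[j]))
            zs.append(float(z))
            ps.append(float(2.0 * sps.norm.sf(abs(z))))

    m = len(pairs)
    if adjustment == "bonferroni":
        ps = [min(1.0, m * p) for p in ps]
    elif adjustment == "holm":
        order = np.argsort(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * ps[idx])
            adj[idx] = min(1.0, running)
        ps = adj.tolist()
    return [DunnResult(pair, z, p, adjustment) for pair, z, p in zip(pairs, zs, ps)]


def format_p(p: float, floor: float = 0.001) -> str:
    """Render a p-value the way reports print it (e.g. ``p < 0.001``)."""
    return f"p < {floor:g}" if p < floor else f"p = {p:.3g}"
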