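"""Alpha and beta diversity: inverse Simpson, richness, Bray-Curtis,
baseline-referenced dissimilarity, and a similarity-based sample ordering.

The sample ordering solves a Hamiltonian-path problem on the Bray-Curtis
distance matrix: samples are permuted so that the summed distance between
neighbouring samples is minimal.  For n <= 10 the optimum is found exactly by
Held-Karp dynamic programming; larger instances use greedy nearest-neighbour
construction from every start, refined by 2-opt moves until no improvement.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import AbundanceTable, StudyDesign
from .errors import ValidationError

logger = logging.getLogger(__name__)

EXACT_ORDERING_LIMIT = 10


def inverse_simpson(composition) -> float:
    """1 / sum(p_i^2): the effective number of equally abundant taxa."""
    p = np.asarray(composition, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValidationError("composition has no positive entries")
    if not math.isclose(float(p.sum()), 1.0, abs_tol=1e-6):
        raise ValidationError("composition does not sum to 1")
    return float(1.0 / np.sum(p * p))


def richness(counts) -> int:
    """Number of taxa observed (count > 0) in a counts-mode vector."""
    c = np.asarray(counts, dtype=float)
    if c.size and not np.allclose(c, np.round(c)):
        raise ValidationError("richness requires integer counts, not relative data")
    if math.isclose(float(c.sum()), 1.0, abs_tol=1e-6) and (c < 1).any():
        raise ValidationError("richness requires integer counts, not relative data")
    if (c < 0).any():
        raise ValidationError("negative count")
    return int(np.count_nonzero(c > 0))


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two relative abundance vectors.

    For normalized inputs this equals 0.5 * sum |x_i - y_i|; a semimetric in
    [0, 1].
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        if not x.index.equals(y.index):
            raise ValidationError("mismatched taxon universes")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValidationError("mismatched taxon universes")
    for v in (xa, ya):
        if not math.isclose(float(v.sum()), 1.0, abs_tol=1e-6):
            raise ValidationError("inputs must each sum to 1")
    return float(np.abs(xa - ya).sum() / (xa + ya).sum())


def bray_curtis_matrix(table: AbundanceTable) -> pd.DataFrame:
    """All-pairs Bray-Curtis distances for a relative table."""
    if table.mode != "relative":
        raise ValidationError("Bray-Curtis requires a relative table")
    mat = table.values.to_numpy(dtype=float).T  # samples x taxa
    d = squareform(pdist(mat, metric="braycurtis")) if mat.shape[0] > 1 else np.zeros((1, 1))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


def _path_cost(d: np.ndarray, order: list[int]) -> float:
    return float(sum(d[a, b] for a, b in zip(order, order[1:])))


def _exact_order(d: np.ndarray) -> list[int]:
    """Minimum-cost Hamiltonian path by Held-Karp dynamic programming."""
    n = d.shape[0]
    size = 1 << n
    dp = np.full((size, n), np.inf)
    parent = np.full((size, n), -1, dtype=int)
    for i in range(n):
        dp[1 << i, i] = 0.0
    for mask in range(size):
        for last in range(n):
            if not (mask >> last) & 1:
                continue
            cost = dp[mask, last]
            if not np.isfinite(cost):
                continue
            for nxt in range(n):
                if (mask >> nxt) & 1:
                    continue
                nm = mask | (1 << nxt)
                nc = cost + d[last, nxt]
                if nc < dp[nm, nxt]:
                    dp[nm, nxt] = nc
                    parent[nm, nxt] = last
    full = size - 1
    end = int(np.argmin(dp[full]))
    order = [end]
    mask = full
    while parent[mask, order[-1]] != -1:
        prev = parent[mask, order[-1]]
        mask ^= 1 << order[-1]
        order.append(int(prev))
    return order[::-1]


def _greedy_two_opt(d: np.ndarray) -> list[int]:
    n = d.shape[0]
    best_order: list[int] | None = None
    best_cost = np.inf
    for start in range(n):
        order = [start]
        remaining = set(range(n)) - {start}
        while remaining:
            last = order[-1]
            nxt = min(remaining, key=lambda j: (d[last, j], j))
            order.append(nxt)
            remaining.remove(nxt)
        cost = _path_cost(d, order)
        if cost < best_cost:
            best_cost, best_order = cost, order
    order = list(best_order)  # type: ignore[arg-type]
    improved = True
    while improved:
        improved = False
        for i in range(n - 1):
            for j in range(i + 1, n):
                new = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                c = _path_cost(d, new)
                if c < best_cost - 1e-15:
                    order, best_cost = new, c
                    improved = True
    return order


def order_by_neighbor_distance(table: AbundanceTable) -> list[str]:
    """Permute samples to minimize summed Bray-Curtis distance between neighbours.

    Exact (Held-Karp) for up to :data:`EXACT_ORDERING_LIMIT` samples,
    greedy + 2-opt beyond.  Deterministic: of the two traversal directions,
    the one starting at the lexicographically smaller endpoint is returned.
    """
    ids = table.sample_ids
    if len(ids) == 1:
        return list(ids)
    d = bray_curtis_matrix(table).to_numpy()
    if len(ids) <= EXACT_ORDERING_LIMIT:
        order = _exact_order(d)
    else:
        order = _greedy_two_opt(d)
    if ids[order[-1]] < ids[order[0]]:
        order = order[::-1]
    return [ids[i] for i in order]


def distance_to_baseline(table: AbundanceTable, design: StudyDesign) -> pd.Series:
    """Bray-Curtis distance from each sample to the same participant's V1 sample.

    Participants without a V1 sample get NaN for all their samples (logged as
    a warning); the V1 sample itself maps to 0.
    """
    if table.mode != "relative":
        raise ValidationError("distance_to_baseline requires a relative table")
    out = pd.Series(np.nan, index=pd.Index(table.sample_ids, name="sample_id"))
    for pid in design.participants:
        baseline = design.sample_for(pid, "V1")
        samples = [s for s in design.samples_of(pid).index if s in table.values.columns]
        if baseline is None or baseline not in table.values.columns:
            if samples:
                logger.warning("participant %s has no V1 baseline sample", pid)
            continue
        base = table.sample(baseline)
        for sid in samples:
            out[sid] = bray_curtis(base, table.sample(sid))
    return out


def alpha_diversity(counts_table: AbundanceTable) -> pd.DataFrame:
    """Per-sample inverse Simpson and richness from a counts-mode table."""
    if counts_table.mode != "counts":
        raise ValidationError("alpha_diversity requires a counts table")
    rows = []
    for sid in counts_table.sample_ids:
        c = counts_table.sample(sid).to_numpy(dtype=float)
        p = c / c.sum()
        rows.append(
            {
                "sample_id": sid,
                "inv_simpson": inverse_simpson(p),
                "richness": richness(c),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
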