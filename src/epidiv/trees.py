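"""Neighbor-joining trees and Evanno delta-K cluster-number selection.

Neighbor joining (Saitou & Nei) greedily joins the pair (i, j) minimising

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k)

with branch lengths from the standard split formula, producing an unrooted
additive tree; on an exactly additive input the source tree is recovered.
Ties are broken by the lowest (row, column) pair in current node order, so
results are deterministic.  Negative branch lengths (possible on noisy,
non-additive input) are clamped to zero with the deficit moved to the sister
branch, keeping the pair's path length intact; each clamp is recorded.

Trees are :class:`skbio.TreeNode` objects, so Newick serialisation and leaf
path-length queries come for free.

``delta_k`` post-processes replicate log-probability tables from an external
Bayesian clustering run (K values x replicates of log Pr(data | K)):

    delta_K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd L(K)

The optimum K is the interior K maximising delta_K.  The admixture sampler
itself is out of scope; any program producing an (K, replicate, lnP) table
can feed this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = ["neighbor_joining", "DeltaKTable", "delta_k"]


def _leaf(name: str) -> TreeNode:
    return TreeNode(name=name)


def neighbor_joining(d) -> TreeNode:
    """Build an unrooted NJ tree from a DistanceMatrix.

    Operates on the matrix entries as plain dissimilarities whatever the
    metric tag (callers wanting Euclidean geometry should pass a
    ``euclidean`` matrix).  Two samples yield a single split edge; three or
    more run the full algorithm, finishing with the three-point formula on
    the last triplet.  The returned tree is rooted at an internal node of
    degree 3 (the usual representation of an unrooted binary tree).
    """
    dm = np.asarray(d.data, dtype=float).copy()
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("neighbor joining needs a symmetric matrix")
    names = list(d.sample_ids)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 samples")
    nodes: list[TreeNode] = [_leaf(nm) for nm in names]
    clamps: list[str] = []

    if n == 2:
        half = dm[0, 1] / 2.0
        root = TreeNode()
        for node in nodes:
            node.length = half
            root.append(node)
        return root

    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = dm[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin over the flattened array = lowest (row, col) on ties
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        vi, vj = _clamp_pair(vi, vj, dij, nodes[active[i]], nodes[active[j]], clamps)
        parent = TreeNode()
        for child, length in ((nodes[active[i]], vi), (nodes[active[j]], vj)):
            child.length = float(length)
            parent.append(child)
        # reduction: distance from the new node to every remaining node
        new_row = 0.5 * (dm[active[i], :] + dm[active[j], :] - dij)
        ai = active[i]
        dm[ai, :] = new_row
        dm[:, ai] = new_row
        dm[ai, ai] = 0.0
        nodes[ai] = parent
        del active[j]

    a, b, c = active
    root = TreeNode()
    va = 0.5 * (dm[a, b] + dm[a, c] - dm[b, c])
    vb = 0.5 * (dm[a, b] + dm[b, c] - dm[a, c])
    vc = 0.5 * (dm[a, c] + dm[b, c] - dm[a, b])
    for idx, v in ((a, va), (b, vb), (c, vc)):
        if v < 0:
            clamps.append(f"terminal branch to {nodes[idx].name or 'internal'} "
                          f"clamped from {v:.6g} to 0")
            v = 0.0
        nodes[idx].length = float(v)
        root.append(nodes[idx])
    if clamps:
        root.clamped_branches = clamps  # type: ignore[attr-defined]
    return root


def _clamp_pair(vi: float, vj: float, dij: float, ni: TreeNode, nj: TreeNode,
                log: list[str]) -> tuple[float, float]:
    # keep vi + vj == d(i,j) while forbidding negative lengths
    if vi < 0:
        log.append(f"branch to {ni.name or 'internal'} clamped from {vi:.6g} to 0")
        return 0.0, dij
    if vj < 0:
        log.append(f"branch to {nj.name or 'internal'} clamped from {vj:.6g} to 0")
        return dij, 0.0
    return vi, vj


@dataclass
class DeltaKTable:
    """Evanno second-difference statistics per K."""

    table: pd.DataFrame  # columns: K, n_replicates, mean_lnP, sd_lnP, delta_K
    optimum_k: int | None
    notices: list[str] = field(default_factory=list)


def delta_k(lnp: pd.DataFrame) -> DeltaKTable:
    """Evanno delta-K from a table with columns ``K`` and ``lnP``.

    Needs at least 3 consecutive K values with >= 2 replicates each.
    delta_K is defined only for interior K; where the replicate standard
    deviation is zero it is left undefined (NaN) and flagged rather than
    reported as infinite.
    """
    if not {"K", "lnP"}.issubset(lnp.columns):
        raise ValueError("expected columns 'K' and 'lnP'")
    grouped = lnp.groupby("K")["lnP"]
    ks = np.array(sorted(grouped.groups))
    if len(ks) < 3:
        raise ValueError("need at least 3 K values")
    if not np.array_equal(ks, np.arange(ks[0], ks[0] + len(ks))):
        raise ValueError(f"K values must be consecutive integers, got {list(ks)}")
    counts = grouped.count()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"need >= 2 replicates per K; offending K: {bad}")
    mean = grouped.mean().reindex(ks).to_numpy()
    sd = grouped.std(ddof=1).reindex(ks).to_numpy()

    delta = np.full(len(ks), np.nan)
    notices = []
    for t in range(1, len(ks) - 1):
        second = abs(mean[t + 1] - 2.0 * mean[t] + mean[t - 1])
        if sd[t] == 0:
            notices.append(f"sd(lnP) = 0 at K={ks[t]}; delta_K undefined there")
            continue
        delta[t] = second / sd[t]
    table = pd.DataFrame(
        {
            "K": ks,
            "n_replicates": counts.reindex(ks).to_numpy(),
            "mean_lnP": mean,
            "sd_lnP": sd,
            "delta_K": delta,
        }
    )
    if np.isnan(delta).all():
        optimum = None
        notices.append("delta_K undefined at every interior K; no optimum")
    else:
        optimum = int(ks[int(np.nanargmax(delta))])
    return DeltaKTable(table, optimum, notices)
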