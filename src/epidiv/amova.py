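"""One-level analysis of molecular variance (AMOVA) on a distance matrix.

Variance in pairwise squared distances is partitioned into among-group and
within-group components:

    SS_total  = (1/N) * sum_{i<j} d2[i,j]
    SS_within = sum over groups g of (1/n_g) * sum_{i<j in g} d2[i,j]
    SS_among  = SS_total - SS_within

    df_among  = k - 1,  df_within = N - k
    MS        = SS / df
    var_within = MS_within
    var_among  = (MS_among - MS_within) / n0,
        n0 = (N - sum n_g^2 / N) / (k - 1)

PhiPT = var_among / (var_among + var_within) measures among-group
differentiation for binary/dominant markers.  Significance is a one-tailed
permutation test: whole samples are shuffled among groups with group sizes
fixed, and p = (1 + #{var_among_perm >= var_among_obs}) / (n_perm + 1).
A negative among-group component is truncated to zero for percentages and
PhiPT; the raw value is retained in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .band_data import Grouping
from .distances import DistanceMatrix

__all__ = ["AmovaTable", "amova"]


@dataclass
class AmovaTable:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    var_among: float  # truncated at 0
    var_within: float
    var_among_raw: float  # pre-truncation estimate
    pct_among: float
    pct_within: float
    phi_pt: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    n_samples: int
    n_groups: int
    notices: list[str] = field(default_factory=list)

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within


def _ss_components(d2: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """Total and within-group sums of squared deviations from squared distances."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def amova(
    d: DistanceMatrix,
    grouping: Grouping,
    n_permutations: int = 999,
    seed: int | None = None,
) -> AmovaTable:
    """AMOVA with PhiPT permutation test; pass ``n_permutations=0`` to skip.

    ``d`` is read on its own convention: a ``squared_euclidean`` matrix is
    used as squared distances directly, other metrics are squared first.
    """
    labels = grouping.labels_for(d.sample_ids)
    groups = grouping.groups()
    k = len(groups)
    n = d.n
    if k < 2:
        raise ValueError("AMOVA needs at least 2 groups")
    if n_permutations > 0 and seed is None:
        raise ValueError("a seed is required for the permutation test")
    codes = np.array([groups.index(lab) for lab in labels])
    sizes = np.bincount(codes, minlength=k).astype(float)
    d2 = d.squared()

    ss_total, ss_within = _ss_components(d2, codes, k)
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, n - k
    if df_within <= 0:
        raise ValueError("no within-group degrees of freedom")
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    var_among_raw = (ms_among - ms_within) / n0
    var_within = ms_within

    notices = []
    var_among = var_among_raw
    if var_among < 0:
        notices.append(f"negative among-group component {var_among_raw:.6g} truncated to 0")
        var_among = 0.0
    total_var = var_among + var_within
    pct_among = 100.0 * var_among / total_var if total_var > 0 else 0.0
    phi_pt = var_among / total_var if total_var > 0 else 0.0

    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm_codes = rng.permutation(codes)
            st, sw = _ss_components(d2, perm_codes, k)
            msa = (st - sw) / df_among
            msw = sw / df_within
            if (msa - msw) / n0 >= var_among_raw:
                hits += 1
        p_value = (1 + hits) / (n_permutations + 1)

    return AmovaTable(
        df_among=df_among,
        df_within=df_within,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_among,
        ms_within=ms_within,
        var_among=var_among,
        var_within=var_within,
        var_among_raw=var_among_raw,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        phi_pt=phi_pt,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
        n_samples=n,
        n_groups=k,
        notices=notices,
    )


def amova_frame(table: AmovaTable):
    """Two-row summary mirroring the conventional AMOVA layout."""
    import pandas as pd

    return pd.DataFrame(
        {
            "source": ["among_groups", "within_groups"],
            "df": [table.df_among, table.df_within],
            "SS": [table.ss_among, table.ss_within],
            "MS": [table.ms_among, table.ms_within],
            "est_var": [table.var_among, table.var_within],
            "pct": [table.pct_among, table.pct_within],
            "p_value": [table.p_value, None],
        }
    )
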