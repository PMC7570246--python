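"""Dominant-marker diversity summaries.

Each scored band (one locus x digest column) is treated as a two-state
phenotype with observed presence frequency p — no Hardy-Weinberg
back-transformation is applied, which suits highly selfing material where
dominant-genotype allele-frequency corrections are unreliable.  Under this
model, per band:

    H  = 1 - p^2 - q^2            (Nei's gene diversity, max 0.5)
    I  = -p ln p - q ln q         (Shannon's information index, max ln 2)
    ne = 1 / (p^2 + q^2)          (effective number of alleles, in [1, 2])
    PIC = 1 - p^2 - q^2 - 2 p^2 q^2   (biallelic PIC, max 0.375)

with q = 1 - p and 0 ln 0 := 0.  A band is polymorphic in a group when
0 < p < 1 among its non-missing calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .band_data import BandMatrix, Grouping

__all__ = [
    "LocusDiversity",
    "DiversitySummary",
    "band_frequencies",
    "locus_diversity",
    "diversity_summary",
    "pct_polymorphic",
]


@dataclass(frozen=True)
class LocusDiversity:
    locus_id: str
    p: float
    H: float
    I: float
    ne: float
    polymorphic: bool


@dataclass(frozen=True)
class DiversitySummary:
    group: str
    n_samples: int
    n_loci: int  # number of scored bands considered
    n_polymorphic: int
    pct_polymorphic: float
    mean_H: float
    mean_I: float
    PIC: float


def band_frequencies(matrix: BandMatrix, group: str | None = None,
                     grouping: Grouping | None = None) -> pd.Series:
    """Presence frequency per scored band, over non-missing calls.

    With ``group``/``grouping`` given, restricts to that group's samples.
    Bands that are missing in every considered sample are excluded (NaN-free
    result); their ids are attached as ``result.attrs['excluded']``.
    """
    table = matrix.band_table()
    if group is not None:
        if grouping is None:
            raise ValueError("grouping required when group is given")
        labels = grouping.labels_for(matrix.sample_ids)
        rows = [i for i, lab in enumerate(labels) if lab == group]
        if not rows:
            raise ValueError(f"empty group {group!r}")
        table = table.iloc[rows]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        p = table.mean(axis=0, skipna=True)
    excluded = list(p.index[p.isna()])
    p = p.dropna()
    p.attrs["excluded"] = excluded
    return p


def locus_diversity(p: float, locus_id: str = "") -> LocusDiversity:
    """Two-state diversity indices for one band frequency."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"frequency {p} outside [0, 1]")
    q = 1.0 - p
    h = 1.0 - p * p - q * q
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.array([p * np.log(p) if p > 0 else 0.0,
                          q * np.log(q) if q > 0 else 0.0])
    i = float(-terms.sum())
    ne = 1.0 / (p * p + q * q)
    return LocusDiversity(locus_id, p, h, i, ne, 0.0 < p < 1.0)


def _pic(p: np.ndarray) -> float:
    q = 1.0 - p
    return float(np.mean(1.0 - p**2 - q**2 - 2.0 * p**2 * q**2))


def pct_polymorphic(n_polymorphic: int, n_loci: int) -> float:
    """Percent polymorphic loci, the polymorphism rate printed in summaries."""
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    return 100.0 * n_polymorphic / n_loci


def diversity_summary(
    matrix: BandMatrix,
    grouping: Grouping,
    scope: str = "all_loci",
    include_total: bool = True,
) -> list[DiversitySummary]:
    """Per-group polymorphism and diversity means over scored bands.

    ``scope``: ``all_loci`` averages H and I over every scored band (fixed
    bands contribute zeros); ``polymorphic_only`` averages over the group's
    polymorphic bands.  PIC is always pooled over the group's bands.  With
    ``include_total`` a pooled "Total" row over all samples is appended.
    """
    if scope not in ("all_loci", "polymorphic_only"):
        raise ValueError(f"unknown scope {scope!r}")
    labels = grouping.labels_for(matrix.sample_ids)
    groups = grouping.groups() + (["Total"] if include_total else [])
    out = []
    for g in groups:
        if g == "Total":
            members = matrix.sample_ids
            p = band_frequencies(matrix)
        else:
            members = [s for s, lab in zip(matrix.sample_ids, labels) if lab == g]
            p = band_frequencies(matrix, group=g, grouping=grouping)
        if len(members) == 1:
            warnings.warn(
                f"group {g!r} has a single sample; polymorphism is undefined "
                "and diversity reflects raw frequencies",
                stacklevel=2,
            )
        pv = p.to_numpy()
        poly = (pv > 0) & (pv < 1)
        n_bands = len(pv)
        use = pv[poly] if scope == "polymorphic_only" else pv
        qv = 1.0 - use
        lp = np.log(np.where(use > 0, use, 1.0))  # 0 ln 0 := 0
        lq = np.log(np.where(qv > 0, qv, 1.0))
        h = 1.0 - use**2 - qv**2
        i = -(use * lp + qv * lq)
        out.append(
            DiversitySummary(
                group=g,
                n_samples=len(members),
                n_loci=n_bands,
                n_polymorphic=int(poly.sum()),
                pct_polymorphic=pct_polymorphic(int(poly.sum()), n_bands),
                mean_H=float(h.mean()) if len(use) else 0.0,
                mean_I=float(i.mean()) if len(use) else 0.0,
                PIC=_pic(pv),
            )
        )
    return out


def summary_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
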