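"""Band-type classification and methylation-rate statistics.

The (M, H) presence pattern at a CCGG locus maps onto four band types:

===== ====== ====== =============================================
type  M call H call interpretation
===== ====== ====== =============================================
I     1      1      unmethylated site (both digests cut and amplify)
II    1      0      fully (internally) methylated — blocks HpaII only
III   0      1      hemi-methylated — blocks MspI only
IV    0      0      no band in either digest; counted as methylated
                    (dense methylation), though restriction-site
                    mutation is an undistinguishable alternative
===== ====== ====== =============================================

Rates for a group of samples are percentages of the pooled band-type counts:

    total = (II + III + IV) / (I + II + III + IV) * 100
    full  =  II / (I + II + III + IV) * 100
    hemi  = III / (I + II + III + IV) * 100
    non   =   I / (I + II + III + IV) * 100

Counts are poolable and first-class inputs: published count tables can be fed
directly to :func:`methylation_rates` without the underlying matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal, localcontext
from enum import Enum
from fractions import Fraction

import numpy as np
import pandas as pd

from .band_data import BandMatrix, Grouping

__all__ = [
    "BandType",
    "BandTypeCounts",
    "MethylationProfile",
    "classify_band_type",
    "count_band_types",
    "methylation_rates",
    "rate_contrasts",
    "round_half_up",
]


class BandType(Enum):
    I = (1, 1)
    II = (1, 0)
    III = (0, 1)
    IV = (0, 0)


class UnclassifiableCall(ValueError):
    """A missing digest call cannot be assigned a band type."""


def classify_band_type(m_call: int, h_call: int) -> BandType:
    """Map one (M, H) call pair to its band type; missing calls raise."""
    if m_call is None or h_call is None or m_call != m_call or h_call != h_call:
        raise UnclassifiableCall("missing digest call")
    if m_call not in (0, 1) or h_call not in (0, 1):
        raise ValueError(f"calls must be binary, got ({m_call}, {h_call})")
    return BandType((int(m_call), int(h_call)))


@dataclass(frozen=True)
class BandTypeCounts:
    """Pooled band-type counts for one sample group."""

    group: str
    n_I: int
    n_II: int
    n_III: int
    n_IV: int

    def __post_init__(self) -> None:
        for v in (self.n_I, self.n_II, self.n_III, self.n_IV):
            if v < 0 or int(v) != v:
                raise ValueError("band-type counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.n_I + self.n_II + self.n_III + self.n_IV

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.n_I, self.n_II, self.n_III, self.n_IV)


RATE_NAMES = ("total", "full", "hemi", "non")


@dataclass(frozen=True)
class MethylationProfile:
    """Group methylation rates as percentages in [0, 100].

    Invariants: total + non == 100 and full + hemi <= total (type IV carries
    the remainder, exposed separately as ``type_iv_pct``).
    """

    total_pct: float
    full_pct: float
    hemi_pct: float
    non_pct: float

    @property
    def type_iv_pct(self) -> float:
        return self.total_pct - self.full_pct - self.hemi_pct

    def rate(self, name: str) -> float:
        return getattr(self, f"{name}_pct")

    def rounded(self, ndigits: int = 2) -> "MethylationProfile":
        return MethylationProfile(
            *(round_half_up(self.rate(n), ndigits) for n in RATE_NAMES)
        )


def round_half_up(value, ndigits: int = 2) -> float:
    """Round-half-up (0.005 -> 0.01), exact for Fraction inputs.

    Floats pass through ``Decimal(str(...))`` so the decimal literal a human
    would write is what gets rounded, not its binary expansion.
    """
    if isinstance(value, Fraction):
        with localcontext() as ctx:
            ctx.prec = 50
            d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(str(value))
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def methylation_rates(counts: BandTypeCounts, ndigits: int | None = None) -> MethylationProfile:
    """Percent total/full/hemi/non methylation from pooled band-type counts.

    Percentages are exact rationals internally; ``ndigits`` applies
    round-half-up for reporting (the tables' display convention), ``None``
    keeps full float precision.
    """
    if counts.total == 0:
        raise ValueError(f"group {counts.group!r} has zero classified bands")
    t = counts.total
    fracs = (
        Fraction(100 * (counts.n_II + counts.n_III + counts.n_IV), t),
        Fraction(100 * counts.n_II, t),
        Fraction(100 * counts.n_III, t),
        Fraction(100 * counts.n_I, t),
    )
    if ndigits is None:
        return MethylationProfile(*(float(f) for f in fracs))
    return MethylationProfile(*(round_half_up(f, ndigits) for f in fracs))


def count_band_types(matrix: BandMatrix, grouping: Grouping) -> list[BandTypeCounts]:
    """Pool band-type counts per group over all complete (sample, locus) pairs.

    Loci with a missing call for a sample are excluded for that sample only.
    Group order follows first appearance in the matrix's sample order; counts
    over any partition of the samples sum to the whole-matrix counts.
    """
    labels = np.asarray(grouping.labels_for(matrix.sample_ids))
    ok = ~matrix.missing
    # band-type index 0..3 == I, II, III, IV via 2*(1-m) + (m XOR h) trick;
    # simpler: code = (1-m)*2 + (m==h ? 0 : 1) -- just enumerate
    code = np.full(matrix.calls_m.shape, -1, dtype=np.int8)
    m, h = matrix.calls_m, matrix.calls_h
    code[(m == 1) & (h == 1)] = 0
    code[(m == 1) & (h == 0)] = 1
    code[(m == 0) & (h == 1)] = 2
    code[(m == 0) & (h == 0)] = 3
    out = []
    seen: dict[str, None] = {}
    for lab in labels:
        seen.setdefault(lab)
    for g in seen:
        rows = labels == g
        if not rows.any():
            raise ValueError(f"empty group {g!r}")
        sel = code[rows][ok[rows]]
        n = np.bincount(sel, minlength=4)
        out.append(BandTypeCounts(g, *(int(v) for v in n)))
    return out


def rate_contrasts(
    profiles: list[tuple[str, MethylationProfile]],
    reference: str,
    class_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Unweighted class means of each rate and their offset from a reference.

    ``profiles`` are (group, profile) pairs, typically at the 2-decimal
    reporting precision so published per-group tables can be averaged the way
    their summary statistics were.  ``class_map`` maps each group label to a
    treatment class; groups absent from the map keep their own label as
    class.  Returns a tidy frame with columns ``class``, ``rate``, ``mean``
    and ``delta_vs_reference`` (class mean minus the reference group's rate).
    """
    groups = dict(profiles)
    if reference not in groups:
        raise ValueError(f"reference group {reference!r} not among profiles")
    ref = groups[reference]
    class_map = class_map or {}
    classes: dict[str, list[MethylationProfile]] = {}
    for g, prof in profiles:
        classes.setdefault(class_map.get(g, g), []).append(prof)
    rows = []
    for cls, members in classes.items():
        for rate in RATE_NAMES:
            mean = float(np.mean([p.rate(rate) for p in members]))
            rows.append(
                {
                    "class": cls,
                    "rate": rate,
                    "mean": mean,
                    "delta_vs_reference": mean - ref.rate(rate),
                }
            )
    return pd.DataFrame(rows)
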