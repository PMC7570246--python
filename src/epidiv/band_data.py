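"""Domain types, validation and I/O for scored MSAP/TMD band matrices.

An MSAP (methylation-sensitive amplified polymorphism) experiment scores every
locus twice per sample: once after an MseI/MspI digest (the "M" call) and once
after an MseI/HpaII digest (the "H" call).  HpaII and MspI are isoschizomers of
the 5'-CCGG-3' site with different methylation sensitivity, so the (M, H)
presence pattern at a locus encodes its methylation state.  TMD (transposon
methylation display) produces matrices of the same shape, anchored at a
transposon-specific primer.

The file dialect is one row per sample with paired columns ``<locus>__M`` and
``<locus>__H``; calls are 0 (band absent), 1 (band present) or ``NA``
(indistinct band, excluded from downstream counting).  Sample metadata lives in
a separate delimited file keyed by ``sample_id``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MARKER_SYSTEMS",
    "TREATMENT_CLASSES",
    "SampleMeta",
    "BandMatrix",
    "Grouping",
    "BandMatrixError",
    "read_band_matrix",
    "write_band_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "merge_marker_systems",
]

MARKER_SYSTEMS = ("MSAP", "TMD", "MERGED")
TREATMENT_CLASSES = ("Control", "GR", "DNMTi", "DNMTi+GR")
DNMTI_AGENTS = ("none", "AZA", "ZEB")

MISSING_TOKEN = "NA"


class BandMatrixError(ValueError):
    """Raised for malformed band matrices or metadata."""


@dataclass(frozen=True)
class SampleMeta:
    """Treatment metadata for one plant.

    ``treatment_class`` is derived, never stored: a sample is ``GR`` if it
    received a nonzero gamma dose only, ``DNMTi`` if it received a
    methyltransferase-inhibitor soak only, ``DNMTi+GR`` for both and
    ``Control`` for neither.
    """

    sample_id: str
    treatment_group: str
    gamma_dose: float = 0.0  # Gy
    dnmti_agent: str = "none"  # AZA | ZEB | none
    dnmti_conc: float = 0.0  # uM

    def __post_init__(self) -> None:
        if self.dnmti_agent not in DNMTI_AGENTS:
            raise BandMatrixError(
                f"unknown DNMTi agent {self.dnmti_agent!r} for sample "
                f"{self.sample_id!r}; expected one of {DNMTI_AGENTS}"
            )
        if self.gamma_dose < 0 or self.dnmti_conc < 0:
            raise BandMatrixError(f"negative dose for sample {self.sample_id!r}")
        if (self.dnmti_agent != "none") != (self.dnmti_conc > 0):
            raise BandMatrixError(
                f"sample {self.sample_id!r}: DNMTi agent and concentration disagree"
            )

    @property
    def treatment_class(self) -> str:
        gr = self.gamma_dose > 0
        dn = self.dnmti_agent != "none"
        if gr and dn:
            return "DNMTi+GR"
        if gr:
            return "GR"
        if dn:
            return "DNMTi"
        return "Control"


@dataclass
class BandMatrix:
    """Paired-digest presence calls for one marker system.

    ``calls_m`` / ``calls_h`` are int8 arrays of shape (n_samples, n_loci)
    with entries in {0, 1}; positions flagged in ``missing`` carry no
    information and their stored call value is ignored.
    """

    marker_system: str
    locus_ids: list[str]
    samples: list[SampleMeta]
    calls_m: np.ndarray
    calls_h: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.marker_system not in MARKER_SYSTEMS:
            raise BandMatrixError(f"unknown marker system {self.marker_system!r}")
        self.calls_m = np.asarray(self.calls_m, dtype=np.int8)
        self.calls_h = np.asarray(self.calls_h, dtype=np.int8)
        shape = (len(self.samples), len(self.locus_ids))
        if self.calls_m.shape != shape or self.calls_h.shape != shape:
            raise BandMatrixError(
                f"call arrays {self.calls_m.shape}/{self.calls_h.shape} do not "
                f"match {len(self.samples)} samples x {len(self.locus_ids)} loci"
            )
        if self.missing is None:
            self.missing = np.zeros(shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != shape:
                raise BandMatrixError("missing mask shape mismatch")
        ok = self.missing | (((self.calls_m == 0) | (self.calls_m == 1))
                             & ((self.calls_h == 0) | (self.calls_h == 1)))
        if not ok.all():
            i, j = map(int, np.argwhere(~ok)[0])
            raise BandMatrixError(
                f"non-binary call at sample {self.samples[i].sample_id!r}, "
                f"locus {self.locus_ids[j]!r}"
            )
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise BandMatrixError("duplicate locus ids")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise BandMatrixError("duplicate sample ids")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def band_table(self) -> pd.DataFrame:
        """All scored bands as one sample x (2*loci) frame of floats.

        Columns are ``<locus>__M`` then ``<locus>__H`` per locus, in locus
        order; missing calls are NaN.  This is the flattened binary-phenotype
        view that distance and diversity computations operate on.
        """
        data = np.empty((self.n_samples, 2 * self.n_loci), dtype=float)
        data[:, 0::2] = self.calls_m
        data[:, 1::2] = self.calls_h
        miss = np.repeat(self.missing, 2, axis=1)
        data[miss] = np.nan
        cols = []
        for loc in self.locus_ids:
            cols += [f"{loc}__M", f"{loc}__H"]
        return pd.DataFrame(data, index=self.sample_ids, columns=cols)

    def equals(self, other: "BandMatrix") -> bool:
        return (
            self.marker_system == other.marker_system
            and self.locus_ids == other.locus_ids
            and self.samples == other.samples
            and bool(np.array_equal(self.missing, other.missing))
            and bool(((self.calls_m == other.calls_m) | self.missing).all())
            and bool(((self.calls_h == other.calls_h) | self.missing).all())
        )


@dataclass(frozen=True)
class Grouping:
    """Assignment of every sample to exactly one group label."""

    level: str  # "treatment_group" | "treatment_class" (or free-form)
    assignment: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_samples(cls, samples: list[SampleMeta], level: str) -> "Grouping":
        if level not in ("treatment_group", "treatment_class"):
            raise BandMatrixError(f"unknown grouping level {level!r}")
        assignment = {
            s.sample_id: (s.treatment_group if level == "treatment_group"
                          else s.treatment_class)
            for s in samples
        }
        return cls(level=level, assignment=assignment)

    def labels_for(self, sample_ids: list[str]) -> list[str]:
        try:
            return [self.assignment[s] for s in sample_ids]
        except KeyError as exc:
            raise BandMatrixError(f"sample {exc.args[0]!r} not in grouping") from None

    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g)
        return list(seen)


def _read_delimited(path) -> pd.DataFrame:
    """Read CSV with tab auto-detection, keeping NA tokens intact."""
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
        fh.seek(0)
        sep = "\t" if "\t" in head else ","
        return pd.read_csv(fh, sep=sep, dtype=str, keep_default_na=False)


def read_sample_metadata(meta_path) -> dict[str, SampleMeta]:
    df = _read_delimited(meta_path)
    required = {"sample_id", "treatment_group"}
    if not required.issubset(df.columns):
        raise BandMatrixError(f"metadata must contain columns {sorted(required)}")
    metas: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        m = SampleMeta(
            sample_id=row["sample_id"],
            treatment_group=row["treatment_group"],
            gamma_dose=float(row.get("gamma_dose", 0) or 0),
            dnmti_agent=str(row.get("dnmti_agent", "none") or "none"),
            dnmti_conc=float(row.get("dnmti_conc", 0) or 0),
        )
        if m.sample_id in metas:
            raise BandMatrixError(f"duplicate sample {m.sample_id!r} in metadata")
        metas[m.sample_id] = m
    return metas


def write_sample_metadata(samples: list[SampleMeta], path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "treatment_group": [s.treatment_group for s in samples],
            "treatment_class": [s.treatment_class for s in samples],
            "gamma_dose": [s.gamma_dose for s in samples],
            "dnmti_agent": [s.dnmti_agent for s in samples],
            "dnmti_conc": [s.dnmti_conc for s in samples],
        }
    )
    df.to_csv(path, index=False)


def read_band_matrix(path, meta_path, marker_system: str) -> BandMatrix:
    """Read a scored band matrix plus its metadata file.

    Cells must be 0, 1 or ``NA``; anything else is rejected with the sample
    and locus named.  Samples keep file order.
    """
    df = _read_delimited(path)
    if "sample_id" not in df.columns:
        raise BandMatrixError("band matrix must have a sample_id column")
    call_cols = [c for c in df.columns if c != "sample_id"]
    loci_m = [c[:-3] for c in call_cols if c.endswith("__M")]
    loci_h = [c[:-3] for c in call_cols if c.endswith("__H")]
    if loci_m != loci_h:
        raise BandMatrixError(
            "M and H column blocks do not pair up: "
            f"{sorted(set(loci_m) ^ set(loci_h))}"
        )
    stray = [c for c in call_cols if not (c.endswith("__M") or c.endswith("__H"))]
    if stray:
        raise BandMatrixError(f"unrecognised columns (need __M/__H suffix): {stray}")
    metas = read_sample_metadata(meta_path)
    samples = []
    for sid in df["sample_id"]:
        if sid not in metas:
            raise BandMatrixError(f"sample {sid!r} missing from metadata")
        samples.append(metas[sid])

    n, k = len(samples), len(loci_m)
    calls_m = np.zeros((n, k), dtype=np.int8)
    calls_h = np.zeros((n, k), dtype=np.int8)
    missing = np.zeros((n, k), dtype=bool)

    def parse(col: str, out: np.ndarray, j: int) -> None:
        for i, raw in enumerate(df[col]):
            v = raw.strip()
            if v == MISSING_TOKEN:
                missing[i, j] = True
            elif v in ("0", "1"):
                out[i, j] = int(v)
            else:
                raise BandMatrixError(
                    f"non-binary cell {raw!r} at sample "
                    f"{df['sample_id'].iloc[i]!r}, column {col!r}"
                )

    for j, loc in enumerate(loci_m):
        parse(f"{loc}__M", calls_m, j)
        parse(f"{loc}__H", calls_h, j)
    # an indistinct band in either digest voids the locus for that sample
    return BandMatrix(marker_system, loci_m, samples, calls_m, calls_h, missing)


def write_band_matrix(matrix: BandMatrix, path) -> None:
    """Write a matrix in the ``<locus>__M,<locus>__H`` dialect (re-readable)."""
    cols: dict[str, list[str]] = {"sample_id": matrix.sample_ids}
    for j, loc in enumerate(matrix.locus_ids):
        m_col, h_col = [], []
        for i in range(matrix.n_samples):
            if matrix.missing[i, j]:
                m_col.append(MISSING_TOKEN)
                h_col.append(MISSING_TOKEN)
            else:
                m_col.append(str(int(matrix.calls_m[i, j])))
                h_col.append(str(int(matrix.calls_h[i, j])))
        cols[f"{loc}__M"] = m_col
        cols[f"{loc}__H"] = h_col
    pd.DataFrame(cols).to_csv(path, index=False)


def merge_marker_systems(a: BandMatrix, b: BandMatrix) -> BandMatrix:
    """Concatenate two marker systems over the same samples.

    Locus ids are namespaced by source system so e.g. MSAP ``L1`` and TMD
    ``L1`` stay distinct; sample order follows the first argument.
    """
    if set(a.sample_ids) != set(b.sample_ids):
        raise BandMatrixError("cannot merge: sample sets differ")
    order = [b.sample_ids.index(s) for s in a.sample_ids]
    loci = [f"{a.marker_system}:{loc}" for loc in a.locus_ids] + [
        f"{b.marker_system}:{loc}" for loc in b.locus_ids
    ]
    calls_m = np.hstack([a.calls_m, b.calls_m[order]])
    calls_h = np.hstack([a.calls_h, b.calls_h[order]])
    missing = np.hstack([a.missing, b.missing[order]])
    return BandMatrix("MERGED", loci, list(a.samples), calls_m, calls_h, missing)


def to_genalex(matrix: BandMatrix, grouping: Grouping) -> str:
    """GenAlEx-style binary export (header: n loci, n samples, n groups)."""
    labels = grouping.labels_for(matrix.sample_ids)
    groups = grouping.groups()
    sizes = [labels.count(g) for g in groups]
    table = matrix.band_table()
    buf = io.StringIO()
    n_bands = table.shape[1]
    buf.write(f"{n_bands},{matrix.n_samples},{len(groups)},"
              + ",".join(str(s) for s in sizes) + "\n")
    buf.write(f"{matrix.marker_system},,," + ",".join(groups) + "\n")
    buf.write("sample_id,group," + ",".join(table.columns) + "\n")
    for sid, lab in zip(matrix.sample_ids, labels):
        row = table.loc[sid]
        vals = ["-9" if np.isnan(v) else str(int(v)) for v in row]
        buf.write(f"{sid},{lab}," + ",".join(vals) + "\n")
    return buf.getvalue()


def subset_samples(matrix: BandMatrix, sample_ids: list[str]) -> BandMatrix:
    idx = [matrix.sample_ids.index(s) for s in sample_ids]
    return replace(
        matrix,
        samples=[matrix.samples[i] for i in idx],
        calls_m=matrix.calls_m[idx],
        calls_h=matrix.calls_h[idx],
        missing=matrix.missing[idx],
    )
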