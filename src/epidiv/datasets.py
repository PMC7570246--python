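"""Reference band-type count tables from a published rice mutagenesis study.

A 93-plant rice (*Oryza sativa* ssp. *japonica*) experiment crossed gamma
irradiation (100/150/250 Gy) with DNA-methyltransferase-inhibitor seed soaks
(5-azacytidine or zebularine, 80 uM) and scored MSAP (102 loci) and TMD
(60 loci, p-SINE1-anchored) band profiles.  The raw 0/1 matrices were not
deposited, but the pooled band-type counts per treatment group were published
and are reproduced here so the rate machinery can be exercised against known
printed percentages.  Counts are (type I, II, III, IV) per group.

The column label "A80+G150" appears in the source under an inconsistent
heading ("A80 + Z150"); the design makes clear it is the AZA 80 uM + 150 Gy
group, and it is recorded as such here.
"""

from __future__ import annotations

from .methylation import BandTypeCounts

__all__ = [
    "GROUP_ORDER",
    "TREATMENT_CLASS_OF_GROUP",
    "GROUP_DESIGN",
    "rice_msap_counts",
    "rice_tmd_counts",
    "rice_polymorphic_counts",
]

GROUP_ORDER = (
    "Control", "G100", "G150", "G250", "A80", "Z80",
    "A80+G100", "A80+G150", "Z80+G100", "Z80+G150",
)

TREATMENT_CLASS_OF_GROUP = {
    "Control": "Control",
    "G100": "GR", "G150": "GR", "G250": "GR",
    "A80": "DNMTi", "Z80": "DNMTi",
    "A80+G100": "DNMTi+GR", "A80+G150": "DNMTi+GR",
    "Z80+G100": "DNMTi+GR", "Z80+G150": "DNMTi+GR",
}

# (group, n_samples, gamma dose Gy, DNMTi agent, DNMTi conc uM); 93 plants total
GROUP_DESIGN = (
    ("Control", 5, 0.0, "none", 0.0),
    ("G100", 8, 100.0, "none", 0.0),
    ("G150", 8, 150.0, "none", 0.0),
    ("G250", 8, 250.0, "none", 0.0),
    ("A80", 8, 0.0, "AZA", 80.0),
    ("Z80", 8, 0.0, "ZEB", 80.0),
    ("A80+G100", 12, 100.0, "AZA", 80.0),
    ("A80+G150", 12, 150.0, "AZA", 80.0),
    ("Z80+G100", 12, 100.0, "ZEB", 80.0),
    ("Z80+G150", 12, 150.0, "ZEB", 80.0),
)

_MSAP_COUNTS = {
    "Control": (221, 70, 102, 142),
    "G100": (336, 100, 126, 246),
    "G150": (337, 67, 97, 317),
    "G250": (338, 84, 84, 288),
    "A80": (363, 57, 54, 331),
    "Z80": (362, 59, 48, 324),
    "A80+G100": (573, 90, 83, 498),
    "A80+G150": (580, 92, 78, 512),
    "Z80+G100": (550, 96, 82, 485),
    "Z80+G150": (586, 102, 46, 503),
}

_TMD_COUNTS = {
    "Control": (97, 53, 16, 61),
    "G100": (148, 54, 45, 119),
    "G150": (162, 52, 46, 126),
    "G250": (164, 55, 48, 127),
    "A80": (166, 51, 66, 115),
    "Z80": (167, 49, 64, 112),
    "A80+G100": (254, 44, 115, 127),
    "A80+G150": (266, 43, 121, 132),
    "Z80+G100": (287, 44, 121, 133),
    "Z80+G150": (299, 41, 130, 121),
}

# (n_polymorphic, n_loci) totals over all 93 samples per marker system
_POLYMORPHIC = {"MSAP": (66, 102), "TMD": (41, 60)}


def rice_msap_counts() -> list[BandTypeCounts]:
    """MSAP band-type counts (types I-IV) per treatment group, 102 loci."""
    return [BandTypeCounts(g, *_MSAP_COUNTS[g]) for g in GROUP_ORDER]


def rice_tmd_counts() -> list[BandTypeCounts]:
    """TMD band-type counts (types I-IV) per treatment group, 60 loci."""
    return [BandTypeCounts(g, *_TMD_COUNTS[g]) for g in GROUP_ORDER]


def rice_polymorphic_counts(marker_system: str) -> tuple[int, int]:
    """(polymorphic loci, total loci) over all samples for a marker system."""
    return _POLYMORPHIC[marker_system]
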