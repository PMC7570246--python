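from fractions import Fraction

import numpy as np
import pytest

from epidiv.band_data import BandMatrix, Grouping
from epidiv.datasets import (
    GROUP_ORDER,
    TREATMENT_CLASS_OF_GROUP,
    rice_msap_counts,
    rice_tmd_counts,
)
from epidiv.methylation import (
    BandType,
    BandTypeCounts,
    MethylationProfile,
    UnclassifiableCall,
    classify_band_type,
    count_band_types,
    methylation_rates,
    rate_contrasts,
    round_half_up,
)

from conftest import make_samples, random_matrix


class TestClassification:
    @pytest.mark.parametrize(
        "m,h,expected",
        [(1, 1, BandType.I), (1, 0, BandType.II), (0, 1, BandType.III), (0, 0, BandType.IV)],
    )
    def test_band_type_codes(self, m, h, expected):
        assert classify_band_type(m, h) is expected

    def test_missing_call_unclassifiable(self):
        with pytest.raises(UnclassifiableCall):
            classify_band_type(float("nan"), 1)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            classify_band_type(2, 0)


class TestCounting:
    def test_single_sample_enumeration(self):
        samples = make_samples([("A", 1, 0.0, "none", 0.0)])
        m = BandMatrix("MSAP", [f"L{i}" for i in range(4)], samples,
                       np.array([[1, 1, 0, 0]]), np.array([[1, 0, 1, 0]]))
        grouping = Grouping("treatment_group", {samples[0].sample_id: "A"})
        (c,) = count_band_types(m, grouping)
        assert c.as_tuple() == (1, 1, 1, 1)

    def test_counts_match_simulator_truth(self, sim_default):
        cfg, bm, truth = sim_default
        grouping = Grouping.from_samples(bm.samples, "treatment_group")
        counts = {c.group: np.array(c.as_tuple()) for c in count_band_types(bm, grouping)}
        for g, tally in truth.group_tallies().items():
            assert np.array_equal(counts[g], tally)

    def test_partition_additivity(self, rng):
        bm = random_matrix(rng, n_samples=8, n_loci=10, p_missing=0.2)
        two = Grouping.from_samples(bm.samples, "treatment_group")
        one = Grouping("treatment_group", {s: "all" for s in bm.sample_ids})
        parts = count_band_types(bm, two)
        (whole,) = count_band_types(bm, one)
        total = np.sum([p.as_tuple() for p in parts], axis=0)
        assert tuple(total) == whole.as_tuple()
        # missing pairs excluded, complete pairs all counted
        assert whole.total == int((~bm.missing).sum())

    def test_sample_and_locus_permutation_invariance(self, rng):
        bm = random_matrix(rng, n_samples=6, n_loci=9, p_missing=0.1)
        grouping = Grouping.from_samples(bm.samples, "treatment_group")
        base = {c.group: c.as_tuple() for c in count_band_types(bm, grouping)}
        sperm = rng.permutation(bm.n_samples)
        lperm = rng.permutation(bm.n_loci)
        shuffled = BandMatrix(
            bm.marker_system,
            [bm.locus_ids[j] for j in lperm],
            [bm.samples[i] for i in sperm],
            bm.calls_m[np.ix_(sperm, lperm)],
            bm.calls_h[np.ix_(sperm, lperm)],
            bm.missing[np.ix_(sperm, lperm)],
        )
        assert {c.group: c.as_tuple() for c in count_band_types(shuffled, grouping)} == base

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            BandTypeCounts("g", -1, 0, 0, 0)


# Published band-type count tables and their printed percentages
# (total, full, hemi, non) per treatment group.
MSAP_PRINTED = {
    "Control": (58.69, 13.08, 19.07, 41.31), "G100": (58.42, 12.38, 15.59, 41.58),
    "G150": (58.80, 8.19, 11.86, 41.20), "G250": (57.43, 10.58, 10.58, 42.57),
    "A80": (54.91, 7.08, 6.71, 45.09), "Z80": (54.35, 7.44, 6.05, 45.65),
    "A80+G100": (53.94, 7.23, 6.67, 46.06), "A80+G150": (54.04, 7.29, 6.18, 45.96),
    "Z80+G100": (54.66, 7.91, 6.76, 45.34), "Z80+G150": (52.63, 8.25, 3.72, 47.37),
}
TMD_PRINTED = {
    "Control": (57.27, 23.35, 7.05, 42.73), "G100": (59.56, 14.75, 12.30, 40.44),
    "G150": (58.03, 13.47, 11.92, 41.97), "G250": (58.38, 13.96, 12.18, 41.62),
    "A80": (58.29, 12.81, 16.58, 41.71), "Z80": (57.40, 12.50, 16.33, 42.60),
    "A80+G100": (52.96, 8.15, 21.30, 47.04), "A80+G150": (52.67, 7.65, 21.53, 47.33),
    "Z80+G100": (50.94, 7.52, 20.68, 49.06), "Z80+G150": (49.41, 6.94, 22.00, 50.59),
}


class TestRates:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((221, 70, 102, 142), (58.69, 13.08, 19.07, 41.31)),
            ((97, 53, 16, 61), (57.27, 23.35, 7.05, 42.73)),
        ],
    )
    def test_reference_control_columns(self, counts, expected):
        prof = methylation_rates(BandTypeCounts("ctl", *counts), ndigits=2)
        assert (prof.total_pct, prof.full_pct, prof.hemi_pct, prof.non_pct) == expected

    @pytest.mark.parametrize("table,printed", [
        (rice_msap_counts, MSAP_PRINTED), (rice_tmd_counts, TMD_PRINTED)
    ], ids=["MSAP", "TMD"])
    def test_every_published_cell_reproduced(self, table, printed):
        """All 40 percentage cells per marker table match at 2 decimals."""
        for c in table():
            prof = methylation_rates(c, ndigits=2)
            got = (prof.total_pct, prof.full_pct, prof.hemi_pct, prof.non_pct)
            assert got == printed[c.group], c.group

    def test_all_unmethylated_limit(self):
        prof = methylation_rates(BandTypeCounts("g", 7, 0, 0, 0))
        assert prof.total_pct == 0.0 and prof.non_pct == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            methylation_rates(BandTypeCounts("g", 0, 0, 0, 0))

    def test_exact_rational_identities(self, rng):
        """total+non == 100 and full+hemi+IV-share == total, exactly."""
        for _ in range(100):
            counts = BandTypeCounts("g", *(int(v) for v in rng.integers(0, 50, 4)))
            if counts.total == 0:
                continue
            t = counts.total
            fr = {
                "total": Fraction(100 * (counts.n_II + counts.n_III + counts.n_IV), t),
                "full": Fraction(100 * counts.n_II, t),
                "hemi": Fraction(100 * counts.n_III, t),
                "non": Fraction(100 * counts.n_I, t),
                "iv": Fraction(100 * counts.n_IV, t),
            }
            assert fr["total"] + fr["non"] == 100
            assert fr["full"] + fr["hemi"] + fr["iv"] == fr["total"]
            prof = methylation_rates(counts)
            assert prof.total_pct == pytest.approx(float(fr["total"]))
            assert prof.type_iv_pct == pytest.approx(float(fr["iv"]))

    def test_round_half_up_behaviour(self):
        assert round_half_up(7.565) == 7.57
        assert round_half_up(12.655) == 12.66
        assert round_half_up(Fraction(5869159, 1000000), 2) == 5.87


class TestContrasts:
    @staticmethod
    def _profiles(table_fn):
        return [(c.group, methylation_rates(c, ndigits=2)) for c in table_fn()]

    def test_msap_combined_total_reduction(self):
        """Mean total-methylation drop of the combined class vs control: 4.87."""
        contrasts = rate_contrasts(self._profiles(rice_msap_counts), "Control",
                                   TREATMENT_CLASS_OF_GROUP)
        row = contrasts[(contrasts["class"] == "DNMTi+GR") & (contrasts.rate == "total")]
        assert round_half_up(-float(row.delta_vs_reference.iloc[0])) == 4.87

    @pytest.mark.parametrize("cls,rate,expected", [
        ("GR", "full", 14.06), ("DNMTi", "full", 12.66),
        ("GR", "hemi", 12.13), ("DNMTi", "hemi", 16.46),
        ("DNMTi+GR", "hemi", 21.38),
    ])
    def test_tmd_class_means(self, cls, rate, expected):
        contrasts = rate_contrasts(self._profiles(rice_tmd_counts), "Control",
                                   TREATMENT_CLASS_OF_GROUP)
        row = contrasts[(contrasts["class"] == cls) & (contrasts.rate == rate)]
        assert round_half_up(float(row["mean"].iloc[0])) == expected

    def test_reference_contrasted_with_itself_is_zero(self):
        profs = self._profiles(rice_msap_counts)
        contrasts = rate_contrasts(profs, "Control", TREATMENT_CLASS_OF_GROUP)
        ref_rows = contrasts[contrasts["class"] == "Control"]
        assert (ref_rows.delta_vs_reference == 0).all()

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            rate_contrasts(self._profiles(rice_msap_counts), "NotAGroup")

    def test_class_means_unweighted(self):
        profs = [
            ("a", MethylationProfile(10.0, 1.0, 1.0, 90.0)),
            ("b", MethylationProfile(30.0, 1.0, 1.0, 70.0)),
            ("ref", MethylationProfile(0.0, 0.0, 0.0, 100.0)),
        ]
        out = rate_contrasts(profs, "ref", {"a": "X", "b": "X"})
        row = out[(out["class"] == "X") & (out.rate == "total")]
        assert float(row["mean"].iloc[0]) == 20.0
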