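import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epidiv.band_data import (
    BandMatrix,
    BandMatrixError,
    Grouping,
    SampleMeta,
    merge_marker_systems,
    read_band_matrix,
    write_band_matrix,
    write_sample_metadata,
)
from epidiv.distances import pairwise_distance

from conftest import make_samples, random_matrix


class TestSampleMeta:
    @pytest.mark.parametrize(
        "dose,agent,conc,expected",
        [
            (0.0, "none", 0.0, "Control"),
            (150.0, "none", 0.0, "GR"),
            (0.0, "AZA", 80.0, "DNMTi"),
            (100.0, "ZEB", 80.0, "DNMTi+GR"),
        ],
    )
    def test_treatment_class_derived_from_exposure(self, dose, agent, conc, expected):
        s = SampleMeta("s1", "g", dose, agent, conc)
        assert s.treatment_class == expected

    def test_inconsistent_dnmti_fields_rejected(self):
        with pytest.raises(BandMatrixError):
            SampleMeta("s1", "g", 0.0, "AZA", 0.0)
        with pytest.raises(BandMatrixError):
            SampleMeta("s1", "g", 0.0, "none", 80.0)


class TestIO:
    def _write_pair(self, tmp_path, matrix):
        mp = tmp_path / "m.csv"
        meta = tmp_path / "meta.csv"
        write_band_matrix(matrix, mp)
        write_sample_metadata(matrix.samples, meta)
        return mp, meta

    def test_round_trip_identity(self, tmp_path, rng):
        m = random_matrix(rng, n_samples=2, n_loci=3)
        mp, meta = self._write_pair(tmp_path, m)
        back = read_band_matrix(mp, meta, "MSAP")
        assert back.equals(m)
        assert back.n_loci == 3 and back.n_samples == 2

    def test_round_trip_with_missing_mask(self, tmp_path, rng):
        m = random_matrix(rng, p_missing=0.3)
        mp, meta = self._write_pair(tmp_path, m)
        back = read_band_matrix(mp, meta, "MSAP")
        assert np.array_equal(back.missing, m.missing)
        assert back.equals(m)
        assert "NA" in mp.read_text()

    def test_round_trip_simulated_study_size(self, tmp_path, sim_default):
        _, bm, _ = sim_default
        mp = tmp_path / "m.csv"
        meta = tmp_path / "meta.csv"
        write_band_matrix(bm, mp)
        write_sample_metadata(bm.samples, meta)
        back = read_band_matrix(mp, meta, "MSAP")
        assert back.equals(bm)
        # second write is byte-identical (stable dialect)
        mp2 = tmp_path / "m2.csv"
        write_band_matrix(back, mp2)
        assert mp.read_bytes() == mp2.read_bytes()

    def test_empty_locus_matrix_writes_header_only(self, tmp_path):
        samples = make_samples([("A", 2, 0.0, "none", 0.0)])
        m = BandMatrix("MSAP", [], samples, np.zeros((2, 0)), np.zeros((2, 0)))
        mp = tmp_path / "m.csv"
        write_band_matrix(m, mp)
        lines = mp.read_text().strip().splitlines()
        assert lines[0] == "sample_id"
        assert len(lines) == 3

    def test_non_binary_cell_names_sample_and_column(self, tmp_path, rng):
        m = random_matrix(rng, n_samples=2, n_loci=2)
        mp, meta = self._write_pair(tmp_path, m)
        lines = mp.read_text().splitlines()
        fields = lines[2].split(",")
        fields[1] = "2"  # first call column of the second sample
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join([lines[0], lines[1], ",".join(fields)]) + "\n")
        second_id = lines[2].split(",")[0]
        with pytest.raises(BandMatrixError) as exc:
            read_band_matrix(bad, meta, "MSAP")
        assert "L0__M" in str(exc.value) and second_id in str(exc.value)

    def test_unknown_sample_in_matrix_rejected(self, tmp_path, rng):
        m = random_matrix(rng, n_samples=3, n_loci=2)
        mp = tmp_path / "m.csv"
        meta = tmp_path / "meta.csv"
        write_band_matrix(m, mp)
        write_sample_metadata(m.samples[:2], meta)
        with pytest.raises(BandMatrixError, match="missing from metadata"):
            read_band_matrix(mp, meta, "MSAP")

    def test_tab_delimited_autodetect(self, tmp_path, rng):
        m = random_matrix(rng, n_samples=2, n_loci=2)
        mp, meta = self._write_pair(tmp_path, m)
        tsv = tmp_path / "m.tsv"
        tsv.write_text(mp.read_text().replace(",", "\t"))
        assert read_band_matrix(tsv, meta, "MSAP").equals(m)

    @given(seed=st.integers(0, 2**32 - 1), p_missing=st.floats(0.0, 0.4))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_round_trip_property(self, tmp_path_factory, seed, p_missing):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_samples=int(rng.integers(2, 6)),
                          n_loci=int(rng.integers(1, 7)), p_missing=p_missing)
        tmp = tmp_path_factory.mktemp("rt")
        mp = tmp / "m.csv"
        meta = tmp / "meta.csv"
        write_band_matrix(m, mp)
        write_sample_metadata(m.samples, meta)
        assert read_band_matrix(mp, meta, "MSAP").equals(m)


class TestValidation:
    def test_non_binary_array_rejected_with_coordinates(self):
        samples = make_samples([("A", 2, 0.0, "none", 0.0)])
        calls = np.array([[0, 1], [2, 0]], dtype=np.int8)
        with pytest.raises(BandMatrixError, match="A_1.*L0"):
            BandMatrix("MSAP", ["L0", "L1"], samples, calls, np.zeros_like(calls))

    def test_shape_mismatch_rejected(self):
        samples = make_samples([("A", 2, 0.0, "none", 0.0)])
        with pytest.raises(BandMatrixError, match="do not match"):
            BandMatrix("MSAP", ["L0"], samples, np.zeros((2, 1)), np.zeros((2, 2)))

    def test_grouping_requires_known_samples(self, small_matrix):
        g = Grouping("treatment_group", {"nope": "A"})
        with pytest.raises(BandMatrixError):
            g.labels_for(small_matrix.sample_ids)


class TestMerge:
    def test_merged_locus_count_is_sum(self, rng):
        a = random_matrix(rng, n_loci=102)
        b = random_matrix(np.random.default_rng(1), n_loci=60, marker="TMD")
        merged = merge_marker_systems(a, b)
        assert merged.n_loci == 162
        assert merged.marker_system == "MERGED"
        assert merged.sample_ids == a.sample_ids

    def test_merge_with_empty_namespaces_ids(self, rng):
        a = random_matrix(rng, n_loci=3)
        samples = list(a.samples)
        empty = BandMatrix("TMD", [], samples, np.zeros((len(samples), 0)),
                           np.zeros((len(samples), 0)))
        merged = merge_marker_systems(a, empty)
        assert merged.locus_ids == [f"MSAP:{loc}" for loc in a.locus_ids]
        assert np.array_equal(merged.calls_m, a.calls_m)

    def test_differing_sample_sets_rejected(self, rng):
        a = random_matrix(rng)
        b = random_matrix(rng, groups=[("C", 4, 0.0, "none", 0.0)])
        with pytest.raises(BandMatrixError, match="sample sets differ"):
            merge_marker_systems(a, b)

    def test_merge_reorders_second_argument_by_id(self, rng):
        a = random_matrix(rng, n_samples=4, n_loci=2)
        rev = BandMatrix(
            "TMD", ["X1"], list(reversed(a.samples)),
            np.arange(4, dtype=np.int8).reshape(4, 1) % 2,
            np.zeros((4, 1), dtype=np.int8),
        )
        merged = merge_marker_systems(a, rev)
        j = merged.locus_ids.index("TMD:X1")
        for i, sid in enumerate(merged.sample_ids):
            k = rev.sample_ids.index(sid)
            assert merged.calls_m[i, j] == rev.calls_m[k, 0]

    def test_squared_distance_additive_over_merge(self, rng):
        """Mismatch-count distances on the merged matrix are the sum of parts."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            a = random_matrix(r, n_samples=5, n_loci=7)
            b = random_matrix(r, n_samples=5, n_loci=4, marker="TMD")
            da = pairwise_distance(a).data
            db = pairwise_distance(b).data
            dm = pairwise_distance(merge_marker_systems(a, b)).data
            np.testing.assert_allclose(dm, da + db, atol=1e-12)

    def test_merge_associative_up_to_locus_order(self, rng):
        a = random_matrix(rng, n_samples=3, n_loci=2)
        b = random_matrix(rng, n_samples=3, n_loci=2, marker="TMD")
        ab = merge_marker_systems(a, b)
        ba = merge_marker_systems(b, a)
        assert set(ab.locus_ids) == set(ba.locus_ids)
        ta, tb = ab.band_table(), ba.band_table()
        assert ta.sort_index(axis=1).equals(tb.loc[ta.index].sort_index(axis=1))
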