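import h5py
import numpy as np
import pytest

from schicab import (
    ContactMatrix,
    CompartmentProfile,
    expected_profile,
    mask_bins,
    oe_normalize,
    pseudo_bulk,
    read_cpg_track,
    read_matrix,
    write_compartments,
    write_matrix,
)
from conftest import random_symmetric_counts


class TestReadMatrix:
    def test_triplet_symmetrized(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 1 3\n1 2 2\n")
        m = read_matrix(str(p), "triplet")
        assert np.array_equal(m.values, [[0, 3, 0], [3, 0, 2], [0, 2, 0]])

    def test_triplet_mirror_duplicates_summed_once(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 1 3\n1 0 2\n1 2 1\n")
        with pytest.warns(UserWarning, match="duplicate"):
            m = read_matrix(str(p), "triplet")
        assert m.values[0, 1] == 5 and m.values[1, 0] == 5

    def test_dense_readback(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 5\n5 0\n")
        m = read_matrix(str(p), "dense")
        assert np.array_equal(m.values, [[0, 5], [5, 0]])

    def test_dense_nonsquare_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 5 1\n5 0 1\n")
        with pytest.raises(ValueError, match="square"):
            read_matrix(str(p), "dense")

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("0 1 -3\n")
        with pytest.raises(ValueError, match="negative"):
            read_matrix(str(p), "triplet")

    @pytest.mark.parametrize("fmt", ["dense", "triplet"])
    def test_round_trip(self, tmp_path, rng, fmt):
        vals = random_symmetric_counts(rng, 10)
        m = ContactMatrix(values=vals)
        p = tmp_path / "m.txt"
        write_matrix(m, str(p), fmt)
        back = read_matrix(str(p), fmt)
        assert np.array_equal(back.values, vals)

    def test_cooler_schema_round_trip(self, tmp_path, rng):
        """A minimal cooler-layout HDF5 file reads back the planted pixels."""
        vals = random_symmetric_counts(rng, 6)
        path = tmp_path / "toy.cool"
        iu = np.triu_indices(6)
        nz = vals[iu] != 0
        b1, b2, cnt = iu[0][nz], iu[1][nz], vals[iu][nz]
        order = np.lexsort((b2, b1))
        b1, b2, cnt = b1[order], b2[order], cnt[order]
        with h5py.File(path, "w") as f:
            f.attrs["bin-size"] = 100_000
            f.create_dataset("chroms/name", data=[b"chr1"])
            f.create_dataset("chroms/length", data=[600_000])
            f.create_dataset("bins/chrom", data=np.zeros(6, int))
            f.create_dataset("bins/start", data=np.arange(6) * 100_000)
            f.create_dataset("bins/end", data=(np.arange(6) + 1) * 100_000)
            f.create_dataset("pixels/bin1_id", data=b1)
            f.create_dataset("pixels/bin2_id", data=b2)
            f.create_dataset("pixels/count", data=cnt)
            off = np.searchsorted(b1, np.arange(7))
            f.create_dataset("indexes/bin1_offset", data=off)
            f.create_dataset("indexes/chrom_offset", data=[0, 6])
        m = read_matrix(str(path), "cooler", chrom="chr1", resolution=100_000)
        assert np.array_equal(m.values, vals)

    def test_cooler_missing_chrom_names_available(self, tmp_path):
        path = tmp_path / "toy.cool"
        with h5py.File(path, "w") as f:
            f.attrs["bin-size"] = 100_000
            f.create_dataset("chroms/name", data=[b"chr1"])
            f.create_dataset("indexes/chrom_offset", data=[0, 2])
            f.create_dataset("indexes/bin1_offset", data=[0, 0, 0])
            f.create_dataset("pixels/bin1_id", data=np.array([], int))
            f.create_dataset("pixels/bin2_id", data=np.array([], int))
            f.create_dataset("pixels/count", data=np.array([], int))
        with pytest.raises(ValueError, match="chr1"):
            read_matrix(str(path), "cooler", chrom="chrX", resolution=100_000)


class TestPseudoBulk:
    def test_doubling_and_identity(self, small_matrix):
        assert np.array_equal(
            pseudo_bulk([small_matrix, small_matrix]).values, 2 * small_matrix.values
        )
        assert np.array_equal(pseudo_bulk([small_matrix]).values, small_matrix.values)

    def test_total_count_conservation_and_order(self, rng):
        cells = [ContactMatrix(values=random_symmetric_counts(rng, 7)) for _ in range(4)]
        bulk = pseudo_bulk(cells)
        assert bulk.values.sum() == sum(c.values.sum() for c in cells)
        assert np.array_equal(pseudo_bulk(cells[::-1]).values, bulk.values)

    def test_empty_and_mismatch_errors(self, small_matrix, rng):
        with pytest.raises(ValueError):
            pseudo_bulk([])
        other = ContactMatrix(values=random_symmetric_counts(rng, 5))
        with pytest.raises(ValueError):
            pseudo_bulk([small_matrix, other])


class TestExpectedAndOE:
    def test_constant_matrix_bands(self):
        m = ContactMatrix(values=np.full((4, 4), 3.0))
        assert np.allclose(expected_profile(m).band_means, 3.0)

    def test_hand_computed_band_means(self):
        m = ContactMatrix(values=np.array([[0, 4, 2], [4, 0, 6], [2, 6, 0]], float))
        assert np.allclose(expected_profile(m).band_means, [0, 5, 2])

    def test_far_corner_band_single_entry(self, small_matrix):
        prof = expected_profile(small_matrix)
        assert prof.band_means[-1] == small_matrix.values[0, -1]

    def test_oe_self_consistency(self, rng):
        """Per-band means of O/E(m, expected(m)) are 1 where defined."""
        m = ContactMatrix(values=random_symmetric_counts(rng, 12))
        prof = expected_profile(m)
        oe = oe_normalize(m, prof)
        n = m.n
        for d in range(n):
            if prof.band_means[d] > 0:
                i = np.arange(n - d)
                assert abs(oe.values[i, i + d].mean() - 1.0) < 1e-9

    def test_identity_expected(self, small_matrix):
        from schicab import ExpectedProfile

        prof = ExpectedProfile(band_means=np.ones(small_matrix.n))
        oe = oe_normalize(small_matrix, prof)
        assert np.array_equal(oe.values, small_matrix.values)
        assert oe.normalized == "oe"

    def test_zero_band_maps_to_zero(self):
        m = ContactMatrix(values=np.diag([2.0, 3.0, 4.0]))
        oe = oe_normalize(m, expected_profile(m))
        assert np.all(oe.values[np.triu_indices(3, 1)] == 0)

    def test_double_normalization_rejected(self, small_matrix):
        prof = expected_profile(small_matrix)
        oe = oe_normalize(small_matrix, prof)
        with pytest.raises(ValueError, match="already"):
            oe_normalize(oe, prof)


class TestCpGTrack:
    def test_single_full_bin(self, tmp_path):
        p = tmp_path / "cpg.bedgraph"
        p.write_text("chr1\t100000\t200000\t0.7\n")
        t = read_cpg_track(str(p), "chr1", 100_000, 4)
        assert np.allclose(t.values, [0, 0.7, 0, 0])

    def test_interval_spanning_two_bins(self, tmp_path):
        p = tmp_path / "cpg.bedgraph"
        p.write_text("chr1\t50000\t150000\t0.4\n")
        t = read_cpg_track(str(p), "chr1", 100_000, 2)
        assert np.allclose(t.values, [0.4, 0.4])

    def test_weighted_mean_of_two_half_intervals(self, tmp_path):
        p = tmp_path / "cpg.bedgraph"
        p.write_text("chr1\t0\t50000\t2\nchr1\t50000\t100000\t4\n")
        t = read_cpg_track(str(p), "chr1", 100_000, 1)
        assert np.allclose(t.values, [3.0])

    def test_absent_chrom(self, tmp_path):
        p = tmp_path / "cpg.bedgraph"
        p.write_text("chr1\t0\t100000\t1\n")
        with pytest.raises(ValueError, match="chr2"):
            read_cpg_track(str(p), "chr2", 100_000, 2)


class TestMaskBins:
    def test_zero_threshold_masks_nothing(self, small_matrix):
        assert mask_bins(small_matrix, 0).mask.all()

    def test_zero_row_masked(self):
        v = np.ones((4, 4))
        v[2, :] = 0
        v[:, 2] = 0
        m = ContactMatrix(values=v)
        masked = mask_bins(m, 1)
        assert not masked.mask[2] and masked.mask[[0, 1, 3]].all()

    def test_idempotent(self, small_matrix):
        once = mask_bins(small_matrix, 1)
        twice = mask_bins(once, 1)
        assert np.array_equal(once.mask, twice.mask)

    def test_all_masked_error(self):
        m = ContactMatrix(values=np.zeros((3, 3)))
        with pytest.raises(ValueError, match="all bins"):
            mask_bins(m, 1)


class TestWriteCompartments:
    def _profile(self, ncut, labels):
        return CompartmentProfile(
            labels=np.array(labels, dtype=object),
            ncut_values=np.array(ncut, float),
            cpg_corr=0.9,
            chrom="chr1",
            resolution=100_000,
        )

    def test_bedgraph_lines(self, tmp_path):
        prof = self._profile([0.3, -0.2], ["A", "B"])
        out = tmp_path / "out"
        write_compartments([prof], str(out), "bedgraph")
        lines = (tmp_path / "out.bedgraph").read_text().splitlines()
        assert lines[0].split("\t") == ["chr1", "0", "100000", "0.3"]
        assert lines[1].split("\t") == ["chr1", "100000", "200000", "-0.2"]

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd

        profs = [
            self._profile([0.3, -0.2, 0.1], ["A", "B", "A"]),
            self._profile([0.5, 0.4, np.nan], ["A", "A", "NA"]),
        ]
        out = tmp_path / "out"
        write_compartments(profs, str(out), "tsv")
        labels = pd.read_csv(out.parent / "out.labels.tsv", sep="\t").to_numpy(float)
        expected = np.array([[1, 0, 1], [1, 1, np.nan]])
        assert np.array_equal(labels, expected, equal_nan=True)

    def test_empty_profile_list(self, tmp_path):
        with pytest.raises(ValueError):
            write_compartments([], str(tmp_path / "x"), "tsv")
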