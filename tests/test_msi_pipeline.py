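import numpy as np
import pytest

from lareims.msi_pipeline import (ImageGrid, LockMassCorrector, ScanStream,
                                  Spectrum, annotate_peaks, bin_spectrum,
                                  composite_rgb, compute_mz,
                                  default_annotation_table, extract_ion_image,
                                  lockmass_correct, read_imzml,
                                  reconstruct_image, region_correlation_map,
                                  tic_normalize, write_imzml)


class TestComputeMz:
    @pytest.mark.parametrize("formula, adduct, printed", [
        ("C5H5N5O", "[M-H]-", 150.04),      # guanine
        ("C43H78NO8P", "[M-H]-", 766.54),   # PE(38:4)
    ])
    def test_printed_two_decimal_values(self, formula, adduct, printed):
        assert round(compute_mz(formula, adduct), 2) == printed

    def test_glycine_isotope_sum(self):
        # independent hand sum: 2C + 5H + N + 2O - proton
        masses = {"H": 1.00782503207, "C": 12.0, "N": 14.0030740048,
                  "O": 15.9949146196}
        m = 2 * masses["C"] + 5 * masses["H"] + masses["N"] + 2 * masses["O"]
        expected = m - 1.00782503207 + 5.48579909065e-4
        assert compute_mz("C2H5NO2", "[M-H]-") == pytest.approx(expected,
                                                                abs=1e-9)

    def test_pyteomics_oracle_random_formulas(self):
        """In-repo isotope table vs the pyteomics mass oracle, 1e-4 Da."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        rng = np.random.default_rng(8)
        for _ in range(20):
            formula = (f"C{rng.integers(1, 60)}H{rng.integers(1, 120)}"
                       f"N{rng.integers(0, 6) + 1}O{rng.integers(0, 10) + 1}")
            ours = compute_mz(formula, "[M-H]-")
            theirs = pyteomics_mass.calculate_mass(formula=formula,
                                                   ion_type="M", charge=-1)
            assert ours == pytest.approx(theirs, abs=1e-4)

    def test_chloride_adduct(self):
        tg = compute_mz("C55H102O6", "[M+Cl]-")
        assert round(tg, 2) == 893.74   # computed value, see module notes

    def test_positive_adduct_and_errors(self):
        assert compute_mz("C5H5N5", "[M+H]+") == pytest.approx(136.0618,
                                                               abs=2e-4)
        with pytest.raises(ValueError):
            compute_mz("C5Xx2", "[M-H]-")
        with pytest.raises(ValueError):
            compute_mz("C5H5N5", "[M+Na]+")

    def test_annotation_table_recomputable(self):
        table = default_annotation_table()
        for _, row in table.iterrows():
            assert row["theoretical_mz"] == pytest.approx(
                compute_mz(row["formula"], row["adduct"]), abs=1e-12)


class TestLockMass:
    def _spectrum(self, lock_at, extra=()):
        mz = sorted([lock_at] + [m for m, _ in extra])
        inten = []
        lookup = dict(extra)
        for m in mz:
            inten.append(lookup.get(m, 1000.0))
        return Spectrum(mz=np.array(mz), intensity=np.array(inten))

    def test_exact_lock_leaves_spectrum_unchanged(self):
        s = self._spectrum(554.2615, [(766.5398, 50.0)])
        out = lockmass_correct(s)
        np.testing.assert_array_equal(out.mz, s.mz)

    def test_multiplicative_correction(self):
        s = self._spectrum(554.3000, [(766.5930, 50.0)])
        out = lockmass_correct(s)
        expected = 766.5930 * 554.2615 / 554.3000
        peak = out.mz[np.argmin(np.abs(out.mz - 766.54))]
        assert peak == pytest.approx(expected, abs=1e-9)
        assert peak == pytest.approx(766.5398, abs=1e-3)
        lock = out.mz[np.argmin(np.abs(out.mz - 554.26))]
        assert abs(lock - 554.2615) / 554.2615 < 1e-6

    def test_missing_lock_carries_last_factor(self, caplog):
        corrector = LockMassCorrector()
        with_lock = self._spectrum(554.3000)
        corrector.correct(with_lock)
        factor = corrector.last_factor
        without = Spectrum(mz=np.array([100.0, 200.0]),
                           intensity=np.array([1.0, 1.0]))
        out = corrector.correct(without)
        np.testing.assert_allclose(out.mz, np.array([100.0, 200.0]) * factor)

    def test_missing_lock_no_prior_is_identity(self, caplog):
        import logging

        without = Spectrum(mz=np.array([100.0, 200.0]),
                           intensity=np.array([1.0, 1.0]))
        with caplog.at_level(logging.WARNING, logger="lareims.msi_pipeline"):
            out = lockmass_correct(without)
        np.testing.assert_array_equal(out.mz, without.mz)
        assert any("lock" in rec.message for rec in caplog.records)

    def test_most_intense_peak_in_window_wins(self):
        s = Spectrum(mz=np.array([554.0, 554.30, 554.45]),
                     intensity=np.array([5.0, 100.0, 20.0]))
        out = lockmass_correct(s)
        assert out.mz[1] == pytest.approx(554.2615, abs=1e-9)


class TestBinning:
    def test_peaks_summed_into_bin(self):
        s = Spectrum(mz=np.array([100.04, 100.06]),
                     intensity=np.array([5.0, 7.0]))
        v = bin_spectrum(s)
        idx = int(round((100.0 - 50.0) / 0.1))
        assert v[idx] == pytest.approx(12.0)

    def test_half_open_boundary(self):
        s = Spectrum(mz=np.array([100.1]), intensity=np.array([3.0]))
        v = bin_spectrum(s)
        lower = int(round((100.0 - 50.0) / 0.1))
        assert v[lower] == 0.0
        assert v[lower + 1] == pytest.approx(3.0)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(2)
        mz = np.sort(rng.uniform(50.0, 1199.9, 500))
        mz += np.arange(500) * 1e-9     # enforce strict increase
        inten = rng.uniform(0.0, 100.0, 500)
        v = bin_spectrum(Spectrum(mz=mz, intensity=inten))
        assert v.sum() == pytest.approx(inten.sum(), rel=1e-9)

    def test_out_of_range_dropped(self):
        s = Spectrum(mz=np.array([10.0, 100.0, 1500.0]),
                     intensity=np.array([1.0, 2.0, 3.0]))
        assert bin_spectrum(s).sum() == pytest.approx(2.0)

    def test_bad_width(self):
        s = Spectrum(mz=np.array([100.0]), intensity=np.array([1.0]))
        with pytest.raises(ValueError):
            bin_spectrum(s, width=0.0)


class TestTicNormalize:
    def test_values(self):
        np.testing.assert_allclose(tic_normalize([2.0, 3.0, 5.0]),
                                   [0.2, 0.3, 0.5])

    def test_idempotent(self):
        v = tic_normalize([2.0, 3.0, 5.0])
        np.testing.assert_allclose(tic_normalize(v), v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty spectrum"):
            tic_normalize([0.0, 0.0, 0.0])


def _stream(n_rows, n_cols, marker_start=0):
    """Stream whose i-th spectrum has a unique marker peak intensity."""
    spectra = []
    for i in range(n_rows * n_cols):
        spectra.append(Spectrum(
            mz=np.array([100.05, 554.2615]),
            intensity=np.array([float(marker_start + i + 1), 50.0])))
    return ScanStream(spectra=spectra, rows=n_rows, cols=n_cols)


class TestReconstruct:
    def test_row_major_assignment(self):
        grid = reconstruct_image(_stream(2, 3), normalize=False)
        marker = extract_ion_image(grid, (100.0, 100.1))
        np.testing.assert_allclose(marker,
                                   [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])

    def test_serpentine_option(self):
        grid = reconstruct_image(_stream(2, 3), normalize=False,
                                 serpentine=True)
        marker = extract_ion_image(grid, (100.0, 100.1))
        np.testing.assert_allclose(marker,
                                   [[1.0, 2.0, 3.0], [6.0, 5.0, 4.0]])

    def test_incomplete_stream_rejected(self):
        stream = _stream(2, 3)
        stream.spectra.pop()
        with pytest.raises(ValueError, match="expected 6.*got 5"):
            reconstruct_image(stream)

    def test_field_of_view_from_raster(self):
        stream = _stream(1, 1)
        stream.rows, stream.cols, stream.pixel_size_um = 200, 200, 5.0
        # 200 x 200 at 5 um covers 1 x 1 mm^2
        assert stream.rows * stream.pixel_size_um == 1000.0
        assert stream.cols * stream.pixel_size_um == 1000.0

    def test_order_invariance_with_per_scan_lock(self):
        """With a lock peak in every scan there is no cross-scan state, so
        any processing order gives identical pixel vectors."""
        rng = np.random.default_rng(0)
        spectra = []
        for i in range(6):
            drift = 1.0 + rng.uniform(-2e-5, 2e-5)
            mz = np.array([100.05, 300.21, 554.2615]) * drift
            spectra.append(Spectrum(mz=mz,
                                    intensity=rng.uniform(1, 10, 3) + 1))
        fwd = ScanStream(spectra=list(spectra), rows=2, cols=3)
        grid_fwd = reconstruct_image(fwd)
        rev = ScanStream(spectra=list(reversed(spectra)), rows=2, cols=3)
        grid_rev = reconstruct_image(rev)
        np.testing.assert_allclose(grid_fwd.data.reshape(6, -1),
                                   grid_rev.data.reshape(6, -1)[::-1],
                                   atol=1e-15)


class TestIonImages:
    def _grid(self):
        data = np.zeros((2, 2, 10))
        data[0, 0, 3] = 1.0
        data[1, 1, 7] = 2.0
        return ImageGrid(data=data, bin_lo=100.0, bin_width=0.1)

    def test_window_extraction(self):
        img = extract_ion_image(self._grid(), (100.3, 100.4))
        np.testing.assert_allclose(img, [[1.0, 0.0], [0.0, 0.0]])

    def test_window_outside_range_is_zero(self):
        img = extract_ion_image(self._grid(), (500.0, 500.5))
        assert not img.any()

    def test_empty_window_is_zero(self):
        img = extract_ion_image(self._grid(), (100.4, 100.4))
        assert not img.any()

    def test_composite_channels_independent(self):
        r = np.array([[1.0, 2.0], [3.0, 4.0]])
        g = np.zeros((2, 2))
        b = np.array([[4.0, 3.0], [2.0, 1.0]])
        rgb = composite_rgb(r, g, b)
        assert not rgb[..., 1].any()
        perm = composite_rgb(b, g, r)
        np.testing.assert_allclose(perm[..., 0], rgb[..., 2])
        np.testing.assert_allclose(perm[..., 2], rgb[..., 0])

    def test_composite_saturates_at_its_percentile(self):
        c = np.full((10, 10), 7.0)
        rgb = composite_rgb(c, c, c)
        np.testing.assert_allclose(rgb, 1.0)

    def test_composite_shape_mismatch(self):
        with pytest.raises(ValueError):
            composite_rgb(np.zeros((2, 2)), np.zeros((2, 3)),
                          np.zeros((2, 2)))


class TestCorrelationMap:
    def test_homogeneous_reference_is_unity(self):
        data = np.tile(np.array([1.0, 2.0, 3.0, 0.0]), (3, 3, 1))
        grid = ImageGrid(data=data, bin_lo=100.0, bin_width=0.1)
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, :2] = True
        corr = region_correlation_map(grid, mask)
        np.testing.assert_allclose(corr, 1.0, atol=1e-12)
        assert corr.shape == (3, 3)

    def test_disjoint_spectrum_anticorrelates(self):
        data = np.zeros((1, 2, 4))
        data[0, 0] = [1.0, 1.0, 0.0, 0.0]
        data[0, 1] = [0.0, 0.0, 1.0, 1.0]
        grid = ImageGrid(data=data, bin_lo=100.0, bin_width=0.1)
        mask = np.array([[True, False]])
        corr = region_correlation_map(grid, mask)
        assert corr[0, 1] <= 0.0

    def test_empty_mask_rejected(self):
        grid = ImageGrid(data=np.zeros((2, 2, 3)), bin_lo=100.0,
                         bin_width=0.1)
        with pytest.raises(ValueError):
            region_correlation_map(grid, np.zeros((2, 2), dtype=bool))


class TestAnnotatePeaks:
    def test_close_match_found(self):
        out = annotate_peaks([150.0430])
        assert out["name"].iloc[0] == "guanine"
        assert abs(out["ppm"].iloc[0]) < 10.0

    def test_far_peak_unknown(self):
        out = annotate_peaks([150.100])
        assert out["name"].iloc[0] == "unknown"

    def test_nearest_ppm_wins(self):
        import pandas as pd

        table = pd.DataFrame([
            {"name": "a", "formula": "X", "adduct": "[M-H]-",
             "theoretical_mz": 500.0000},
            {"name": "b", "formula": "Y", "adduct": "[M-H]-",
             "theoretical_mz": 500.0030},
        ])
        out = annotate_peaks([500.0020], table=table, tol_ppm=10.0)
        assert out["name"].iloc[0] == "b"


class TestImzmlRoundTrip:
    def test_write_read_preserves_binned_matrices(self, tmp_path):
        rng = np.random.default_rng(5)
        data = rng.random((3, 4, 50))
        grid = ImageGrid(data=data, bin_lo=50.0, bin_width=0.1)
        path = tmp_path / "grid.imzML"
        write_imzml(grid, str(path))
        back = read_imzml(str(path))
        assert back.data.shape == grid.data.shape
        np.testing.assert_allclose(back.data, grid.data, atol=1e-9)
        assert back.bin_width == pytest.approx(0.1, rel=1e-6)


class TestPhantomIonImageRecovery:
    def test_tumor_marker_image_localizes_to_planted_region(self, phantom_truth,
                                                            phantom_grid):
        """The adenine ion image, thresholded by two-cluster log-intensity
        means, overlaps the tumor region with Dice >= 0.95."""
        grid, _info = phantom_grid
        img = extract_ion_image(grid, (134.0, 134.1))
        x = np.log(img[img > 0])
        centers = np.array([x.min(), x.max()])
        for _ in range(50):
            lab = np.abs(x[:, None] - centers).argmin(axis=1)
            centers = np.array([x[lab == 0].mean(), x[lab == 1].mean()])
        mask = img > np.exp(centers.mean())
        tumor = phantom_truth.labels == list(
            phantom_truth.class_names).index("tumor")
        dice = 2.0 * np.sum(mask & tumor) / (mask.sum() + tumor.sum())
        assert dice >= 0.95

    def test_marker_image_clean_without_noise(self):
        """Noise- and drift-free phantom: the adenine window is nonzero on
        tumor-containing pixels and carries its largest values there."""
        from lareims.synthetic_data import gen_msi_dataset, gen_phantom

        truth = gen_phantom(rows=9, cols=9, seed=3, noise_sigma=0.0,
                            drift_ppm_amplitude=0.0)
        stream, info = gen_msi_dataset(truth, noise_sigma=0.0)
        grid = reconstruct_image(stream)
        img = extract_ion_image(grid, (134.0, 134.1))
        tumor = truth.labels == list(truth.class_names).index("tumor")
        assert img[tumor].min() > img[~tumor].max()
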