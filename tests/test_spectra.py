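import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from specphot.spectra import (
    BackgroundSpectrum,
    EmissionSpectrum,
    ReferenceSet,
    SingularReferenceError,
    SpectralFrameSeries,
    WavelengthGrid,
    _generate_builtin_csv,
    builtin_reference_set,
    peak_normalize,
    read_frame_series,
    read_reference_spectra,
    resample_to_grid,
    subtract_background,
    write_frame_series,
    write_reference_spectra,
)


class TestWavelengthGrid:
    def test_rejects_non_monotone(self):
        with pytest.raises(ValueError, match="increasing"):
            WavelengthGrid([500.0, 499.0, 501.0])

    def test_rejects_single_point(self):
        with pytest.raises(ValueError, match="2 wavelengths"):
            WavelengthGrid([500.0])

    def test_non_uniform_spacing_allowed(self):
        g = WavelengthGrid([480.0, 481.0, 483.0, 490.0])
        assert len(g) == 4


class TestPeakNormalize:
    def test_divides_by_max(self, grid):
        y = np.full(len(grid), 2.0)
        y[10] = 5.0
        out = peak_normalize(EmissionSpectrum("x", grid, y))
        assert out.intensities.max() == 1.0
        assert np.allclose(out.intensities, y / 5.0)

    def test_constant_spectrum_becomes_ones(self, grid):
        out = peak_normalize(EmissionSpectrum("x", grid, np.full(len(grid), 3.0)))
        assert np.all(out.intensities == 1.0)

    def test_all_zero_rejected(self, grid):
        with pytest.raises(ValueError, match="all-zero"):
            peak_normalize(EmissionSpectrum("x", grid, np.zeros(len(grid))))

    @given(c=st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, c):
        grid = WavelengthGrid(np.linspace(480, 650, 50))
        y = np.exp(-0.5 * ((grid.wavelengths - 520) / 25) ** 2) + 0.1
        a = peak_normalize(EmissionSpectrum("x", grid, y))
        b = peak_normalize(EmissionSpectrum("x", grid, c * y))
        assert np.allclose(a.intensities, b.intensities, rtol=1e-12)


class TestResample:
    def test_identity_grid(self, grid):
        y = np.exp(-0.5 * ((grid.wavelengths - 520) / 25) ** 2)
        s = EmissionSpectrum("x", grid, y)
        out = resample_to_grid(s, grid)
        assert np.array_equal(out.intensities, y)
        assert out.fluorophore_id == "x"

    def test_midpoint_is_neighbor_mean(self):
        src = WavelengthGrid([500.0, 510.0, 520.0])
        s = EmissionSpectrum("x", src, [1.0, 3.0, 2.0])
        out = resample_to_grid(s, WavelengthGrid([505.0, 515.0]))
        assert np.allclose(out.intensities, [2.0, 2.5])

    def test_no_extrapolation(self, grid):
        s = EmissionSpectrum("x", grid, np.ones(len(grid)))
        with pytest.raises(ValueError, match="beyond"):
            resample_to_grid(s, WavelengthGrid([470.0, 500.0]))

    def test_gaussian_downsample_within_linear_interp_bound(self):
        # coarse 10-nm sampling of a Gaussian, resampled to 1 nm; linear
        # interpolation error is bounded by max|f''| h^2 / 8
        sigma, mu, h = 20.0, 550.0, 10.0
        coarse = WavelengthGrid(np.arange(480.0, 651.0, h))
        fine = WavelengthGrid(np.arange(480.0, 641.0, 1.0))
        f = lambda x: np.exp(-0.5 * ((x - mu) / sigma) ** 2)
        out = resample_to_grid(EmissionSpectrum("g", coarse, f(coarse.wavelengths)), fine)
        err = np.max(np.abs(out.intensities - f(fine.wavelengths)))
        bound = (1.0 / sigma**2) * h**2 / 8.0  # max|f''| = 1/sigma^2 at the peak
        assert err <= bound


class TestBackgroundSubtraction:
    def _series(self, grid, frames):
        n = frames.shape[0]
        return SpectralFrameSeries(
            grid=grid,
            frame_times=np.arange(n) / 25.0,
            frames=frames,
            frame_rate=25.0,
        )

    def test_zero_background_is_identity(self, grid):
        frames = np.ones((5, len(grid)))
        bg = BackgroundSpectrum(grid, np.zeros(len(grid)))
        out = subtract_background(self._series(grid, frames), bg)
        assert np.array_equal(out.frames, frames)
        assert out.background_subtracted

    def test_frames_equal_background_gives_zeros(self, grid):
        bgvals = np.linspace(1, 2, len(grid))
        frames = np.tile(bgvals, (4, 1))
        out = subtract_background(
            self._series(grid, frames), BackgroundSpectrum(grid, bgvals)
        )
        assert np.allclose(out.frames, 0.0)

    def test_linearity_of_successive_subtractions(self, grid):
        rng = np.random.default_rng(0)
        frames = rng.uniform(5, 10, (3, len(grid)))
        b1 = rng.uniform(0, 1, len(grid))
        b2 = rng.uniform(0, 1, len(grid))
        s = self._series(grid, frames)
        with pytest.warns(UserWarning, match="already subtracted"):
            twice = subtract_background(
                subtract_background(s, BackgroundSpectrum(grid, b1)),
                BackgroundSpectrum(grid, b2),
            )
        once = subtract_background(s, BackgroundSpectrum(grid, b1 + b2))
        assert np.allclose(twice.frames, once.frames)

    def test_grid_mismatch_rejected(self, grid):
        other = WavelengthGrid(np.arange(480.0, 651.0, 2.0))
        s = self._series(grid, np.ones((2, len(grid))))
        with pytest.raises(ValueError, match="grid"):
            subtract_background(s, BackgroundSpectrum(other, np.zeros(len(other))))


class TestFrameSeriesInvariants:
    def test_times_must_match_frame_rate(self, grid):
        t = np.arange(10) / 25.0
        t[5] += 0.01
        with pytest.raises(ValueError, match="frame_rate"):
            SpectralFrameSeries(grid, t, np.ones((10, len(grid))), 25.0)

    def test_negative_counts_only_after_subtraction(self, grid):
        frames = -np.ones((3, len(grid)))
        t = np.arange(3) / 25.0
        with pytest.raises(ValueError, match="negative"):
            SpectralFrameSeries(grid, t, frames, 25.0)
        s = SpectralFrameSeries(grid, t, frames, 25.0, background_subtracted=True)
        assert s.n_frames == 3


class TestReferenceIO:
    def test_disjoint_support_condition_number_one(self, two_disjoint):
        assert two_disjoint.condition_number() == pytest.approx(1.0, rel=1e-9)

    def test_identical_columns_singular(self, grid, tmp_path):
        y = np.exp(-0.5 * ((grid.wavelengths - 520) / 25) ** 2)
        import pandas as pd

        pd.DataFrame(
            {"wavelength_nm": grid.wavelengths, "a": y, "b": y}
        ).to_csv(tmp_path / "refs.csv", index=False)
        with pytest.raises(SingularReferenceError, match="singular reference set"):
            read_reference_spectra(tmp_path / "refs.csv")

    def test_all_zero_column_rejected(self, grid, tmp_path):
        import pandas as pd

        pd.DataFrame(
            {"wavelength_nm": grid.wavelengths, "a": np.ones(len(grid)),
             "b": np.zeros(len(grid))}
        ).to_csv(tmp_path / "refs.csv", index=False)
        with pytest.raises(ValueError, match="all-zero"):
            read_reference_spectra(tmp_path / "refs.csv")

    def test_packaged_condition_number_vs_svd_oracle(self, refset):
        # independent oracle: singular values via eigendecomposition of the
        # Gram matrix of the L2-column-normalized mixing matrix
        M = refset.mixing_matrix
        Mn = M / np.linalg.norm(M, axis=0)
        ev = np.linalg.eigvalsh(Mn.T @ Mn)
        oracle = np.sqrt(ev[-1] / ev[0])
        assert refset.condition_number() == pytest.approx(oracle, rel=1e-9)

    def test_reference_round_trip_exact(self, refset, tmp_path):
        path = tmp_path / "refs.csv"
        write_reference_spectra(refset, path)
        back = read_reference_spectra(path)
        assert back.fluorophores == refset.fluorophores
        assert np.array_equal(back.grid.wavelengths, refset.grid.wavelengths)
        assert np.array_equal(back.mixing_matrix, refset.mixing_matrix)

    def test_frame_series_round_trip_exact(self, fast_session, tmp_path):
        path = tmp_path / "frames.csv"
        write_frame_series(fast_session.series, path)
        back = read_frame_series(path, frame_rate=fast_session.series.frame_rate)
        assert np.array_equal(back.frames, fast_session.series.frames)
        assert np.array_equal(back.frame_times, fast_session.series.frame_times)

    def test_builtin_csv_matches_parametric_shapes(self, tmp_path):
        _generate_builtin_csv(tmp_path / "regen.csv")
        regen = read_reference_spectra(tmp_path / "regen.csv")
        packaged = builtin_reference_set()
        assert np.array_equal(regen.mixing_matrix, packaged.mixing_matrix)
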