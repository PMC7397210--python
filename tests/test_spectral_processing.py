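"""Spectral container, preprocessing operators and I/O round trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pahscreen.spectral_processing import (
    GRID_1NM,
    PreprocessChain,
    SpectraFormatError,
    Spectrum,
    average_replicates,
    moving_average,
    read_spectra,
    resample_to_1nm,
    savitzky_golay_first_derivative,
    snv,
    write_spectra,
)


def flat_spectrum(values, sample_id="S1", wavelengths=None, replicate=None):
    wl = GRID_1NM if wavelengths is None else np.asarray(wavelengths, float)
    return Spectrum(sample_id, wl, np.asarray(values, float), replicate_id=replicate)


@pytest.fixture
def random_spectrum(rng):
    values = 0.3 + 0.1 * np.sin(GRID_1NM / 200.0) + 0.01 * rng.standard_normal(GRID_1NM.size)
    return flat_spectrum(values)


class TestContainer:
    def test_rejects_non_monotone_grid(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum("S1", [400.0, 400.0, 500.0], [0.2, 0.2, 0.2])

    def test_rejects_out_of_range_reflectance(self):
        with pytest.raises(ValueError, match="0, 1.5"):
            Spectrum("S1", [400.0, 500.0], [0.2, 1.8])

    def test_reflectance_above_one_allowed(self):
        # reflectance factor can exceed 1 against the white reference
        s = Spectrum("S1", [400.0, 500.0], [1.1, 1.2])
        assert s.reflectance.max() == 1.2


class TestAverageReplicates:
    def test_identical_replicates_unchanged(self, random_spectrum):
        out = average_replicates([random_spectrum] * 5)
        np.testing.assert_allclose(out.reflectance, random_spectrum.reflectance)
        assert out.replicate_id is None

    def test_two_constant_replicates(self):
        a = flat_spectrum(np.full(GRID_1NM.size, 0.2), replicate=1)
        b = flat_spectrum(np.full(GRID_1NM.size, 0.4), replicate=2)
        np.testing.assert_allclose(average_replicates([a, b]).reflectance, 0.3)

    def test_random_replicates_match_brute_force(self, rng):
        reps = [flat_spectrum(rng.uniform(0.1, 0.9, GRID_1NM.size), replicate=i)
                for i in range(5)]
        out = average_replicates(reps)
        brute = sum(r.reflectance for r in reps) / 5.0
        np.testing.assert_allclose(out.reflectance, brute, atol=1e-12)

    def test_mismatched_grids_rejected(self):
        a = Spectrum("S1", [400.0, 500.0], [0.2, 0.3])
        b = Spectrum("S1", [400.0, 600.0], [0.2, 0.3])
        with pytest.raises(ValueError, match="grids"):
            average_replicates([a, b])


class TestResample:
    def test_identity_on_target_grid(self, random_spectrum):
        out = resample_to_1nm(random_spectrum)
        np.testing.assert_allclose(out.reflectance, random_spectrum.reflectance)

    def test_midpoint_interpolation(self):
        coarse = Spectrum("S1", [350.0, 1000.0, 1002.0, 2500.0], [0.2, 0.2, 0.4, 0.4])
        out = resample_to_1nm(coarse)
        assert out.reflectance[np.where(out.wavelengths == 1001.0)][0] == pytest.approx(0.3)

    def test_matches_piecewise_linear_oracle(self, rng):
        interior = np.sort(rng.uniform(351, 2499, 40))
        grid = np.concatenate([[350.0], interior, [2500.0]])
        values = rng.uniform(0.1, 0.9, grid.size)
        out = resample_to_1nm(Spectrum("S1", grid, values))

        def oracle(x):
            j = np.searchsorted(grid, x, side="right") - 1
            j = min(max(j, 0), grid.size - 2)
            t = (x - grid[j]) / (grid[j + 1] - grid[j])
            return values[j] * (1 - t) + values[j + 1] * t

        for x in rng.uniform(350, 2500, 50):
            idx = int(round(x - 350))
            np.testing.assert_allclose(
                out.reflectance[idx], oracle(out.wavelengths[idx]), atol=1e-10
            )

    def test_partial_grid_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            resample_to_1nm(Spectrum("S1", [400.0, 2500.0], [0.2, 0.2]))


class TestMovingAverage:
    def test_constant_unchanged(self):
        s = flat_spectrum(np.full(GRID_1NM.size, 0.42))
        np.testing.assert_allclose(moving_average(s).reflectance, 0.42)

    def test_linear_ramp_interior_unchanged(self):
        ramp = np.linspace(0.1, 0.9, GRID_1NM.size)
        out = moving_average(flat_spectrum(ramp), segment=5)
        np.testing.assert_allclose(out.reflectance[2:-2], ramp[2:-2], atol=1e-12)

    def test_unit_impulse_spread(self):
        values = np.full(201, 0.1)
        values[100] += 1.0
        out = moving_average(Spectrum("S1", np.arange(201.0), values, validate=False),
                             segment=5)
        np.testing.assert_allclose(out.reflectance[98:103], 0.1 + 0.2, atol=1e-12)
        np.testing.assert_allclose(out.reflectance[:98], 0.1, atol=1e-12)

    def test_edges_use_shrunken_windows(self, rng):
        values = rng.uniform(0.1, 0.9, 50)
        out = moving_average(Spectrum("S1", np.arange(50.0), values), segment=5)
        # brute-force window means, truncated at the boundaries
        for i in [0, 1, 2, 25, 48, 49]:
            window = values[max(i - 2, 0): min(i + 3, 50)]
            assert out.reflectance[i] == pytest.approx(window.mean(), abs=1e-12)

    def test_invalid_segment(self):
        s = flat_spectrum(np.full(GRID_1NM.size, 0.4))
        with pytest.raises(ValueError):
            moving_average(s, segment=4)
        with pytest.raises(ValueError):
            moving_average(Spectrum("S1", np.arange(5.0), np.full(5, 0.2)), segment=7)


class TestSnv:
    def test_output_standardised(self, random_spectrum):
        out = snv(random_spectrum)
        assert out.reflectance.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.reflectance.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0.1, 5.0), st.floats(-0.5, 0.5))
    def test_affine_invariance(self, a, b):
        base = 0.3 + 0.1 * np.sin(GRID_1NM / 150.0)
        s = flat_spectrum(base)
        transformed = Spectrum("S1", GRID_1NM, a * base + b, validate=False)
        np.testing.assert_allclose(
            snv(s).reflectance, snv(transformed).reflectance, atol=1e-9
        )

    def test_matches_brute_force(self, rng):
        values = rng.uniform(0.2, 0.8, 100)
        out = snv(Spectrum("S1", np.arange(100.0), values))
        mean = values.sum() / 100
        sd = (((values - mean) ** 2).sum() / 99) ** 0.5
        np.testing.assert_allclose(out.reflectance, (values - mean) / sd, atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            snv(flat_spectrum(np.full(GRID_1NM.size, 0.4)))


class TestSavitzkyGolay:
    def test_linear_slope_recovered(self):
        m = 2.5e-4
        ramp = 0.1 + m * (GRID_1NM - 350.0)
        out = savitzky_golay_first_derivative(flat_spectrum(ramp))
        np.testing.assert_allclose(out.reflectance[5:-5], m, atol=1e-12)

    def test_constant_gives_zero(self):
        out = savitzky_golay_first_derivative(flat_spectrum(np.full(GRID_1NM.size, 0.4)))
        np.testing.assert_allclose(out.reflectance, 0.0, atol=1e-12)

    def test_quadratic_matches_analytic_derivative(self):
        x = GRID_1NM - 350.0
        values = 0.2 + 1e-4 * x + 1e-7 * x**2
        out = savitzky_golay_first_derivative(flat_spectrum(values), window=11, polyorder=2)
        analytic = 1e-4 + 2e-7 * x
        np.testing.assert_allclose(out.reflectance[5:-5], analytic[5:-5], atol=1e-9)

    def test_invalid_parameters(self):
        s = flat_spectrum(np.full(GRID_1NM.size, 0.4))
        with pytest.raises(ValueError):
            savitzky_golay_first_derivative(s, window=10)
        with pytest.raises(ValueError):
            savitzky_golay_first_derivative(s, window=5, polyorder=5)


class TestChain:
    def test_parse_serialise_round_trip(self):
        chain = PreprocessChain.parse("ma:5|snv|sg:11:2")
        assert chain.serialise() == "ma:5|snv|sg:11:2"
        assert PreprocessChain.parse(chain.serialise()) == chain

    def test_defaults_filled_in(self):
        chain = PreprocessChain.parse("ma|sg")
        assert chain.steps == (("ma", (5,)), ("sg", (11, 2)))

    def test_apply_equals_manual_composition(self, random_spectrum):
        chain = PreprocessChain.parse("ma:5|snv")
        via_chain = chain.apply(random_spectrum)
        manual = snv(moving_average(random_spectrum, 5))
        np.testing.assert_allclose(via_chain.reflectance, manual.reflectance, atol=1e-12)

    def test_reparsed_chain_same_result(self, random_spectrum):
        chain = PreprocessChain.parse("ma:7|sg:11:2")
        reparsed = PreprocessChain.parse(chain.serialise())
        np.testing.assert_allclose(
            chain.apply(random_spectrum).reflectance,
            reparsed.apply(random_spectrum).reflectance,
        )

    def test_unknown_operator_rejected(self):
        with pytest.raises(ValueError, match="unknown preprocessing"):
            PreprocessChain.parse("msc")

    def test_operators_commute_with_constant_offset_interior(self):
        values = 0.3 + 0.05 * np.sin(np.arange(200) / 10.0)
        s = Spectrum("S1", np.arange(200.0), values)
        shifted = Spectrum("S1", np.arange(200.0), values + 0.1)
        # smoothing shifts by the same constant ...
        ma_a = moving_average(s, 5).reflectance
        ma_b = moving_average(shifted, 5).reflectance
        np.testing.assert_allclose(ma_b[2:-2] - ma_a[2:-2], 0.1, atol=1e-12)
        # ... while the derivative is unchanged by it
        sg_a = savitzky_golay_first_derivative(s, 11, 2).reflectance
        sg_b = savitzky_golay_first_derivative(shifted, 11, 2).reflectance
        np.testing.assert_allclose(sg_b[5:-5], sg_a[5:-5], atol=1e-12)


class TestIO:
    def test_wide_round_trip(self, tmp_path, rng):
        spectra = [
            flat_spectrum(rng.uniform(0.2, 0.8, GRID_1NM.size), sample_id=f"S{i}",
                          replicate=j)
            for i in range(2) for j in (1, 2)
        ]
        path = tmp_path / "wide.csv"
        write_spectra(spectra, path)
        back = read_spectra(path)
        assert len(back) == 4
        assert back[0].wavelengths.size == 2151
        for orig, rec in zip(spectra, back):
            assert rec.sample_id == orig.sample_id
            assert rec.replicate_id == orig.replicate_id
            np.testing.assert_allclose(rec.reflectance, orig.reflectance)

    def test_long_write_then_wide_round_trip(self, tmp_path, rng):
        wl = np.arange(350.0, 2501.0, 50.0)
        spectra = [Spectrum("S1", wl, rng.uniform(0.2, 0.8, wl.size), replicate_id=1)]
        long_path = tmp_path / "long.csv"
        write_spectra(spectra, long_path, dialect="long")
        from_long = read_spectra(long_path)
        wide_path = tmp_path / "wide.csv"
        write_spectra(from_long, wide_path, dialect="wide")
        from_wide = read_spectra(wide_path)
        np.testing.assert_allclose(
            from_wide[0].reflectance, spectra[0].reflectance, atol=1e-12
        )

    def test_malformed_header_names_column(self, tmp_path):
        (tmp_path / "bad.csv").write_text(
            "sample_id,350,351,banana\nS1,0.2,0.2,0.2\n"
        )
        with pytest.raises(SpectraFormatError, match="banana"):
            read_spectra(tmp_path / "bad.csv")

    def test_missing_value_reported(self, tmp_path):
        (tmp_path / "gap.csv").write_text(
            "sample_id,350,351,352\nS1,0.2,,0.2\n"
        )
        with pytest.raises(SpectraFormatError, match="351"):
            read_spectra(tmp_path / "gap.csv")
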