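"""Spectral pre-treatments: definitions, fit-state handling and the search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import silcal as sc
from silcal.preprocess import admissible, enumerate_pipelines, pipeline_from_tokens

spectrum_rows = hnp.arrays(
    float,
    shape=st.tuples(st.integers(1, 4), st.integers(8, 32)),
    elements=st.floats(-50, 50, allow_nan=False, width=32),
)


class TestStepDefinitions:
    def test_snv_centers_and_scales(self):
        out = pipeline_from_tokens("SNV").fit_transform([[1.0, 2.0, 3.0]])
        assert np.allclose(out, [[-1.0, 0.0, 1.0]])

    def test_msc_inverts_affine_distortion(self):
        # x = 0.5 + 2*ref corrects back to ref exactly (affine inversion)
        ref = np.linspace(0.2, 1.0, 40)
        pl = pipeline_from_tokens("MSC")
        pl.fit_transform(ref[None, :])  # reference spectrum = ref itself
        corrected = pl.transform((0.5 + 2.0 * ref)[None, :])
        assert np.allclose(corrected, ref[None, :], atol=1e-10)

    def test_msc_of_reference_is_reference(self):
        rng = np.random.default_rng(0)
        X = rng.random((6, 30))
        pl = pipeline_from_tokens("MSC")
        pl.fit_transform(X)
        ref = X.mean(axis=0)
        assert np.allclose(pl.transform(ref[None, :]), ref[None, :], atol=1e-10)

    def test_second_derivative_of_quadratic_is_two(self):
        j = np.arange(32, dtype=float)
        pl = sc.PretreatmentPipeline([("deriv2", {"window": 5, "polyorder": 2})])
        out = pl.fit_transform((j**2)[None, :])
        assert np.allclose(out, 2.0, atol=1e-8)

    def test_detrend_removes_straight_line(self):
        j = np.arange(20, dtype=float)
        out = pipeline_from_tokens("Detrend").fit_transform((3.0 + 2.0 * j)[None, :])
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_normalize_gives_unit_vector(self):
        out = pipeline_from_tokens("Norm").fit_transform([[3.0, 4.0]])
        assert np.allclose(out, [[0.6, 0.8]])

    def test_baseline_subtracts_row_minimum(self):
        out = pipeline_from_tokens("Base").fit_transform([[2.0, 5.0, 3.0]])
        assert np.allclose(out, [[0.0, 3.0, 1.0]])

    def test_snv_constant_spectrum_names_row(self):
        with pytest.raises(ValueError, match="row index 1"):
            pipeline_from_tokens("SNV").fit_transform([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])


class TestProperties:
    @settings(max_examples=40, deadline=None)
    @given(spectrum_rows)
    def test_snv_is_idempotent_and_standardizing(self, X):
        if np.any(X.std(axis=1, ddof=1) < 1e-3):
            return  # SNV is undefined for (near-)constant rows
        one = pipeline_from_tokens("SNV").fit_transform(X)
        two = pipeline_from_tokens("SNV").fit_transform(one)
        assert np.max(np.abs(two - one)) < 1e-10
        assert np.max(np.abs(one.mean(axis=1))) < 1e-10
        assert np.allclose(one.std(axis=1, ddof=1), 1.0)

    def test_mean_center_idempotent_on_calibration_data(self, rng):
        X = rng.random((10, 15))
        pl = pipeline_from_tokens("MC")
        once = pl.fit_transform(X)
        pl2 = pipeline_from_tokens("MC")
        twice = pl2.fit_transform(once)
        assert np.max(np.abs(twice - once)) < 1e-12


class TestFitStateReuse:
    def test_prediction_row_equal_to_calibration_row_transforms_identically(self, rng):
        X = rng.random((12, 20))
        pl = pipeline_from_tokens("MSC + 1Der + Auto")
        Xt = pl.fit_transform(X)
        again = pl.transform(X[3][None, :])
        assert np.allclose(again, Xt[3][None, :], atol=1e-10)

    def test_transform_before_fit_is_an_error(self):
        with pytest.raises(RuntimeError, match="fitted"):
            pipeline_from_tokens("MC").transform([[1.0, 2.0]])

    def test_new_row_at_calibration_mean_centers_to_zero(self, rng):
        X = rng.random((8, 10))
        pl = pipeline_from_tokens("MC")
        pl.fit_transform(X)
        out = pl.transform(X.mean(axis=0)[None, :])
        assert np.max(np.abs(out)) < 1e-12

    def test_channel_mismatch_rejected(self, rng):
        pl = pipeline_from_tokens("MC")
        pl.fit_transform(rng.random((5, 10)))
        with pytest.raises(ValueError):
            pl.transform(rng.random((2, 9)))


class TestGrammar:
    def test_grammar_rules(self):
        ok = [("snv",), ("deriv2", "normalize"), ("msc", "deriv1", "autoscale"),
              ("detrend", "mean_center"), ("snv", "detrend"), ("deriv2", "detrend"),
              ("smoothing", "deriv1", "autoscale")]
        bad = [("snv", "msc"), ("deriv1", "msc"), ("mean_center", "snv"),
               ("baseline", "detrend"), ("snv", "snv")]
        for names in ok:
            assert admissible(names), names
        for names in bad:
            assert not admissible(names), names

    def test_pipeline_length_capped_at_four(self):
        for p in enumerate_pipelines(max_len=4):
            assert 1 <= len(p.steps) <= 4

    def test_empty_grammar_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_pipelines(step_names=[])


class TestSearch:
    def test_winner_never_worse_than_raw_spectra(self, noiseless_dataset):
        spectra, refs = noiseless_dataset
        X, y = spectra.absorbance, refs.values_for("CP")
        best, table = sc.search_pipelines(
            X, y, wavelengths=spectra.wavelengths,
            step_names=["snv", "baseline", "smoothing"], max_len=2, seed=0,
        )
        raw = table.loc[table["pipeline"] == "(raw)", "rmsecv"].iloc[0]
        assert table["rmsecv"].iloc[0] <= raw + 1e-12

    def test_tie_breaks_toward_shorter_pipeline(self, noisy_dataset):
        # PLS centers X internally, so "MC" scores identically to raw spectra;
        # the tie must resolve to the shorter candidate (raw).
        spectra, refs = noisy_dataset
        best, table = sc.search_pipelines(
            spectra.absorbance, refs.values_for("NDF"),
            wavelengths=spectra.wavelengths, step_names=["mean_center"],
            max_len=1, seed=0,
        )
        assert np.isclose(table["rmsecv"].iloc[0], table["rmsecv"].iloc[1], atol=1e-10)
        assert best is None  # the raw (identity, 0-step) candidate wins

    def test_multiplicative_scatter_makes_scatter_correction_win(self, library):
        # strong per-sample gain and offset; among single treatments the
        # winner should be a scatter correction (MSC or SNV) most of the time
        wins = 0
        for seed in range(10):
            recipe = sc.default_recipe(
                n_samples=40, seed=100 + seed,
                gain_range=(0.3, 3.0), offset_range=(-1.0, 1.0),
                baseline_slope_range=(0.0, 0.0), noise_sd=0.005,
            )
            spectra, refs = sc.gen_spectra_dataset(library, recipe)
            best, _ = sc.search_pipelines(
                spectra.absorbance, refs.values_for("NDF"),
                wavelengths=spectra.wavelengths, max_len=1, seed=seed, nlv_max=6,
            )
            if best is not None and any(n in ("msc", "snv") for n, _ in best.steps):
                wins += 1
        assert wins >= 6
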