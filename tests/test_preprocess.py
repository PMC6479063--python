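"""Pre-processing transforms: SNV, MSC, baselines, derivatives, dispatch."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from rootnir import preprocess as pp
from rootnir.spectra import SpectraMatrix


def _sm(values, ids=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    grid = 800.0 + 3.0 * np.arange(values.shape[1])
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return SpectraMatrix(ids, grid, values)


class TestSnv:
    def test_three_point_example(self):
        out = pp.snv(_sm([[1.0, 2.0, 3.0]]))
        assert out.values[0] == pytest.approx([-1.0, 0.0, 1.0])

    @settings(derandomize=True, max_examples=30)
    @given(hnp.arrays(np.float64, 12,
                      elements=st.floats(-5, 5, allow_nan=False)),
           st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance(self, x, scale, shift):
        if np.std(x, ddof=1) < 1e-6:
            return
        a = pp.snv(_sm([x]))
        b = pp.snv(_sm([scale * x + shift]))
        assert b.values == pytest.approx(a.values, abs=1e-9)

    def test_output_standardized(self, random_spectra):
        out = pp.snv(random_spectra)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-12
        assert out.values.std(axis=1, ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_spectrum_names_sample(self):
        sm = _sm([[1, 2, 3, 4], [5, 5, 5, 5]], ids=["good", "flat"])
        with pytest.raises(ValueError, match="flat"):
            pp.snv(sm)


class TestMsc:
    def test_identity_when_all_equal_reference(self):
        row = np.sin(np.linspace(0, 3, 20)) + 2
        sm = _sm(np.tile(row, (3, 1)))
        out = pp.msc(sm)
        assert out.values == pytest.approx(sm.values, abs=1e-10)

    def test_inverts_affine_distortion(self):
        ref = np.sin(np.linspace(0, 3, 20)) + 2
        sm = _sm([ref, 2 * ref + 3])
        out = pp.msc(sm, reference=ref)
        assert out.values[1] == pytest.approx(ref, abs=1e-10)

    def test_regression_on_reference_normalized(self, random_spectra):
        out = pp.msc(random_spectra)
        ref = random_spectra.values.mean(axis=0)
        ref_c = ref - ref.mean()
        for row in out.values:
            slope = (row - row.mean()) @ ref_c / (ref_c @ ref_c)
            intercept = row.mean() - slope * ref.mean()
            assert slope == pytest.approx(1.0, abs=1e-9)
            assert intercept == pytest.approx(0.0, abs=1e-9)

    def test_set_dependent_reference_diverges(self, rng):
        # same spectrum corrected within two different sets gives different
        # results: the information comes from the set mean
        common = rng.normal(0.5, 0.1, size=12)
        set_a = _sm(np.vstack([common, rng.normal(0.5, 0.1, size=(3, 12))]))
        set_b = _sm(np.vstack([common, rng.normal(0.9, 0.2, size=(3, 12))]))
        out_a = pp.msc(set_a).values[0]
        out_b = pp.msc(set_b).values[0]
        assert not np.allclose(out_a, out_b)


@pytest.mark.parametrize("corrector", [pp.baseline_als, pp.baseline_irls])
class TestBaselines:
    def test_constant_offset_nulled(self, corrector):
        y = np.full(200, 3.7)
        assert np.abs(corrector(y)).max() < 1e-6

    def test_zero_spectrum_zero_output(self, corrector):
        assert np.abs(corrector(np.zeros(150))).max() < 1e-9

    def test_peak_preserved_on_polynomial_baseline(self, corrector):
        x = np.arange(400.0)
        peak = 1.0 * np.exp(-0.5 * ((x - 200) / 8) ** 2)
        baseline = 0.5 + 1e-3 * x + 2e-6 * (x - 150) ** 2
        corrected = corrector(peak + baseline)
        # peak height preserved within 5 %, baseline residual small off-peak
        height = corrected[200] - np.median(corrected[np.abs(x - 200) > 50])
        assert height == pytest.approx(1.0, rel=0.05)
        off_peak = corrected[np.abs(x - 200) > 80]
        assert np.abs(off_peak - np.median(off_peak)).max() < 0.05


class TestDerivative:
    def test_first_derivative_of_affine_is_constant(self):
        grid_step = 3.0
        x = np.arange(40.0)
        sm = _sm([2.0 + 0.5 * x])  # slope 0.5 per band = 0.5/3 per nm
        out = pp.derivative(sm, order=1)
        assert out.values[0] == pytest.approx(0.5 / grid_step, abs=1e-10)

    def test_second_derivative_of_affine_is_zero(self):
        sm = _sm([2.0 + 0.5 * np.arange(40.0)])
        out = pp.derivative(sm, order=2)
        assert np.abs(out.values).max() < 1e-10

    def test_linearity(self, rng):
        a = rng.normal(size=(1, 40))
        b = rng.normal(size=(1, 40))
        d = lambda v: pp.derivative(_sm(v), order=1).values
        assert d(a + b) == pytest.approx(d(a) + d(b), abs=1e-12)

    def test_window_larger_than_bands_rejected(self):
        with pytest.raises(ValueError, match="window"):
            pp.derivative(_sm([np.arange(5.0)]), order=1, window=11)


class TestDispatch:
    def test_raw_is_identity(self, random_spectra):
        out = pp.apply_preprocess(random_spectra, pp.PreprocessSpec("raw"))
        assert np.array_equal(out.values, random_spectra.values)
        assert out.meta["preprocess"]["method"] == "raw"

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pp.PreprocessSpec("fourier")

    @pytest.mark.parametrize("method", pp.METHODS)
    def test_shape_and_order_preserved(self, method, random_spectra):
        out = pp.apply_preprocess(random_spectra, pp.PreprocessSpec(method))
        assert out.values.shape == random_spectra.values.shape
        assert out.ids == random_spectra.ids

    def test_no_information_flow_between_sets(self, rng):
        # SNV processing of one set is unchanged by changes in the other set
        val = _sm(rng.normal(0.5, 0.1, size=(4, 30)))
        out1 = pp.apply_preprocess(val, pp.PreprocessSpec("snv"))
        _ = pp.apply_preprocess(_sm(rng.normal(5, 2, size=(6, 30))),
                                pp.PreprocessSpec("snv"))
        out2 = pp.apply_preprocess(val, pp.PreprocessSpec("snv"))
        assert np.array_equal(out1.values, out2.values)
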