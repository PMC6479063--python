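"""Validation engine: splits, metrics, aggregation, frequency, survey."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rootnir as rn
from rootnir import validation as val
from rootnir.spectra import SpectraMatrix


class TestSplits:
    def test_default_partition_shape(self):
        plans = val.make_splits(master_seed=1)
        assert len(plans) == 100
        for p in plans[:5]:
            assert p.cal_idx.size == 44 and p.val_idx.size == 30
            assert np.array_equal(np.sort(np.r_[p.cal_idx, p.val_idx]),
                                  np.arange(74))

    def test_deterministic(self):
        a = val.make_splits(master_seed=9)
        b = val.make_splits(master_seed=9)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.cal_idx, pb.cal_idx)

    def test_small_case_invariants(self):
        plans = val.make_splits(n=10, n_cal=6, n_val=4, repeats=3, master_seed=2)
        for p in plans:
            assert not set(p.cal_idx) & set(p.val_idx)
            assert set(p.cal_idx) | set(p.val_idx) == set(range(10))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            val.make_splits(n=74, n_cal=40, n_val=30)


class TestMetrics:
    def test_perfect_prediction(self):
        obs = np.array([10.0, 20.0, 30.0])
        rep = val.compute_metrics(obs, obs)
        assert rep.rmsep == 0 and rep.bias == 0 and rep.r2p == 1
        assert np.isinf(rep.rpd) and rep.flags

    def test_pure_offset(self):
        obs = np.array([10.0, 20.0, 30.0])
        rep = val.compute_metrics(obs, obs + 2)
        assert rep.bias == pytest.approx(2.0)
        assert rep.sep == pytest.approx(0.0)
        assert rep.rmsep == pytest.approx(2.0)
        assert rep.flags

    def test_hand_computed_oracle(self):
        rep = val.compute_metrics([10, 20, 30], [12, 18, 33])
        assert rep.bias == pytest.approx(1.0)
        assert rep.rmsep == pytest.approx(2.3804761428476167)
        assert rep.sep == pytest.approx(2.6457513110645907)
        assert rep.r2p == pytest.approx(0.9423076923076921)
        assert rep.rpd == pytest.approx(3.779644730092272)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 10_000))
    def test_identities_on_random_vectors(self, seed):
        g = np.random.default_rng(seed)
        n = int(g.integers(3, 40))
        obs = g.normal(20, 7, n)
        pred = obs + g.normal(0, 3, n)
        rep = val.compute_metrics(obs, pred)
        assert rep.rmsep**2 == pytest.approx(
            rep.sep**2 * (n - 1) / n + rep.bias**2, abs=1e-9)
        assert rep.rpd * rep.sep == pytest.approx(np.std(obs, ddof=1), abs=1e-9)

    def test_zero_variance_flagged(self):
        rep = val.compute_metrics([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])
        assert np.isnan(rep.rpd) and rep.flags


class TestAggregate:
    def _rep(self, rpd):
        return val.MetricsReport(nlv=3, rmse_cal=1.0, rmsep=2.0, sep=2.0,
                                 bias=0.0, r2p=0.9, rpd=rpd, n_val=30)

    def test_identical_reports_zero_sd(self):
        agg = val.aggregate_reports([self._rep(2.0)] * 5)
        assert agg.loc["RPD", "sd"] == 0.0

    def test_mean_and_sample_sd(self):
        agg = val.aggregate_reports([self._rep(2.0), self._rep(3.0)])
        assert agg.loc["RPD", "mean"] == pytest.approx(2.5)
        assert agg.loc["RPD", "sd"] == pytest.approx(np.sqrt(0.5))

    def test_formatted_layout(self):
        agg = val.aggregate_reports([self._rep(2.0), self._rep(3.0)])
        assert agg.loc["RPD", "formatted"] == "2.50 ± 0.71"
        assert set(agg.index) >= {"nLV", "RPD", "R2p", "RMSEP", "SEP", "BIAS"}


class TestSelectionFrequency:
    def test_always_and_never_selected(self):
        freq = val.selection_frequency([np.array([0, 2])] * 4, 4)
        assert freq.tolist() == [100.0, 0.0, 100.0, 0.0]

    def test_partial(self):
        freq = val.selection_frequency([np.array([0]), np.array([0, 1])], 3)
        assert freq.tolist() == [100.0, 50.0, 0.0]


class TestEvaluateSplit:
    def test_perfect_limit_noise_free_one_component(self, rng):
        grid = np.linspace(800, 2500, 30)
        t = rng.normal(size=40)
        profile = np.exp(-0.5 * ((grid - 1600) / 100) ** 2)
        values = 0.5 + np.outer(t, profile)
        sm = SpectraMatrix([f"s{i}" for i in range(40)], grid, values)
        ref = pd.DataFrame({"sample_id": sm.ids, "lignin_pct": 20 + 5 * t})
        split = val.make_splits(n=40, n_cal=24, n_val=16, repeats=1,
                                master_seed=3)[0]
        rep, _ = val.evaluate_split(sm, ref, split, rn.PreprocessSpec("raw"))
        assert rep.rmsep < 1e-8
        assert rep.r2p == pytest.approx(1.0)

    def test_no_leakage_perturbing_validation_sample(self, small_dataset):
        _, _, sm, ref = small_dataset
        split = val.make_splits(master_seed=5, repeats=1)[0]
        rep1, _ = val.evaluate_split(sm, ref, split, rn.PreprocessSpec("snv"))
        sm2 = sm.copy()
        victim = split.val_idx[0]
        sm2.values[victim] += 0.05
        rep2, _ = val.evaluate_split(sm2, ref, split, rn.PreprocessSpec("snv"))
        # calibration untouched -> same model; only metrics (through the one
        # perturbed prediction) may move
        assert rep1.nlv == rep2.nlv
        assert rep1.rmse_cal == pytest.approx(rep2.rmse_cal, abs=1e-12)

    def test_perturbing_calibration_changes_model_not_val_processing(
            self, small_dataset):
        _, _, sm, ref = small_dataset
        split = val.make_splits(master_seed=5, repeats=1)[0]
        sm2 = sm.copy()
        sm2.values[split.cal_idx[0], 100] += 0.05  # single-band bump
        rep1, _ = val.evaluate_split(sm, ref, split, rn.PreprocessSpec("snv"))
        rep2, _ = val.evaluate_split(sm2, ref, split, rn.PreprocessSpec("snv"))
        assert rep1.rmse_cal != rep2.rmse_cal


class TestSurvey:
    def test_odd_length_median(self):
        df = pd.DataFrame({"RPD": [1.0, 2.0, 3.0]})
        out = val.summarize_survey(df)
        assert out.loc["RPD", "median"] == 2.0
        assert out.loc["RPD", "n"] == 3

    def test_single_value_column(self):
        df = pd.DataFrame({"SEP": [0.9]})
        out = val.summarize_survey(df)
        assert out.loc["SEP", "min"] == out.loc["SEP", "median"] \
            == out.loc["SEP", "max"] == 0.9

    def test_missing_cells_ignored_per_column(self):
        df = pd.DataFrame({"RPD": [1.0, np.nan, 3.0], "R2p": [0.5, 0.7, np.nan]})
        out = val.summarize_survey(df)
        assert out.loc["RPD", "n"] == 2
        assert out.loc["RPD", "median"] == 2.0
        assert out.loc["R2p", "median"] == pytest.approx(0.6)

    def test_empty_column_omitted_with_note(self):
        df = pd.DataFrame({"RPD": [1.0, 2.0], "SEP": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="SEP"):
            out = val.summarize_survey(df)
        assert "SEP" not in out.index

    def test_quartiles_linear_interpolation(self):
        df = pd.DataFrame({"RPD": [1.0, 2.0, 3.0, 4.0]})
        out = val.summarize_survey(df)
        assert out.loc["RPD", "Q25"] == pytest.approx(1.75)
        assert out.loc["RPD", "Q75"] == pytest.approx(3.25)
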