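"""Splits, target scaling, accuracy metrics, ranking, indicator structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hsitex import (
    EvaluationReport,
    GeneratorConfig,
    SplitSpec,
    TextureTable,
    generate_dataset,
    indicator_pca,
    indicator_spearman,
    r_coefficient,
    rank_models,
    rmsec,
    rmsep,
    split_dataset,
    standardize_targets,
)
from hsitex.errors import DegenerateTargetError, ParameterError
from hsitex.io import INDICATORS


class TestSplit:
    def test_sizes_disjoint_covering(self):
        cal, prd = split_dataset(10, SplitSpec(0.7, seed=3))
        assert len(cal) == 7 and len(prd) == 3
        assert set(cal.tolist()).isdisjoint(prd.tolist())
        assert sorted(cal.tolist() + prd.tolist()) == list(range(10))

    def test_same_seed_identical(self):
        a = split_dataset(50, SplitSpec(seed=9))
        b = split_dataset(50, SplitSpec(seed=9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_kennard_stone_takes_extremes_first(self):
        # three collinear points: the two ends are mutually farthest
        X = np.array([[0.0], [1.0], [10.0]])
        cal, prd = split_dataset(4, SplitSpec(0.5, strategy="kennard_stone"),
                                 X=np.vstack([X, [[5.0]]]))
        assert {0, 2} <= set(cal.tolist())

    def test_empty_set_fraction_rejected(self):
        with pytest.raises(ParameterError):
            split_dataset(4, SplitSpec(0.01))


class TestStandardizeTargets:
    def test_basic_z_score(self):
        scaler, z = standardize_targets(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(z, [-np.sqrt(1.5), 0, np.sqrt(1.5)])
        scaler1, z1 = standardize_targets(np.array([1.0, 2.0, 3.0]), ddof=1)
        np.testing.assert_allclose(z1, [-1.0, 0.0, 1.0])

    def test_round_trip(self, rng):
        y = rng.uniform(10, 20, size=30)
        scaler, z = standardize_targets(y)
        np.testing.assert_allclose(scaler.inverse(z), y, rtol=1e-12)

    def test_prediction_set_uses_calibration_scaler(self, rng):
        y_cal = rng.normal(100, 10, size=50)
        y_prd = rng.normal(130, 10, size=20)
        scaler, _ = standardize_targets(y_cal)
        z = scaler.transform(y_prd)
        # a shifted prediction set keeps its shift - no refitting on it
        assert z.mean() > 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateTargetError):
            standardize_targets(np.ones(10))


class TestMetricFormulas:
    def test_rmsec_frozen_values(self):
        y = np.zeros(5)
        assert rmsec(y, y, R=1) == 0.0
        ones = np.ones(5)
        assert rmsec(ones, ones - 1.0, R=1) == pytest.approx(np.sqrt(5 / 3), rel=1e-12)
        assert rmsec(ones, ones - 1.0, R=3) == pytest.approx(np.sqrt(5.0), rel=1e-12)

    def test_rmsec_undefined_denominator(self):
        with pytest.raises(ParameterError):
            rmsec(np.ones(4), np.zeros(4), R=3)

    def test_rmsep_frozen_values(self):
        assert rmsep(np.zeros(7), np.zeros(7)) == 0.0
        assert rmsep(np.ones(4), np.zeros(4)) == 1.0
        assert rmsep(np.array([3.0, 4.0]), np.zeros(2)) == pytest.approx(
            np.sqrt(12.5), rel=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(c=st.floats(-50.0, 50.0))
    def test_rmsep_constant_shift(self, c):
        y = np.arange(6, dtype=float)
        assert rmsep(y, y + c) == pytest.approx(abs(c), abs=1e-9)

    def test_r_is_one_for_affine_predictions(self, rng):
        y = rng.uniform(size=20)
        assert r_coefficient(y, 3.0 * y - 7.0) == pytest.approx(1.0, abs=1e-12)
        assert r_coefficient(y, y) == pytest.approx(1.0, abs=1e-12)

    def test_r_degenerate_constant_prediction(self, rng):
        y = rng.uniform(size=10)
        with pytest.raises(DegenerateTargetError):
            r_coefficient(y, np.full(10, y.mean()))

    def test_printed_mode_goes_to_zero_for_perfect_fit(self, rng):
        """The residual-ratio form behaves inversely to the default mode."""
        y = rng.uniform(size=15)
        near = y + 1e-6 * rng.standard_normal(15)
        assert r_coefficient(y, near, mode="printed") < 1e-9
        assert r_coefficient(y, near) > 0.999


class TestRankModels:
    def _rep(self, model, r_p, rmsep_val=0.1):
        return EvaluationReport("dorsal", "hardness", model, 0.9, r_p,
                                0.1, rmsep_val, 75, 25, 600)

    def test_highest_rp_retained(self):
        best = rank_models([self._rep("plsr", 0.90), self._rep("lssvm", 0.95),
                            self._rep("bpann", 0.93)])
        assert best[("dorsal", "hardness")].model_kind == "lssvm"

    def test_tie_breaks_to_lower_rmsep_then_name(self):
        best = rank_models([self._rep("plsr", 0.9, 0.3), self._rep("lssvm", 0.9, 0.2)])
        assert best[("dorsal", "hardness")].model_kind == "lssvm"
        best = rank_models([self._rep("plsr", 0.9, 0.2), self._rep("lssvm", 0.9, 0.2)])
        assert best[("dorsal", "hardness")].model_kind == "lssvm"  # alphabetical

    def test_order_invariance(self):
        reps = [self._rep("plsr", 0.91), self._rep("lssvm", 0.94),
                self._rep("bpann", 0.92)]
        a = rank_models(reps)
        b = rank_models(list(reversed(reps)))
        assert a[("dorsal", "hardness")].model_kind == b[("dorsal", "hardness")].model_kind

    def test_single_report_is_itself(self):
        rep = self._rep("plsr", 0.5)
        assert rank_models([rep])[("dorsal", "hardness")] is rep


def _table_from_matrix(M):
    rows = []
    for i, row in enumerate(M):
        d = {"sample_id": f"s{i:03d}", "region": "dorsal"}
        d.update({ind: float(v) for ind, v in zip(INDICATORS, row)})
        rows.append(d)
    return TextureTable(pd.DataFrame(rows))


class TestIndicatorPCA:
    def test_collinear_data_has_pc1_fraction_one(self, rng):
        t = rng.uniform(size=30)
        M = np.outer(t, np.arange(1, 9, dtype=float))
        frac, _ = indicator_pca(_table_from_matrix(M), "dorsal")
        assert frac[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_fractions_near_uniform(self, rng):
        M = rng.standard_normal((4000, 8))
        frac, _ = indicator_pca(_table_from_matrix(M), "dorsal")
        np.testing.assert_allclose(frac, np.full(8, 1 / 8), atol=0.03)

    def test_fractions_sum_to_one(self, rng):
        M = rng.standard_normal((50, 8))
        frac, _ = indicator_pca(_table_from_matrix(M), "dorsal")
        assert frac.sum() == pytest.approx(1.0, rel=1e-9)

    def test_two_cluster_data_scores_bimodal_along_pc1(self):
        cfg = GeneratorConfig(n_samples=300, n_bands=40, regions=("dorsal",),
                              two_cluster=True, noise_sd_texture=0.05, seed=21)
        _, table, _ = generate_dataset(cfg)
        frac, scores = indicator_pca(table, "dorsal")
        pc1 = scores[:, 0]
        lo, hi = pc1[pc1 < np.median(pc1)], pc1[pc1 >= np.median(pc1)]
        # between-cluster separation dwarfs within-cluster spread
        assert abs(hi.mean() - lo.mean()) > 1.5 * (lo.std() + hi.std()) / 2


class TestIndicatorSpearman:
    def test_duplicated_indicator_has_rho_one(self, rng):
        M = rng.standard_normal((40, 8))
        M[:, 1] = M[:, 0]
        rho, _, _ = indicator_spearman(_table_from_matrix(M), "dorsal")
        assert rho[0, 1] == pytest.approx(1.0)

    def test_monotone_decreasing_pair_has_rho_minus_one(self, rng):
        M = rng.standard_normal((40, 8))
        M[:, 2] = -np.exp(M[:, 0])  # monotone decreasing transform
        rho, _, _ = indicator_spearman(_table_from_matrix(M), "dorsal")
        assert rho[0, 2] == pytest.approx(-1.0)

    def test_matrix_is_symmetric_unit_diagonal(self, rng):
        M = rng.standard_normal((60, 8))
        rho, p, flags = indicator_spearman(_table_from_matrix(M), "dorsal")
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)
        assert not flags.diagonal().any()

    def test_independent_noise_significance_near_nominal(self, rng):
        """False-positive rate of the alpha=0.05 flags stays near nominal
        under independence (checked over many draws)."""
        rates = []
        for _ in range(25):
            M = rng.standard_normal((100, 8))
            _, _, flags = indicator_spearman(_table_from_matrix(M), "dorsal")
            rates.append(flags[np.triu_indices(8, 1)].mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.03)

    def test_generated_texture_has_designed_correlations(self):
        cfg = GeneratorConfig(n_samples=300, n_bands=30, regions=("gluteal",),
                              noise_sd_texture=0.05, seed=2)
        _, table, _ = generate_dataset(cfg)
        rho, _, _ = indicator_spearman(table, "gluteal")
        i = {n: k for k, n in enumerate(INDICATORS)}
        assert rho[i["resilience"], i["springiness"]] > 0.5
        assert rho[i["cohesiveness"], i["chewiness"]] > 0.3
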