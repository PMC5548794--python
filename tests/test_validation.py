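"""Node residuals, LOOCV closure and paired model comparison."""

import math

import numpy as np
import pytest
from scipy import stats

from cochleashape import (
    BaseParameters,
    CochleaRecord,
    HeightProfile,
    PopulationTable,
    PredictedCochlea,
    RadiusProfile,
    UnderdeterminedError,
    ValidationError,
    compare_models,
    default_config,
    generate,
    loocv,
    loocv_summary,
    node_residuals,
)
from cochleashape.fitting import HeightPolyCoefficients, PolySpiralCoefficients
from cochleashape.validation import NodeResiduals
from conftest import make_record


def perfect_prediction(record):
    """Prediction matching a linear-radius, linear-height record exactly."""
    return PredictedCochlea(
        base=record.base,
        radius_coeffs=PolySpiralCoefficients(5.0, -0.25, 0.0, 0.0),
        height_coeffs=HeightPolyCoefficients(0.0, 0.15, 0.0, 0.0, 0.0),
        angular_length=record.angular_length,
    )


class TestNodeResiduals:
    def test_exact_prediction_gives_zero_residuals(self):
        rec = make_record()
        res = node_residuals(rec, perfect_prediction(rec))
        np.testing.assert_allclose(res.radius_residuals, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.height_residuals, 0.0, atol=1e-12)
        assert res.angular_length_residual == 0.0

    def test_nodes_match_angular_length(self):
        rec = make_record(angular_length=930.0)
        res = node_residuals(rec, perfect_prediction(rec))
        assert res.node_angles_deg.tolist() == [0, 90, 180, 270, 360, 450, 540, 630, 720, 810, 900]

    def test_absent_measurement_propagates(self):
        rec = make_record(angular_length=1000.0)
        r = rec.radius.r.copy()
        r[-1] = np.nan  # 990 degrees missing
        rec = CochleaRecord(
            id=rec.id, side=rec.side, base=rec.base,
            radius=RadiusProfile(alpha=rec.radius.alpha, r=r),
            height=rec.height, angular_length=1000.0,
        )
        res = node_residuals(rec, perfect_prediction(rec))
        assert np.isnan(res.radius_residuals[-1])  # absent, not zero
        assert np.isfinite(res.radius_residuals[:-1]).all()

    def test_hand_computed_toy_record(self):
        """3-node toy: residuals equal hand arithmetic, measured - predicted."""
        alpha = np.radians([0.0, 90.0, 180.0, 270.0, 360.0, 450.0])
        rec = CochleaRecord(
            id="toy", side="left", base=BaseParameters(A_a=5, A_b=4, B_a=3, B_b=3),
            radius=RadiusProfile(alpha=alpha, r=np.array([5.0, 4.0, 3.5, 3.0, 2.5, 2.0])),
            height=HeightProfile(alpha=alpha, h=np.array([0.0, 0.1, 0.2, 0.1, 0.4, 0.6])),
            angular_length=450.0,
        )
        pred = PredictedCochlea(
            base=rec.base,
            radius_coeffs=PolySpiralCoefficients(4.5, 0.0, 0.0, 0.0),
            height_coeffs=HeightPolyCoefficients(0.2, 0.0, 0.0, 0.0, 0.0),
            angular_length=468.0,  # 1.3 turns
        )
        res = node_residuals(rec, pred)
        np.testing.assert_allclose(res.radius_residuals, [0.5, -0.5, -1.0, -1.5, -2.0, -2.5])
        np.testing.assert_allclose(
            res.height_residuals, [-0.2, -0.1, 0.0, -0.1, 0.2, 0.4], atol=1e-12
        )
        assert res.angular_length_residual == pytest.approx(450 / 360 - 1.3)
        assert res.ssr("radius") == pytest.approx(0.25 + 0.25 + 1 + 2.25 + 4 + 6.25)

    def test_interpolation_between_samples(self):
        """Node values interpolate linearly when samples miss the nodes."""
        alpha = np.radians([0.0, 60.0, 120.0, 180.0, 300.0, 420.0])
        rec = CochleaRecord(
            id="i", side="left", base=BaseParameters(A_a=5, A_b=4, B_a=3, B_b=3),
            radius=RadiusProfile(alpha=alpha, r=np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])),
            height=HeightProfile(alpha=alpha, h=np.zeros(6)),
            angular_length=430.0,
        )
        pred = PredictedCochlea(
            base=rec.base,
            radius_coeffs=PolySpiralCoefficients(0.0, 0.0, 0.0, 0.0),
            height_coeffs=HeightPolyCoefficients(0, 0, 0, 0, 0),
            angular_length=430.0,
        )
        res = node_residuals(rec, pred)
        # measured at 90 deg interpolates between 60 and 120: 4.5
        assert res.radius_residuals[1] == pytest.approx(4.5)

    def test_no_overlap_errors(self):
        rec = make_record()
        empty = CochleaRecord(
            id="e", side="left", base=rec.base,
            radius=RadiusProfile(alpha=rec.radius.alpha, r=np.full(len(rec.radius), np.nan)),
            height=HeightProfile(alpha=rec.height.alpha, h=np.full(len(rec.height), np.nan)),
            angular_length=rec.angular_length,
        )
        with pytest.raises(ValidationError, match="node"):
            node_residuals(empty, perfect_prediction(rec))


class TestLoocv:
    def test_noiseless_closure(self, noiseless_population):
        """Self-consistent linear truth: all LOOCV residuals vanish."""
        res = loocv(noiseless_population.table, "polynomial")
        for r in res:
            np.testing.assert_allclose(
                r.radius_residuals[np.isfinite(r.radius_residuals)], 0.0, atol=1e-6
            )
            assert abs(r.angular_length_residual) < 1e-9
        summ = loocv_summary(res)
        assert summ["mse_radius_mm2"] < 1e-13
        assert summ["mse_angular_length_turns2"] < 1e-19

    def test_too_few_records(self):
        recs = [make_record(f"r{i}") for i in range(5)]
        with pytest.raises(UnderdeterminedError):
            loocv(PopulationTable(recs), "polynomial")

    def test_duplicate_specimens_predicted_identically(self):
        cfg = default_config(n=10, seed=3, radius_noise_sd=0.05)
        pop = generate(cfg)
        recs = list(pop.table)
        dup = CochleaRecord(
            id="dup", side=recs[0].side, base=recs[0].base, radius=recs[0].radius,
            height=recs[0].height, angular_length=recs[0].angular_length,
            metric_length_measured=recs[0].metric_length_measured,
        )
        res = loocv(PopulationTable(recs + [dup]), "polynomial")
        by_id = {r.specimen_id: r for r in res}
        np.testing.assert_allclose(
            by_id[recs[0].id].radius_residuals, by_id["dup"].radius_residuals, atol=1e-9
        )

    def test_noise_floor_calibration(self):
        """Radius noise SD 0.1 mm at n=60: LOOCV radius MSE ~ sigma^2 plus
        prediction variance."""
        cfg = default_config(n=60, seed=2024, radius_noise_sd=0.1, height_noise_sd=0.1)
        pop = generate(cfg)
        res = loocv(pop.table, "polynomial")
        mse = loocv_summary(res)["mse_radius_mm2"]
        assert 0.005 <= mse <= 0.02


class TestCompareModels:
    @staticmethod
    def _residuals_from_ssr(values, ids=None):
        out = []
        for i, v in enumerate(values):
            rid = (ids or [f"s{k}" for k in range(len(values))])[i]
            out.append(
                NodeResiduals(
                    specimen_id=rid,
                    node_angles_deg=np.array([0.0]),
                    radius_residuals=np.array([math.sqrt(v)]),
                    height_residuals=np.array([np.nan]),
                    angular_length_residual=0.0,
                    metric_length_residual=math.nan,
                )
            )
        return out

    def test_identical_sets(self):
        a = self._residuals_from_ssr([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = compare_models(a, a)
        assert rep.mean_difference == 0.0
        assert rep.ssr_ratio == pytest.approx(1.0)

    def test_hand_computed_paired_t(self):
        """Textbook paired t on two 5-specimen SSR vectors."""
        ssr_a = [1.0, 2.0, 1.5, 3.0, 2.5]
        ssr_b = [2.0, 2.6, 2.1, 4.4, 3.0]
        rep = compare_models(self._residuals_from_ssr(ssr_a), self._residuals_from_ssr(ssr_b))
        d = np.array(ssr_b) - np.array(ssr_a)
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(5))
        assert rep.t_statistic == pytest.approx(t_hand, rel=1e-12)
        assert rep.mean_difference == pytest.approx(d.mean())
        half = stats.t.ppf(0.975, 4) * d.std(ddof=1) / math.sqrt(5)
        assert rep.ci_low == pytest.approx(d.mean() - half)
        assert rep.ci_high == pytest.approx(d.mean() + half)
        assert rep.ssr_ratio == pytest.approx(np.mean(ssr_b) / np.mean(ssr_a))

    def test_id_mismatch_lists_symmetric_difference(self):
        a = self._residuals_from_ssr([1.0, 2.0], ids=["x", "y"])
        b = self._residuals_from_ssr([1.0, 2.0], ids=["x", "z"])
        with pytest.raises(ValidationError, match="'y'.*'z'|'z'.*'y'"):
            compare_models(a, b)

    def test_polynomial_beats_logarithmic_on_cubic_law(self):
        """Cubic-law population: log-spiral LOOCV SSRs larger, p < 0.05."""
        cfg = default_config(n=50, seed=17)
        pop = generate(cfg)
        res_pol = loocv(pop.table, "polynomial")
        res_log = loocv(pop.table, "logarithmic")
        rep = compare_models(res_pol, res_log)
        assert rep.ssr_ratio > 1.0
        assert rep.mean_difference > 0.0
        assert rep.t_pvalue < 0.05
        assert rep.wilcoxon_pvalue < 0.05

    def test_t_and_wilcoxon_agree_in_sign(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            base = rng.uniform(1, 3, 12)
            shift = rng.uniform(1.0, 2.0)  # large standardized effect
            a = self._residuals_from_ssr(base)
            b = self._residuals_from_ssr(base + shift + rng.normal(0, 0.3, 12))
            rep = compare_models(a, b)
            assert np.sign(rep.t_statistic) == np.sign(rep.mean_difference)
            assert rep.t_pvalue < 0.05 and rep.wilcoxon_pvalue < 0.05

    def test_ssr_bookkeeping_against_exported_tables(self, noisy_population):
        """SSR recomputed from exported per-node dicts matches ssr()."""
        res = loocv(noisy_population.table, "polynomial")
        for r in res[:5]:
            doc = r.to_dict()
            manual = sum(v * v for v in doc["radius_residuals_mm"] if v is not None)
            assert r.ssr("radius") == pytest.approx(manual, rel=1e-12)
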