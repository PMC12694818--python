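import warnings

import numpy as np
import pandas as pd
import pytest

from mitoshift import (
    OocyteRecord,
    PedigreeSimConfig,
    TransmissionPair,
    age_effect,
    copy_dynamics_summary,
    fit_transmission_regression,
    litter_size_association,
    mean_shift_test,
    simulate_pedigree,
    stage_shift_summary,
    tissue_cv,
)
from mitoshift.errors import DegenerateInputError, InsufficientDataError
from mitoshift.transmission import holm_adjust


def _pairs(h0, h, **kw):
    return [TransmissionPair(f"m{i}", f"p{i}", "F2", a, b, **kw)
            for i, (a, b) in enumerate(zip(h0, h))]


class TestRegression:
    def test_unbiased_identity(self):
        h0 = np.linspace(0.1, 0.5, 20)
        fit = fit_transmission_regression(_pairs(h0, h0))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_through_origin_drops_intercept(self):
        h0 = np.linspace(0.1, 0.5, 20)
        fit = fit_transmission_regression(_pairs(h0, 0.7 * h0),
                                          through_origin=True)
        assert fit.through_origin
        assert fit.intercept is None
        assert fit.slope == pytest.approx(0.7)

    def test_singular_design(self):
        with pytest.raises(DegenerateInputError):
            fit_transmission_regression(_pairs([0.3] * 5, [0.2] * 5))

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            fit_transmission_regression(_pairs([0.1, 0.2], [0.1, 0.2]))

    def test_known_slope_recovery(self):
        # parameter recovery on a noisy known-slope design
        hits = 0
        for r in range(40):
            g = np.random.default_rng(r)
            x = g.uniform(0.05, 0.5, 500)
            y = np.clip(0.8 * x + g.normal(0, 0.05, 500), 0, 1)
            fit = fit_transmission_regression(_pairs(x, y))
            lo, hi = fit.slope_ci95()
            hits += lo <= 0.8 <= hi
        assert hits >= 34  # ~90% coverage

    def test_neutral_pedigree_slope_covers_one(self):
        hits = 0
        for r in range(40):
            pairs = simulate_pedigree(PedigreeSimConfig(
                n_mothers=20, pups_per_mother=10, seed=700 + r))
            lo, hi = fit_transmission_regression(pairs).slope_ci95()
            hits += lo <= 1.0 <= hi
        assert hits >= 34


class TestMeanShiftTest:
    def test_zero_variance_case(self):
        h0 = np.linspace(0.1, 0.5, 10)
        res = mean_shift_test(_pairs(h0, h0))
        assert res.mean_log_shift == 0.0
        assert res.test_used == "zero-variance"
        assert res.p_value == 1.0

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            mean_shift_test(_pairs([0.3], [0.2]))

    def test_selection_detected(self):
        hits = neg = 0
        for r in range(30):
            pairs = simulate_pedigree(PedigreeSimConfig(
                n_mothers=20, pups_per_mother=10, selection_s=-0.05,
                seed=800 + r))
            res = mean_shift_test(pairs)
            hits += res.p_value <= 0.05
            neg += res.mean_log_shift < 0
        assert hits >= 27
        assert neg >= 27

    def test_neutral_type_one_error(self):
        rej = 0
        runs = 60
        for r in range(runs):
            pairs = simulate_pedigree(PedigreeSimConfig(
                n_mothers=20, pups_per_mother=10, seed=900 + r))
            rej += mean_shift_test(pairs).p_value <= 0.05
        assert 0 <= rej / runs <= 0.12  # nominal [0.01, 0.10] plus MC slack

    def test_reports_gate_choice(self, neutral_pairs):
        res = mean_shift_test(neutral_pairs)
        assert res.test_used in ("t-test", "wilcoxon")


def _oocytes(stage_values: dict[str, list[float]], mother_h=0.3):
    recs = []
    for stage, hs in stage_values.items():
        for i, h in enumerate(hs):
            recs.append(OocyteRecord(mouse_id=f"{stage}{i}", mother_h=mother_h,
                                     h=h, stage=stage))
    return recs


class TestStageShiftSummary:
    def test_identity_records(self):
        recs = _oocytes({"primary": [0.3] * 8, "early_secondary": [0.3] * 8})
        out = stage_shift_summary(recs)
        assert [s.stage for s in out] == ["primary", "early_secondary"]
        for s in out:
            assert s.mean_ratio == pytest.approx(1.0)
        key = "primary-vs-early_secondary"
        assert out[0].pairwise_p[key]["raw"] == pytest.approx(1.0)

    def test_order_and_duplication_invariance(self):
        g = np.random.default_rng(0)
        recs = _oocytes({"primary": list(g.uniform(0.2, 0.4, 12)),
                         "antral": list(g.uniform(0.1, 0.3, 12))})
        base = stage_shift_summary(recs, seed=1)
        shuffled = stage_shift_summary(recs[::-1], seed=1)
        doubled = stage_shift_summary(recs + recs, seed=1)
        for a, b, c in zip(base, shuffled, doubled):
            assert a.mean_ratio == pytest.approx(b.mean_ratio)
            assert a.mean_ratio == pytest.approx(c.mean_ratio)
            # duplicating the data shrinks the bootstrap CI
            assert (c.ci95[1] - c.ci95[0]) <= (a.ci95[1] - a.ci95[0]) + 1e-9

    def test_ci_contains_mean(self):
        g = np.random.default_rng(3)
        recs = _oocytes({"late_secondary": list(g.uniform(0.1, 0.5, 20))})
        s = stage_shift_summary(recs)[0]
        assert s.ci95[0] <= s.mean_ratio <= s.ci95[1]

    def test_pairs_enter_as_offspring(self):
        recs = _oocytes({"primary": [0.25] * 5})
        pairs = [TransmissionPair("m", f"p{i}", "F2", 0.3, 0.2)
                 for i in range(5)]
        out = stage_shift_summary(recs + pairs)
        assert [s.stage for s in out] == ["primary", "offspring"]

    def test_boundary_mother_skipped(self):
        recs = [OocyteRecord(mouse_id="x", mother_h=0.0, h=0.1,
                             stage="primary"),
                OocyteRecord(mouse_id="y", mother_h=0.3, h=0.1,
                             stage="primary")]
        with pytest.warns(UserWarning, match="boundary"):
            out = stage_shift_summary(recs)
        assert out[0].n == 1


class TestHolm:
    def test_never_decreases(self):
        raw = [0.01, 0.04, 0.3, 0.9]
        adj = holm_adjust(raw)
        assert np.all(adj >= np.asarray(raw))
        assert np.all((adj >= 0) & (adj <= 1))


class TestAgeEffect:
    def test_null_small_correlation(self):
        small = 0
        for r in range(30):
            pairs = simulate_pedigree(PedigreeSimConfig(
                n_mothers=40, pups_per_mother=24, seed=r))
            small += abs(age_effect(pairs)["correlation"]) < 0.2
        assert small >= 27

    def test_injected_trend_detected(self):
        hits = 0
        for r in range(30):
            pairs = simulate_pedigree(PedigreeSimConfig(
                n_mothers=40, pups_per_mother=24,
                age_shift_per_month=-0.4, seed=r))
            res = age_effect(pairs)
            hits += res["correlation"] < 0 and res["p_value"] <= 0.05
        assert hits >= 27

    def test_single_delivery_errors(self):
        pairs = _pairs([0.3] * 4, [0.2, 0.25, 0.3, 0.35],
                       maternal_age_months=3.0, litter_id="L0", litter_size=4)
        with pytest.raises(DegenerateInputError):
            age_effect(pairs)

    def test_requires_covariates(self):
        with pytest.raises(InsufficientDataError):
            age_effect(_pairs([0.3] * 5, [0.2] * 5))


class TestLitterSize:
    def test_null_no_association(self):
        ok = 0
        for r in range(30):
            pairs = simulate_pedigree(PedigreeSimConfig(
                n_mothers=40, pups_per_mother=24, seed=100 + r))
            ok += litter_size_association(pairs)["p_value"] > 0.05
        assert ok >= 27

    def test_first_litter_filter(self):
        pairs = simulate_pedigree(PedigreeSimConfig(
            n_mothers=44, pups_per_mother=24, seed=3))
        res = litter_size_association(pairs, first_litter_only=True)
        assert res["n_deliveries"] == 44

    def test_constant_litter_size_errors(self):
        pairs = []
        for m in range(6):
            for i in range(8):
                pairs.append(TransmissionPair(
                    f"m{m}", f"p{m}.{i}", "F2", 0.2 + 0.05 * m, 0.2,
                    maternal_age_months=3.0, litter_id=f"L{m}",
                    litter_size=8))
        with pytest.raises(DegenerateInputError):
            litter_size_association(pairs)


class TestTissueCv:
    def test_identical_values_zero_cv(self):
        df = pd.DataFrame({"mouse_id": ["a"] * 5, "tissue": list("vwxyz"),
                           "h": [0.2] * 5})
        assert tissue_cv(df).grand_mean_cv == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # sd({0.10, 0.12}) = 0.0141421, mean 0.11 -> 12.8565%
        df = pd.DataFrame({"mouse_id": ["a", "a"], "tissue": ["t1", "t2"],
                           "h": [0.10, 0.12]})
        assert tissue_cv(df).grand_mean_cv == pytest.approx(12.8565, abs=1e-3)

    def test_scale_invariance(self):
        g = np.random.default_rng(1)
        h = g.uniform(0.1, 0.3, 10)
        df1 = pd.DataFrame({"mouse_id": "a", "tissue": range(10), "h": h})
        df2 = pd.DataFrame({"mouse_id": "a", "tissue": range(10), "h": 3 * h})
        assert tissue_cv(df1).grand_mean_cv == \
            pytest.approx(tissue_cv(df2).grand_mean_cv)

    def test_zero_mean_mouse_excluded(self):
        df = pd.DataFrame({
            "mouse_id": ["a", "a", "b", "b"],
            "tissue": ["t1", "t2", "t1", "t2"],
            "h": [0.0, 0.0, 0.1, 0.12]})
        with pytest.warns(UserWarning, match="CV undefined"):
            res = tissue_cv(df)
        assert list(res.per_mouse_cv) == ["b"]

    def test_grand_mean_is_arithmetic_mean(self):
        df = pd.DataFrame({
            "mouse_id": ["a", "a", "b", "b"],
            "tissue": ["t1", "t2", "t1", "t2"],
            "h": [0.1, 0.12, 0.2, 0.3]})
        res = tissue_cv(df)
        assert res.grand_mean_cv == pytest.approx(
            np.mean(list(res.per_mouse_cv.values())))


def _day_records(day_values, group="edited", h=0.1):
    recs = []
    for day, (wt, mut) in day_values.items():
        for i in range(5):
            recs.append(OocyteRecord(
                mouse_id=f"{group}{day}.{i}", mother_h=0.3,
                h=mut / (wt + mut) if wt + mut else 0.0, day=day,
                wt_copies=wt, mut_copies=mut, group=group))
    return recs


class TestCopyDynamics:
    def test_constant_copies_flat(self):
        recs = _day_records({0: (1000, 100), 3: (1000, 100), 7: (1000, 100)})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = copy_dynamics_summary(recs)
        tab = res["per_day"]
        assert tab["total_mean"].nunique() == 1
        assert (tab["total_sem"] == 0).all()

    def test_day7_comparison_gated(self):
        g = np.random.default_rng(2)
        recs = []
        for grp, mean in (("edited", 120_000), ("unedited", 100_000)):
            for day in (0, 7):
                for i in range(12):
                    wt = float(g.normal(mean, 5000))
                    recs.append(OocyteRecord(
                        mouse_id=f"{grp}{day}.{i}", mother_h=0.3, h=0.0,
                        day=day, wt_copies=wt, mut_copies=0.0, group=grp))
        res = copy_dynamics_summary(recs)
        cmp = res["day7_comparison"]
        assert cmp is not None
        assert cmp["test_used"] in ("t-test", "mann-whitney")
        assert cmp["p_value"] <= 0.05

    def test_missing_group_skips_comparison(self):
        recs = _day_records({0: (1000, 100), 7: (2000, 50)})
        with pytest.warns(UserWarning, match="skipped"):
            res = copy_dynamics_summary(recs)
        assert res["day7_comparison"] is None

    def test_single_day_insufficient(self):
        recs = _day_records({3: (1000, 100)})
        with pytest.raises(InsufficientDataError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                copy_dynamics_summary(recs)
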