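import numpy as np
import pytest

from pairsig.datamodel import (DomainError, ExpressionMatrix, RiskScore,
                               SurvivalData)
from pairsig.io import load_published_signature
from pairsig.pairs import PairMatrix, build_pair_matrix
from pairsig.signature import (ScreenConfig, evaluate_groups, score_rpi,
                               screen_prognostic_pairs, stratify,
                               subgroup_analysis)
from conftest import make_exponential_surv

#: sum of the ten published coefficients, computed independently
ALL_ONES_RPI = -5.022125484


@pytest.fixture(scope="module")
def published():
    return load_published_signature()


def _profile(published, ones=()):
    """Expression profile realizing chosen pair indicators: all genes tie
    at 1.0 (indicator 0); listed pairs get gene2 raised (indicator 1)."""
    prof = {g: 1.0 for g in published.genes}
    for g1, g2 in ones:
        prof[g2] = prof[g1] + 1.0
    return prof


class TestScoreRpi:
    def test_all_zero_indicators_score_zero(self, published):
        rs = score_rpi(_profile(published), published)
        assert rs.score[0] == 0.0

    def test_single_efnb3_ereg_indicator(self, published):
        rs = score_rpi(_profile(published, [("EFNB3", "EREG")]), published)
        assert rs.score[0] == -1.48200304

    def test_all_ones_sum_of_coefficients(self, published):
        # IGFBPL1 heads two pairs, so raise both partners above it
        prof = {g: 1.0 for g in published.genes}
        for g1, g2 in published.pairs:
            prof[g2] = 2.0
        rs = score_rpi(prof, published)
        assert rs.score[0] == pytest.approx(ALL_ONES_RPI, abs=1e-12)

    def test_missing_gene_listed_in_error(self, published):
        prof = _profile(published)
        del prof["EREG"], prof["SNCB"]
        with pytest.raises(DomainError, match="EREG"):
            score_rpi(prof, published)

    def test_expression_matrix_and_profiles_agree(self, published):
        rng = np.random.default_rng(0)
        genes = published.genes
        m = ExpressionMatrix(genes, [f"s{j}" for j in range(7)],
                             rng.lognormal(0, 1, size=(len(genes), 7)))
        cohort = score_rpi(m, published)
        for j, sid in enumerate(m.sample_ids):
            single = score_rpi(m.sample_profile(sid), published)
            assert single.score[0] == cohort.score[j]


class TestStratify:
    @pytest.mark.parametrize("score,expected", [
        (ALL_ONES_RPI, "low"),      # -5.022 < -4.774
        (0.0, "high"),              # 0 > -4.774
        (-4.774, "low"),            # exact tie falls to low
    ])
    def test_against_published_cutoff(self, score, expected):
        rs = stratify(RiskScore(["s"], [score]), -4.774)
        assert rs.group[0] == expected

    def test_cohort_and_single_sample_assignments_agree(self, published):
        rng = np.random.default_rng(1)
        genes = published.genes
        m = ExpressionMatrix(genes, [f"s{j}" for j in range(25)],
                             rng.lognormal(0, 2, size=(len(genes), 25)))
        cohort = stratify(score_rpi(m, published), published.cutoff)
        for j, sid in enumerate(m.sample_ids):
            single = stratify(score_rpi(m.sample_profile(sid), published),
                              published.cutoff)
            assert single.group[0] == cohort.group[j]


class TestCrossPlatformInvariance:
    def test_pair_matrix_scores_and_groups_identical_after_rescaling(
            self, published):
        rng = np.random.default_rng(2)
        genes = sorted(published.genes)
        fpkm = ExpressionMatrix(genes, [f"s{j}" for j in range(30)],
                                rng.lognormal(1, 1, size=(len(genes), 30)),
                                units="FPKM")
        # per-sample strictly increasing transform: global scale + power
        rpm = ExpressionMatrix(genes, fpkm.sample_ids,
                               (fpkm.values * 37.5) ** 1.3, units="RPM")
        pm_f = build_pair_matrix(fpkm, genes)
        pm_r = build_pair_matrix(rpm, genes)
        np.testing.assert_array_equal(pm_f.values, pm_r.values)
        s_f = stratify(score_rpi(fpkm, published), published.cutoff)
        s_r = stratify(score_rpi(rpm, published), published.cutoff)
        np.testing.assert_array_equal(s_f.score, s_r.score)
        np.testing.assert_array_equal(s_f.group, s_r.group)


def _screen_setup(rng, n, planted_hr=3.0, n_noise=30, prevalence=0.4):
    planted = (rng.random(n) < prevalence).astype(np.uint8)
    noise = (rng.random((n_noise, n)) < 0.5).astype(np.uint8)
    values = np.vstack([planted, noise])
    pairs = [(f"a{i:03d}", f"b{i:03d}") for i in range(n_noise + 1)]
    pm = PairMatrix(pairs, [f"s{i}" for i in range(n)], values)
    hazard = 0.03 * planted_hr ** planted.astype(float)
    surv = make_exponential_surv(rng, n, hazard, 80)
    return pm, surv, pairs[0]


class TestScreen:
    def test_planted_pair_with_hr3_is_selected(self):
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            pm, surv, planted = _screen_setup(rng, 300)
            res = screen_prognostic_pairs(pm, surv, ScreenConfig())
            hits += planted in res.selected
        assert hits / reps >= 0.9

    def test_selection_ordered_by_adjusted_p(self):
        rng = np.random.default_rng(3)
        pm, surv, _ = _screen_setup(rng, 300)
        res = screen_prognostic_pairs(pm, surv)
        sel_adj = [res.p_adjusted[res.pair_ids.index(p)] for p in res.selected]
        assert sel_adj == sorted(sel_adj)

    def test_constant_pair_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        pm, surv, _ = _screen_setup(rng, 100)
        pm.values[1] = 1
        with pytest.warns(UserWarning, match="constant"):
            res = screen_prognostic_pairs(pm, surv)
        assert res.p_adjusted[1] == 1.0

    def test_no_events_rejected(self):
        rng = np.random.default_rng(5)
        pm, surv, _ = _screen_setup(rng, 50)
        surv.event[:] = 0
        with pytest.raises(DomainError, match="events"):
            screen_prognostic_pairs(pm, surv)


class TestEvaluateGroups:
    def _scored(self, rng, n=400, group_hr=4.0):
        group = (rng.random(n) < 0.5).astype(float)
        surv = make_exponential_surv(rng, n, 0.02 * group_hr ** group, 120)
        scores = RiskScore([f"s{i}" for i in range(n)], group + rng.normal(0, 0.01, n))
        return stratify(scores, 0.5), surv

    def test_recovers_group_hazard_ratio(self):
        scores, surv = self._scored(np.random.default_rng(6))
        ev = evaluate_groups(scores, surv)
        assert 3.0 <= ev.hr_high_vs_low <= 5.3
        assert ev.hr_low_vs_high == pytest.approx(1 / ev.hr_high_vs_low)
        assert ev.logrank.p_value < 1e-6

    def test_three_horizons_return_three_aucs_in_order(self):
        scores, surv = self._scored(np.random.default_rng(7))
        ev = evaluate_groups(scores, surv, horizons=[12, 36, 60])
        assert list(ev.auc_by_horizon) == [12.0, 36.0, 60.0]
        assert all(0.5 < a <= 1 for a in ev.auc_by_horizon.values())

    def test_single_group_rejected(self):
        rng = np.random.default_rng(8)
        surv = make_exponential_surv(rng, 20, 0.1)
        scores = stratify(RiskScore(surv.sample_ids, np.ones(20)), 0.0)
        with pytest.raises(DomainError, match="group"):
            evaluate_groups(scores, surv)


class TestSubgroupAnalysis:
    def _cohort(self, rng, n=500):
        import pandas as pd
        from pairsig.datamodel import ClinicalTable
        group = (rng.random(n) < 0.5).astype(float)
        stage = (rng.random(n) < 0.5).astype(float)
        surv = make_exponential_surv(rng, n, 0.02 * 4.0 ** group * 2.0 ** stage, 150)
        clin = ClinicalTable(pd.DataFrame({
            "sex": (rng.random(n) < 0.5).astype(float),
            "age_ge_18m": np.ones(n),                      # single level
            "mycn_amplified": np.where(rng.random(n) < 0.05, np.nan,
                                       (rng.random(n) < 0.3).astype(float)),
            "stage4": stage,
            "os_time": surv.time, "os_event": surv.event},
            index=pd.Index(surv.sample_ids)))
        scores = stratify(RiskScore(surv.sample_ids,
                                    group + rng.normal(0, 0.01, n)), 0.5)
        return scores, clin, surv

    def test_effect_holds_in_every_evaluable_stratum(self):
        scores, clin, surv = self._cohort(np.random.default_rng(9))
        with pytest.warns(UserWarning, match="single level"):
            out = subgroup_analysis(scores, clin, surv, horizons=[12])
        assert "age_ge_18m" not in out          # degenerate factor skipped
        evaluated = [(f, lv) for f, d in out.items() for lv in d]
        assert len(evaluated) >= 6
        for f, d in out.items():
            for lv, ev in d.items():
                assert ev.hr_high_vs_low > 1.0

    def test_missing_values_only_affect_their_factor(self):
        scores, clin, surv = self._cohort(np.random.default_rng(10))
        with pytest.warns(UserWarning):
            out = subgroup_analysis(scores, clin, surv, horizons=[12])
        n_mycn = sum(ev.n_by_group["high"] + ev.n_by_group["low"]
                     for ev in out["mycn_amplified"].values())
        n_sex = sum(ev.n_by_group["high"] + ev.n_by_group["low"]
                    for ev in out["sex"].values())
        assert n_mycn < n_sex == len(scores)
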