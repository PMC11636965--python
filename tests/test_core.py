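"""The weighted score, influence expansion, covariance, and quadratic
form, checked against definitional and textbook oracles."""

import numpy as np
import pytest

from glogrank import (
    Dataset,
    SubjectRecord,
    TestOptions,
    design_from_dict,
    enumerate_embedded_regimes,
    fit_stratified,
    get_scenario,
    known_model,
    run_glogrank,
    score_contributions,
    simulate_dataset,
)
from glogrank.core import (
    InfluenceMatrix,
    ScoreVector,
    _Prepared,
    baseline_hazard_increments,
    bias_correct,
    consistency_indicator,
    covariance,
    gscore_test,
    history_covariate_matrix,
    influence_matrix,
    ipw_weight,
    regime_propensity,
    residual_adjust,
    score_vector,
)
from conftest import make_single_stage_dataset


def _three_arm_design():
    return design_from_dict(
        {
            "stages": [
                {
                    "options": ["A", "B", "C"],
                    "strata": [
                        {"key": [], "feasible": ["A", "B", "C"],
                         "probs": [1 / 3, 1 / 3, 1 / 3]}
                    ],
                }
            ]
        }
    )


@pytest.fixture(scope="module")
def setup():
    cfg = get_scenario("null_twobytwo")
    ds = simulate_dataset(cfg, 200, 50)
    regimes = enumerate_embedded_regimes(ds.design)
    model = known_model(ds.design)
    return ds, regimes, model


class TestPerSubjectQuantities:
    """C(u,d), pi(u,d) and Omega(u,d) at selected times."""

    def test_consistency_before_and_after_decisions(self, setup):
        ds, regimes, model = setup
        rec = next(r for r in ds.subjects if r.kappa == 2)
        mine = next(
            r for r in regimes
            if r.stage1_option() == rec.treatments[0]
            and r.rule_map[(2, ())] == rec.treatments[1]
        )
        other2 = next(
            r for r in regimes
            if r.stage1_option() == rec.treatments[0]
            and r.rule_map[(2, ())] != rec.treatments[1]
        )
        wrong1 = next(
            r for r in regimes
            if r.stage1_option() != rec.treatments[0]
        )
        t2 = rec.decision_times[1]
        design = ds.design
        assert consistency_indicator(rec, mine, design, t2 + 0.1) == 1
        assert consistency_indicator(rec, wrong1, design, 0.0) == 0
        # stage-2 mismatch not yet in force before the second decision
        assert consistency_indicator(rec, other2, design, t2 - 1e-9) == 1
        assert consistency_indicator(rec, other2, design, t2) == 0

    def test_propensity_products(self, setup):
        ds, regimes, model = setup
        rec = next(r for r in ds.subjects if r.kappa == 2)
        regime = regimes[0]
        t2 = rec.decision_times[1]
        design = ds.design
        assert regime_propensity(rec, regime, design, t2 - 1e-9, model) \
            == pytest.approx(0.5)
        assert regime_propensity(rec, regime, design, t2, model) \
            == pytest.approx(0.25)
        rec1 = next(r for r in ds.subjects if r.kappa == 1)
        assert regime_propensity(
            rec1, regime, design, rec1.followup_time, model
        ) == pytest.approx(0.5)

    def test_weight_values(self, setup):
        ds, regimes, model = setup
        design = ds.design
        rec = next(r for r in ds.subjects if r.kappa == 2)
        mine = next(
            r for r in regimes
            if r.stage1_option() == rec.treatments[0]
            and r.rule_map[(2, ())] == rec.treatments[1]
        )
        u = rec.followup_time  # still at risk (closed) at U
        assert ipw_weight(rec, mine, design, u, model) \
            == pytest.approx(4.0)
        assert ipw_weight(rec, mine, design, u + 0.1, model) == 0.0
        wrong = next(
            r for r in regimes
            if r.stage1_option() != rec.treatments[0]
        )
        assert ipw_weight(rec, wrong, design, 0.5, model) == 0.0

    def test_vectorized_weights_match_scalar_definition(self, setup):
        """The grid engine agrees exactly with the per-subject product
        formulas at every grid time."""
        cfg = get_scenario("null_stratified")
        ds = simulate_dataset(cfg, 50, 9)
        regimes = enumerate_embedded_regimes(ds.design)
        model = known_model(ds.design)
        grid = np.unique(
            [r.followup_time for r in ds.subjects if r.event]
        )
        W = _Prepared(ds, regimes, model).weights(grid)
        for i, rec in enumerate(ds.subjects):
            for j, regime in enumerate(regimes):
                for t_idx, u in enumerate(grid):
                    assert W[i, t_idx, j] == ipw_weight(
                        rec, regime, ds.design, u, model
                    )


class TestBaselineHazard:
    def test_single_arm_is_nelson_aalen(self):
        design = design_from_dict(
            {
                "stages": [
                    {
                        "options": ["A"],
                        "strata": [
                            {"key": [], "feasible": ["A"], "probs": [1.0]}
                        ],
                    }
                ]
            }
        )
        subjects = [
            SubjectRecord(i, 1, (0.0,), ("A",), ({},), u, e)
            for i, (u, e) in enumerate([(1.0, 1), (2.0, 1), (2.5, 0)])
        ]
        ds = Dataset(subjects, design)
        bh = baseline_hazard_increments(
            ds, enumerate_embedded_regimes(design), known_model(design)
        )
        np.testing.assert_allclose(bh.increments, [1 / 3, 1 / 2])

    def test_equal_randomization_pools_to_nelson_aalen(
        self, single_stage_design
    ):
        """With equal arms the constant 1/p weights cancel from the
        ratio, leaving the pooled Nelson-Aalen increments."""
        ds = make_single_stage_dataset(single_stage_design, 80, 3)
        regimes = enumerate_embedded_regimes(single_stage_design)
        bh = baseline_hazard_increments(
            ds, regimes, known_model(single_stage_design)
        )
        u = np.array([r.followup_time for r in ds.subjects])
        d = np.array([r.event for r in ds.subjects], dtype=bool)
        expected = [
            ((u == t) & d).sum() / (u >= t).sum() for t in bh.grid
        ]
        np.testing.assert_allclose(bh.increments, expected, atol=1e-12)
        assert np.all(np.diff(np.cumsum(bh.increments)) >= 0)


class TestScoreVector:
    def test_hand_worked_four_subjects(self, hand_dataset):
        """Arm A: events at 1, 3; arm B: event at 2, censored at 4; equal
        randomization. The weighted observed-minus-expected for arm A is
        2/p times (2 - 4/3) = 4/3."""
        regimes = enumerate_embedded_regimes(hand_dataset.design)
        sv = score_vector(
            hand_dataset, regimes, known_model(hand_dataset.design)
        )
        assert sv.values[0] == pytest.approx(4.0 / 3.0, abs=1e-12)

    def test_single_stage_reduction_to_logrank(self):
        """For one decision with equal randomization, each component is
        (1/p) times the textbook logrank observed-minus-expected."""
        design = _three_arm_design()
        ds = make_single_stage_dataset(design, 90, 7)
        regimes = enumerate_embedded_regimes(design)
        sv = score_vector(ds, regimes, known_model(design))
        u = np.array([r.followup_time for r in ds.subjects])
        delta = np.array([r.event for r in ds.subjects], dtype=bool)
        arms = np.array([r.treatments[0] for r in ds.subjects])
        oe = {}
        for arm in ("A", "B", "C"):
            total = 0.0
            for t in np.unique(u[delta]):
                at_risk = u >= t
                events = (u == t) & delta
                total += (events & (arms == arm)).sum() - events.sum() * (
                    at_risk & (arms == arm)
                ).sum() / at_risk.sum()
            oe[arm] = total
        expected = [3.0 * oe[r.stage1_option()] for r in regimes[:-1]]
        np.testing.assert_allclose(sv.values, expected, atol=1e-10)

    def test_mirrored_dataset_scores_zero(self, single_stage_design):
        """Duplicating the data with the two arms swapped forces the
        score, and hence the statistic, to zero."""
        ds = make_single_stage_dataset(single_stage_design, 40, 11)
        swap = {"A": "B", "B": "A"}
        mirrored = [
            SubjectRecord(
                r.id + 1000, r.kappa, r.decision_times,
                (swap[r.treatments[0]],), r.covariates,
                r.followup_time, r.event,
            )
            for r in ds.subjects
        ]
        sym = Dataset(ds.subjects + mirrored, single_stage_design)
        regimes = enumerate_embedded_regimes(single_stage_design)
        model = known_model(single_stage_design)
        sv = score_vector(sym, regimes, model)
        assert sv.values[0] == pytest.approx(0.0, abs=1e-10)
        infl = influence_matrix(sym, regimes, model)
        z, df, p = gscore_test(sv, covariance(infl), sym.n)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_fewer_than_two_regimes_rejected(self, hand_dataset):
        regimes = enumerate_embedded_regimes(hand_dataset.design)
        with pytest.raises(ValueError, match="at least two"):
            score_vector(
                hand_dataset, regimes[:1], known_model(hand_dataset.design)
            )


class TestInfluence:
    def test_column_sums_reproduce_score(self, twobytwo_dataset,
                                         twobytwo_regimes):
        model = fit_stratified(twobytwo_dataset)
        sv = score_vector(
            twobytwo_dataset, twobytwo_regimes, model, L=2.5
        )
        infl = influence_matrix(
            twobytwo_dataset, twobytwo_regimes, model, L=2.5
        )
        err = np.abs(infl.score - sv.values) / (1.0 + np.abs(sv.values))
        assert err.max() <= 1e-8

    def test_matches_bruteforce_expansion(self, hand_dataset):
        """Term-by-term re-computation of the influence expansion with
        plain Python loops."""
        regimes = enumerate_embedded_regimes(hand_dataset.design)
        model = known_model(hand_dataset.design)
        design = hand_dataset.design
        grid = [1.0, 2.0, 3.0]
        D = len(regimes)
        # weighted pooled hazard increment and risk shares
        dL, q = [], []
        for t in grid:
            num = den = 0.0
            risk_j = []
            for j, reg in enumerate(regimes):
                rj = 0.0
                for rec in hand_dataset.subjects:
                    w = ipw_weight(rec, reg, design, t, model)
                    num += w * (rec.followup_time == t and rec.event)
                    den += w * (rec.followup_time >= t)
                    rj += w * (rec.followup_time >= t)
                risk_j.append(rj)
            dL.append(num / den)
            q.append([r / sum(risk_j) for r in risk_j])
            assert sum(q[-1]) == pytest.approx(1.0)
            assert all(0 <= qq <= 1 for qq in q[-1])
        expected = np.zeros((4, D - 1))
        for i, rec in enumerate(hand_dataset.subjects):
            for j in range(D - 1):
                for t_idx, t in enumerate(grid):
                    m = (rec.followup_time == t and rec.event) - dL[
                        t_idx
                    ] * (rec.followup_time >= t)
                    expected[i, j] += ipw_weight(
                        rec, regimes[j], design, t, model
                    ) * m
                    for jp in range(D):
                        expected[i, j] -= (
                            ipw_weight(rec, regimes[jp], design, t, model)
                            * q[t_idx][j] * m
                        )
        infl = influence_matrix(hand_dataset, regimes, model)
        np.testing.assert_allclose(infl.values, expected, atol=1e-12)


class TestCovarianceAndRank:
    def test_zero_influence_gives_rank_zero(self):
        infl = InfluenceMatrix(
            values=np.zeros((10, 3)), regimes=[], L=1.0
        )
        cov = covariance(infl)
        assert cov.rank == 0
        with pytest.warns(UserWarning, match="rank 0"):
            z, df, p = gscore_test(np.zeros(3), cov, 10)
        assert (z, df, p) == (0.0, 0, 1.0)

    @pytest.mark.parametrize(
        "scenario,expected_rank",
        [("null_stratified", 5), ("null_switch", 3)],
    )
    def test_shared_path_rank_deficiency(self, scenario, expected_rank):
        """Full embedded-regime sets: the response-stratified design
        carries one exact linear dependency per initial arm (rank 5 of
        7x7); the responder-switch design is full rank (3)."""
        cfg = get_scenario(scenario)
        regimes = enumerate_embedded_regimes(cfg.design)
        for seed in range(3):
            ds = simulate_dataset(cfg, 400, seed)
            infl = influence_matrix(
                ds, regimes, known_model(ds.design), L=2.5
            )
            assert covariance(infl).rank == expected_rank

    def test_statistic_invariant_to_reference_choice(
        self, twobytwo_dataset, twobytwo_regimes
    ):
        model = known_model(twobytwo_dataset.design)
        zs = []
        for shift in range(len(twobytwo_regimes)):
            rotated = (
                twobytwo_regimes[shift:] + twobytwo_regimes[:shift]
            )
            infl = influence_matrix(
                twobytwo_dataset, rotated, model, L=2.5
            )
            z, _, _ = gscore_test(
                ScoreVector(infl.score, rotated, 2.5),
                covariance(infl),
                twobytwo_dataset.n,
            )
            zs.append(z)
        assert max(zs) - min(zs) <= 1e-6 * max(zs)

    def test_scalar_case(self, hand_dataset):
        regimes = enumerate_embedded_regimes(hand_dataset.design)
        model = known_model(hand_dataset.design)
        infl = influence_matrix(hand_dataset, regimes, model)
        cov = covariance(infl)
        z, df, p = gscore_test(
            ScoreVector(infl.score, regimes, np.inf), cov, 4
        )
        assert df == 1
        assert z == pytest.approx(
            infl.score[0] ** 2 / (4 * cov.matrix[0, 0])
        )


class TestResidualAdjust:
    def test_no_regressors_is_identity(self, twobytwo_dataset,
                                       twobytwo_regimes):
        model = fit_stratified(twobytwo_dataset)
        infl = influence_matrix(
            twobytwo_dataset, twobytwo_regimes, model, L=2.5
        )
        adj = residual_adjust(infl, np.zeros((twobytwo_dataset.n, 2)))
        np.testing.assert_array_equal(adj.values, infl.values)
        assert adj.n_regressors == 0

    def test_score_column_regression_preserves_score(
        self, twobytwo_dataset, twobytwo_regimes
    ):
        model = fit_stratified(twobytwo_dataset)
        infl = influence_matrix(
            twobytwo_dataset, twobytwo_regimes, model, L=2.5
        )
        sm = score_contributions(model, twobytwo_dataset)
        adj = residual_adjust(infl, sm.values, sm.columns)
        np.testing.assert_allclose(
            adj.score, infl.score, rtol=1e-10, atol=1e-10
        )
        # least-squares projection shrinks every column's sum of squares
        assert np.all(
            (adj.values ** 2).sum(axis=0)
            <= (infl.values ** 2).sum(axis=0) + 1e-12
        )

    def test_collinear_regressors_named(self, twobytwo_dataset,
                                        twobytwo_regimes):
        model = fit_stratified(twobytwo_dataset)
        infl = influence_matrix(
            twobytwo_dataset, twobytwo_regimes, model, L=2.5
        )
        x = np.random.default_rng(0).normal(size=twobytwo_dataset.n)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear.*(orig|dup)"):
            residual_adjust(infl, X, ["orig", "dup"])


class TestBiasCorrect:
    def test_inflation_factor(self, twobytwo_dataset, twobytwo_regimes):
        model = known_model(twobytwo_dataset.design)
        cov = covariance(
            influence_matrix(
                twobytwo_dataset, twobytwo_regimes, model, L=2.5
            )
        )
        corrected = bias_correct(cov, 250, 10)
        np.testing.assert_allclose(
            corrected.matrix, cov.matrix * 250 / 240
        )
        assert corrected.rank == cov.rank
        assert bias_correct(cov, 250, 0).matrix == pytest.approx(
            cov.matrix
        )
        with pytest.raises(ValueError):
            bias_correct(cov, 5, 10)

    def test_correction_deflates_statistic(self, twobytwo_dataset,
                                           twobytwo_regimes):
        a = run_glogrank(
            twobytwo_dataset, twobytwo_regimes,
            TestOptions(correction="none"),
        )
        b = run_glogrank(
            twobytwo_dataset, twobytwo_regimes,
            TestOptions(correction="dof"),
        )
        assert b.statistic < a.statistic


class TestRunPipeline:
    def test_smoke_defaults(self, twobytwo_dataset, twobytwo_regimes):
        res = run_glogrank(twobytwo_dataset, twobytwo_regimes)
        assert 0 <= res.p_value <= 1
        assert res.statistic >= 0
        assert res.df == 3
        assert res.L <= max(
            r.followup_time for r in twobytwo_dataset.subjects if r.event
        )
        counts = res.diagnostics["consistent_subjects"]
        assert sum(counts.values()) >= twobytwo_dataset.n

    def test_pairwise_comparison_has_df_one(self, twobytwo_dataset,
                                            twobytwo_regimes):
        res = run_glogrank(twobytwo_dataset, twobytwo_regimes[2:4])
        assert res.df == 1

    def test_known_and_estimated_differ(self, twobytwo_dataset,
                                        twobytwo_regimes):
        a = run_glogrank(
            twobytwo_dataset, twobytwo_regimes,
            TestOptions(propensity="known", correction="none"),
        )
        b = run_glogrank(
            twobytwo_dataset, twobytwo_regimes,
            TestOptions(propensity="stratified", correction="none"),
        )
        assert np.isfinite(a.statistic) and np.isfinite(b.statistic)
        assert a.statistic != b.statistic

    def test_covariate_matrix_selection(self, twobytwo_dataset):
        X, labels = history_covariate_matrix(twobytwo_dataset, "all")
        assert "x1_x1b" in labels and "x2_x2c" in labels
        np.testing.assert_allclose(
            X.mean(axis=0), 0.0, atol=1e-12
        )
        X2, l2 = history_covariate_matrix(twobytwo_dataset, ["x1b"])
        assert l2 == ["x1_x1b"]
        with pytest.raises(KeyError, match="nope"):
            history_covariate_matrix(twobytwo_dataset, ["nope"])
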