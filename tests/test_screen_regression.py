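"""The second-order regression engine: fit, stepwise pruning, interaction
classification, drug elimination, therapeutic window and ODC selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from odc.design import (
    CandidateCombination,
    DesignMatrix,
    DrugPanel,
    DrugSpec,
    build_search1_design,
    enumerate_candidates,
)
from odc.screen_regression import (
    AliasingError,
    InteractionCall,
    ScreenDataset,
    classify_interactions,
    eliminate_drugs,
    fit_second_order,
    model_matrix,
    second_order_terms,
    select_odc,
    stepwise_reduce,
    therapeutic_window,
)
from odc.synthetic_data import make_ground_truth, simulate_screen


def test_full_model_term_count_for_seven_drugs(panel7):
    # 7 first-order + 21 pairwise + 7 quadratic (+ implicit intercept)
    assert len(second_order_terms(panel7.names)) == 35


class TestFit:
    def test_noiseless_recovery_exact(self, planted3):
        truth, y_true, make_ds = planted3
        model = fit_second_order(make_ds(np.repeat(y_true[:, None], 3, axis=1)))
        for term, value in truth.items():
            assert model.coef[term] == pytest.approx(value, abs=1e-8)
        assert model.beta0 == pytest.approx(80.0, abs=1e-8)
        others = set(model.terms) - set(truth)
        assert max(abs(model.coef[t]) for t in others) < 1e-8

    def test_matches_statsmodels_ols(self, planted3, rng):
        import statsmodels.api as sm

        _, y_true, make_ds = planted3
        y = y_true[:, None] + rng.normal(0, 5, (len(y_true), 3))
        ds = make_ds(y)
        model = fit_second_order(ds)
        coded, yy = ds.observations()
        X = np.column_stack(
            [np.ones(len(yy)), model_matrix(coded, model.drug_names, model.terms)]
        )
        ref = sm.OLS(yy, X).fit()
        np.testing.assert_allclose(
            [model.beta0] + [model.coef[t] for t in model.terms], ref.params, atol=1e-9
        )
        np.testing.assert_allclose(
            [model.se["Intercept"]] + [model.se[t] for t in model.terms],
            ref.bse,
            atol=1e-9,
        )
        np.testing.assert_allclose(
            [model.pvalue[t] for t in model.terms], ref.pvalues[1:], atol=1e-9
        )

    def test_aliased_terms_reported(self):
        # the fifth drug shadows the fourth exactly -> their terms are confounded
        import itertools

        panel = DrugPanel(tuple(DrugSpec.from_ic20(f"d{i}", 1.0) for i in range(5)))
        base = np.array(list(itertools.product((0, 2), repeat=4)), dtype=int)
        rows = np.column_stack([base, base[:, 3]])
        design = DesignMatrix(panel, rows, tuple(f"c{i}" for i in range(len(rows))))
        ds = ScreenDataset(
            design,
            "cancer",
            pd.DataFrame(
                {
                    "condition_id": [f"c{i}" for i in range(len(rows))],
                    "replicate": 1,
                    "viability_pct": 100.0,
                }
            ),
        )
        with pytest.raises(AliasingError) as err:
            fit_second_order(ds)
        assert any("d3" in t or "d4" in t for t in err.value.confounded)

    def test_coverage_of_coefficient_confidence_intervals(self, planted3, design50, panel7):
        """95% t-intervals on the full model cover the truth at ~95%."""
        terms = second_order_terms(panel7.names)
        X = model_matrix(design50.coded_scores(), panel7.names, terms)
        rng = np.random.default_rng(11)
        beta = rng.normal(0, 3, len(terms))
        y0 = 90.0 + X @ beta
        _, _, make_ds = planted3
        hits = total = 0
        for seed in range(200):
            noise = np.random.default_rng(3000 + seed).normal(0, 5, (len(y0), 3))
            model = fit_second_order(make_ds(y0[:, None] + noise))
            ci = model.confint(0.95)
            for i, t in enumerate(terms):
                lo, hi = ci[t]
                hits += lo <= beta[i] <= hi
                total += 1
        assert 0.93 <= hits / total <= 0.97


class TestStepwise:
    def test_noiseless_exact_support(self, planted3):
        truth, y_true, make_ds = planted3
        model = fit_second_order(make_ds(np.repeat(y_true[:, None], 3, axis=1)))
        reduced = stepwise_reduce(model)
        assert set(reduced.terms) == set(truth)

    def test_alpha_one_drops_nothing(self, planted3, rng):
        _, y_true, make_ds = planted3
        model = fit_second_order(make_ds(y_true[:, None] + rng.normal(0, 5, (50, 3))))
        assert stepwise_reduce(model, alpha=1.0).terms == model.terms

    def test_weak_heredity_protects_parent_main_effects(self, design50, panel7):
        # pure-interaction truth: mains are zero but must survive while A:B does
        names = panel7.names
        terms = second_order_terms(names)
        X = model_matrix(design50.coded_scores(), names, terms)
        beta = np.array([-6.0 if t == "drug01:drug02" else 0.0 for t in terms])
        y = 80.0 + X @ beta
        rec = [
            {"condition_id": cid, "replicate": r + 1, "viability_pct": v}
            for cid, v in zip(design50.row_ids, y)
            for r in range(3)
        ]
        model = fit_second_order(ScreenDataset(design50, "cancer", pd.DataFrame(rec)))
        reduced = stepwise_reduce(model)
        assert "drug01:drug02" in reduced.terms
        assert {"drug01", "drug02"} <= set(reduced.terms)

    def test_never_increases_adjusted_error_on_noiseless_data(self, planted3):
        _, y_true, make_ds = planted3
        model = fit_second_order(make_ds(np.repeat(y_true[:, None], 3, axis=1)))
        assert stepwise_reduce(model).sigma2 <= model.sigma2 + 1e-12

    def test_true_terms_retained_under_noise(self, planted3):
        """Planted 3-term truth, noise sd 5, 50-run design: the true terms
        survive the backward pass in at least 90% of 100 runs (the full
        500-run study backs the acceptance suite)."""
        truth, y_true, make_ds = planted3
        kept = 0
        for seed in range(100):
            noise = np.random.default_rng(4000 + seed).normal(0, 5, (50, 3))
            reduced = stepwise_reduce(fit_second_order(make_ds(y_true[:, None] + noise)))
            kept += set(truth) <= set(reduced.terms)
        assert kept >= 90


class TestClassify:
    def _model_with(self, coef, pvalue, term="drug01:drug02"):
        from odc.screen_regression import SecondOrderModel

        return SecondOrderModel(
            model_id="cancer",
            drug_names=("drug01", "drug02"),
            terms=(term,),
            beta0=100.0,
            coef={term: coef},
            se={term: 1.0, "Intercept": 1.0},
            pvalue={term: pvalue, "Intercept": 0.0},
            sigma2=1.0,
            df_resid=10,
        )

    @pytest.mark.parametrize(
        "coef,p,label",
        [
            (-4.0, 0.001, "synergistic"),
            (4.0, 0.001, "antagonistic"),
            (-4.0, 0.2, "additive/neutral"),
        ],
    )
    def test_sign_and_significance_rule(self, coef, p, label):
        calls = classify_interactions(self._model_with(coef, p))
        assert calls[0].label == label


class TestEliminate:
    @staticmethod
    def _fit_reduced(truth_seed, screen_seed, **kwargs):
        truth = make_ground_truth(seed=truth_seed, **kwargs)
        design = build_search1_design(truth.panel)
        data = simulate_screen(truth, design, 3, seed=screen_seed, model="cancer")
        model = fit_second_order(data)
        return truth, model

    def test_drug_with_only_antagonism_is_eliminated(self):
        truth, model = self._fit_reduced(0, 1)
        names = model.drug_names
        calls = [
            InteractionCall(f"{names[0]}:{names[1]}", "antagonistic", 4.0, 0.001),
            InteractionCall(f"{names[2]}:{names[3]}", "synergistic", -5.0, 0.001),
            InteractionCall(names[4], "synergistic", -8.0, 0.001),
        ]
        result = eliminate_drugs(model, calls)
        assert names[0] in result.eliminated and names[1] in result.eliminated
        assert names[2] not in result.eliminated and names[3] not in result.eliminated

    def test_drug_in_two_synergies_is_retained(self):
        truth, model = self._fit_reduced(0, 1)
        names = model.drug_names
        calls = [
            InteractionCall(f"{names[0]}:{names[1]}", "synergistic", -4.0, 0.001),
            InteractionCall(f"{names[0]}:{names[2]}", "synergistic", -4.0, 0.001),
            InteractionCall(names[3], "synergistic", -9.0, 0.001),
        ]
        result = eliminate_drugs(model, calls)
        assert names[0] not in result.eliminated

    def test_forced_retention_keeps_minimum_panel(self):
        truth, model = self._fit_reduced(0, 1)
        names = model.drug_names
        # everything antagonistic -> all would fall; the rule must keep 4
        calls = [
            InteractionCall(f"{a}:{b}", "antagonistic", 3.0, 0.001)
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        ]
        result = eliminate_drugs(model, calls)
        assert len(result.panel) == 4
        assert result.forced_retained

    def test_planted_antagonist_is_eliminated_across_seeds(self):
        """A strong, purely antagonistic pair among 7 drugs (25 viability
        points when co-dosed, nothing else planted) is flagged and removed in
        ≥95% of 200 simulated screens."""
        hits = 0
        n = 200
        for seed in range(n):
            truth = make_ground_truth(
                seed=seed, n_synergies=0, n_antagonisms=1, effect_scale=25.0
            )
            ant_pair = [
                t for t, v in truth.beta_cancer.items() if ":" in t and v > 0
            ][0].split(":")
            design = build_search1_design(truth.panel)
            data = simulate_screen(truth, design, 3, seed=10_000 + seed, model="cancer")
            model = fit_second_order(data)
            result = eliminate_drugs(model, classify_interactions(model))
            hits += any(d in result.eliminated for d in ant_pair)
        assert hits / n >= 0.95


class TestTherapeuticWindow:
    @pytest.mark.parametrize(
        "noncancer,cancer,expected",
        [(100 - 39.2, 100 - 68.5, 29.3), (50.0, 50.0, 0.0), (90.0, 30.0, 60.0)],
    )
    def test_definition(self, noncancer, cancer, expected):
        assert therapeutic_window(noncancer, cancer) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(a=st.floats(0, 130), b=st.floats(0, 130))
    def test_antisymmetric(self, a, b):
        assert therapeutic_window(a, b) == -therapeutic_window(b, a)


class TestSelectODC:
    def test_single_candidate_returned(self, planted3):
        _, y_true, make_ds = planted3
        model = fit_second_order(make_ds(np.repeat(y_true[:, None], 3, axis=1)))
        cand = CandidateCombination(
            ("drug01", "drug02", "drug03", "drug04"), dict.fromkeys(
                ("drug01", "drug02", "drug03", "drug04"), 2
            )
        )
        assert select_odc(model, None, [cand]) is cand

    def test_empty_candidate_list_rejected(self, planted3):
        _, y_true, make_ds = planted3
        model = fit_second_order(make_ds(np.repeat(y_true[:, None], 3, axis=1)))
        with pytest.raises(ValueError):
            select_odc(model, None, [])

    def test_noiseless_selection_matches_exhaustive_truth(self):
        truth = make_ground_truth(seed=5, noise_sd=0.0)
        design = build_search1_design(truth.panel)
        model = stepwise_reduce(
            fit_second_order(simulate_screen(truth, design, 3, seed=0, model="cancer"))
        )
        cands = enumerate_candidates(truth.panel, 4, 2)
        best = select_odc(model, None, cands)
        assert best.key() == truth.planted_odc.key()

    def test_equal_tw_breaks_tie_on_cancer_viability(self):
        class Stub:
            drug_names = ("a", "b", "c", "d", "e")

            def __init__(self, vals):
                self.vals = vals

            def predict_candidate(self, cand):
                return self.vals[cand.members]

        m1 = {("a", "b", "c", "d"): 40.0, ("a", "b", "c", "e"): 30.0}
        cancer, healthy = Stub(m1), Stub({k: v + 20.0 for k, v in m1.items()})
        cands = [
            CandidateCombination(k, dict.fromkeys(k, 2)) for k in m1
        ]
        best = select_odc(cancer, healthy, cands)  # type: ignore[arg-type]
        assert best.ptw == pytest.approx(20.0)
        assert best.pred_cancer_viability == 30.0


def test_mean_absolute_coefficient_bias_small(planted3, design50, panel7):
    """At 3 replicates and noise sd 5, coefficients are unbiased well below
    half a viability point on average."""
    truth, y_true, make_ds = planted3
    terms = second_order_terms(panel7.names)
    true_beta = np.array([truth.get(t, 0.0) for t in terms])
    est = []
    for seed in range(150):
        noise = np.random.default_rng(5_500 + seed).normal(0, 5, (50, 3))
        model = fit_second_order(make_ds(y_true[:, None] + noise))
        est.append([model.coef[t] for t in terms])
    bias = np.abs(np.mean(est, axis=0) - true_beta)
    assert bias.mean() < 0.5


def test_normalization_anchors_controls_at_100(panel7, design50):
    truth = make_ground_truth(seed=1)
    data = simulate_screen(truth, design50, n_replicates=100, seed=3, model="cancer")
    ctrl = data.readouts[
        data.readouts["condition_id"].isin(design50.control_ids())
    ]["viability_pct"]
    assert ctrl.mean() == pytest.approx(100.0, abs=0.5)
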