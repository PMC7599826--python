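"""Signature construction: scoring algebra, selection, retention, groups."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_survival
from repairscore.maxstat import maxstat_cutpoint
from repairscore.signature import (
    GenePanel,
    PathwayScoreModel,
    RiskModel,
    apply_frozen_model,
    assign_global_group,
    compute_pathway_score,
    compute_pathway_scores,
    fit_pathway_cutpoints,
    load_reference_panel,
    retain_pathways,
    select_prognostic_genes,
)
from repairscore.survival import SurvivalData


def make_panel(rows):
    """Panel from (probe, pathway, cutpoint, beta) tuples."""
    table = pd.DataFrame(
        [
            {
                "probe_set": probe,
                "pathway": pw,
                "gene_symbol": probe,
                "cutpoint": cut,
                "beta": beta,
                "hazard_ratio": float(np.exp(beta)),
                "adjusted_p_train": 0.01,
                "adjusted_p_confirm": 0.01,
                "prognosis": "Bad" if beta > 0 else "Good",
            }
            for probe, pw, cut, beta in rows
        ]
    )
    return GenePanel(table)


class TestScoreAlgebra:
    PANEL = make_panel([("g1", "HRR", 5.0, 0.5), ("g2", "HRR", 7.0, 0.7)])

    def test_all_above_cutpoints(self):
        profile = pd.Series({"g1": 6.0, "g2": 8.0})
        assert compute_pathway_score(profile, self.PANEL, "HRR") == pytest.approx(1.2)

    def test_mixed_signs(self):
        profile = pd.Series({"g1": 6.0, "g2": 6.0})
        assert compute_pathway_score(profile, self.PANEL, "HRR") == pytest.approx(-0.2)

    def test_tie_takes_low_branch(self):
        # expression exactly at the cutpoint counts as "below/equal" (-1)
        panel = make_panel([("g1", "NER", 5.0, 0.9)])
        assert compute_pathway_score(
            pd.Series({"g1": 5.0}), panel, "NER"
        ) == pytest.approx(-0.9)

    def test_missing_probe_named(self):
        with pytest.raises(KeyError, match="g2"):
            compute_pathway_score(pd.Series({"g1": 6.0}), self.PANEL, "HRR")

    def test_multi_pathway_gene_counts_in_both(self):
        panel = make_panel(
            [("g1", "HRR", 5.0, 0.5), ("g1", "NER", 5.0, 0.5), ("g2", "NER", 7.0, 0.3)]
        )
        profile = pd.Series({"g1": 9.0, "g2": 9.0})
        assert compute_pathway_score(profile, panel, "HRR") == pytest.approx(0.5)
        assert compute_pathway_score(profile, panel, "NER") == pytest.approx(0.8)

    @given(
        betas=st.lists(
            st.floats(min_value=-2, max_value=2).filter(lambda b: abs(b) > 1e-3),
            min_size=1,
            max_size=6,
        ),
        flip=st.integers(min_value=0, max_value=5),
    )
    def test_crossing_one_cutpoint_moves_score_by_two_beta(self, betas, flip):
        flip = flip % len(betas)
        panel = make_panel(
            [(f"g{i}", "BER", 0.0, b) for i, b in enumerate(betas)]
        )
        below = pd.Series({f"g{i}": -1.0 for i in range(len(betas))})
        above = below.copy()
        above[f"g{flip}"] = 1.0
        s0 = compute_pathway_score(below, panel, "BER")
        s1 = compute_pathway_score(above, panel, "BER")
        assert s1 - s0 == pytest.approx(2 * betas[flip], rel=1e-9)
        # score range is [-sum|beta|, +sum|beta|]
        total = sum(abs(b) for b in betas)
        assert -total - 1e-9 <= s0 <= total + 1e-9

    def test_extremes_attained_when_signs_align(self):
        panel = make_panel([("g1", "BER", 0.0, 0.5), ("g2", "BER", 0.0, -0.7)])
        # max: positive-beta gene high, negative-beta gene low
        hi = compute_pathway_score(pd.Series({"g1": 1.0, "g2": -1.0}), panel, "BER")
        lo = compute_pathway_score(pd.Series({"g1": -1.0, "g2": 1.0}), panel, "BER")
        assert hi == pytest.approx(1.2)
        assert lo == pytest.approx(-1.2)


class TestReferencePanel:
    def test_shape_and_directions(self):
        panel = load_reference_panel()
        assert len(panel) == 23
        assert len(panel.table) == 27  # four genes sit in two pathways
        good = panel.table[panel.table["prognosis"] == "Good"]
        assert set(good["gene_symbol"]) == {"BRCA2", "SRCAP", "EP300", "RAD23A"}
        assert (good["beta"] < 0).all()
        assert (panel.table.loc[panel.table["prognosis"] == "Bad", "beta"] > 0).all()

    def test_dual_membership(self):
        panel = load_reference_panel()
        memb = panel.table.groupby("gene_symbol")["pathway"].apply(set)
        assert memb["BRCA2"] == {"FANC", "HRR"}
        assert memb["ERCC1"] == {"FANC", "NER"}
        assert memb["PMS2 /// PMS2CL"] == {"FANC", "MMR"}
        assert memb["XRCC1"] == {"BER", "NER"}

    def test_direction_inconsistency_rejected(self):
        table = load_reference_panel().table.copy()
        table.loc[table.index[0], "prognosis"] = "Good"  # now contradicts beta > 0
        with pytest.raises(ValueError, match="inconsist"):
            GenePanel(table)


class TestGlobalGroups:
    def test_two_pathway_mapping(self):
        flags = pd.DataFrame(
            {"HRR": [False, True, True, False], "NER": [False, True, False, True]}
        )
        groups = assign_global_group(flags)
        assert list(groups) == ["I", "III", "II", "II"]

    def test_zero_retained_rejected(self):
        with pytest.raises(ValueError):
            assign_global_group(pd.DataFrame(index=[0, 1]))

    def test_generalizes_to_three_pathways(self):
        flags = pd.DataFrame({"a": [False, True], "b": [False, True], "c": [True, True]})
        assert list(assign_global_group(flags)) == ["II", "III"]


class TestSelection:
    def _cohort(self, rng, n, effects=None):
        """Expression for 12 genes; `effects` maps probe -> (cutpoint, hr)."""
        genes = [f"g{i}" for i in range(12)]
        expr = pd.DataFrame(rng.normal(size=(n, 12)), columns=genes)
        lam = np.full(n, 1.0 / 300)
        for probe, (cut, hr) in (effects or {}).items():
            lam = lam * np.where(expr[probe] > cut, hr, 1.0)
        t_event = rng.exponential(1.0 / lam)
        cens = rng.exponential(900.0, n)
        surv = SurvivalData(np.minimum(t_event, cens), (t_event <= cens).astype(int))
        return expr, surv

    def test_empty_candidates_rejected(self, rng):
        expr, surv = self._cohort(rng, 30)
        with pytest.raises(ValueError):
            select_prognostic_genes(expr, surv, expr, surv, {})

    def test_candidate_absent_from_both_rejected(self, rng):
        expr, surv = self._cohort(rng, 30)
        with pytest.raises(ValueError, match="absent"):
            select_prognostic_genes(expr, surv, expr, surv, {"nope": "HRR"})

    def test_candidate_missing_from_one_cohort_skipped(self, rng):
        expr1, surv1 = self._cohort(rng, 40)
        expr2, surv2 = self._cohort(rng, 40)
        cand = {"g0": "HRR", "g1": "HRR"}
        with pytest.warns(UserWarning, match="skipping"):
            panel = select_prognostic_genes(
                expr1, surv1, expr2.drop(columns=["g1"]), surv2, cand
            )
        assert "g1" not in panel.probe_sets

    def test_planted_gene_selected_with_training_frozen_beta(self, rng):
        effects = {"g0": (0.0, 3.5)}
        expr1, surv1 = self._cohort(rng, 250, effects)
        expr2, surv2 = self._cohort(rng, 250, effects)
        cand = {g: "HRR" for g in expr1.columns}
        panel = select_prognostic_genes(expr1, surv1, expr2, surv2, cand)
        assert "g0" in panel.probe_sets
        row = panel.table[panel.table["probe_set"] == "g0"].iloc[0]
        assert row["hazard_ratio"] > 1.5
        assert abs(row["cutpoint"]) < 1.0  # near the planted threshold
        assert row["prognosis"] == "Bad"

    def test_membership_decision_symmetric_in_cohorts(self, rng):
        effects = {"g0": (0.0, 3.0)}
        expr1, surv1 = self._cohort(rng, 200, effects)
        expr2, surv2 = self._cohort(rng, 200, effects)
        cand = {g: "HRR" for g in expr1.columns}
        fwd = select_prognostic_genes(expr1, surv1, expr2, surv2, cand)
        rev = select_prognostic_genes(expr2, surv2, expr1, surv1, cand)
        assert set(fwd.probe_sets) == set(rev.probe_sets)


class TestPathwayCutpointsAndRetention:
    def test_constant_score_dropped_with_warning(self, rng):
        surv = random_survival(rng, 40)
        panel = make_panel([("g1", "HRR", 0.0, 0.5)])
        scores = pd.DataFrame({"HRR": rng.normal(size=40), "BER": np.zeros(40)})
        with pytest.warns(UserWarning, match="BER"):
            models = fit_pathway_cutpoints(scores, surv, panel)
        assert "BER" not in models
        assert "HRR" in models

    def test_cutpoint_matches_direct_maxstat_call(self, rng):
        surv = random_survival(rng, 60)
        panel = make_panel([("g1", "HRR", 0.0, 0.5)])
        score = rng.normal(size=60)
        models = fit_pathway_cutpoints(pd.DataFrame({"HRR": score}), surv, panel)
        direct = maxstat_cutpoint(score, surv, pmethod="none")
        assert models["HRR"].score_cutpoint == pytest.approx(direct.cutpoint)

    def test_single_strong_pathway_retained(self, rng):
        n = 150
        flag = rng.random(n) < 0.5
        lam = np.where(flag, 4.0, 1.0) / 300.0
        t_event = rng.exponential(1.0 / lam)
        surv = SurvivalData(t_event, np.ones(n, dtype=int))
        res = retain_pathways(pd.DataFrame({"HRR": flag}), surv)
        assert res.retained == ["HRR"]
        assert res.univariate.loc[0, "multivariate_hr"] > 1.0

    def test_constant_flag_excluded_and_reported(self, rng):
        surv = random_survival(rng, 50)
        flags = pd.DataFrame(
            {"HRR": rng.random(50) < 0.5, "NER": np.ones(50, dtype=bool)}
        )
        res = retain_pathways(flags, surv)
        assert "NER" in res.excluded_constant

    def test_null_pathways_return_empty_set_not_error(self, rng):
        surv = random_survival(rng, 80)
        flags = pd.DataFrame({"HRR": rng.random(80) < 0.5, "NER": rng.random(80) < 0.5})
        res = retain_pathways(flags, surv, alpha=1e-6)
        assert res.retained == []

    def test_two_true_pathways_selected_among_five(self, rng):
        # flags correlated ~0.3; two drive survival
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 200
            shared = rng.normal(size=n)
            latent = 0.55 * shared[:, None] + rng.normal(size=(n, 5))
            flags = pd.DataFrame(latent > 0, columns=list("abcde"))
            lam = 1.0 / 400 * np.exp(
                0.9 * flags["a"].to_numpy() + 0.9 * flags["b"].to_numpy()
            )
            surv = SurvivalData(rng.exponential(1.0 / lam), np.ones(n, dtype=int))
            res = retain_pathways(flags, surv)
            hits += set(res.retained) == {"a", "b"}
        assert hits >= int(0.8 * n_rep)


class TestFrozenModel:
    def test_training_reapplication_is_idempotent(self, trained_study):
        model = trained_study["model"]
        expr = trained_study["training"].expression
        first = apply_frozen_model(expr, model)
        second = apply_frozen_model(expr, model)
        pd.testing.assert_series_equal(first.global_group, second.global_group)
        pd.testing.assert_series_equal(
            first.global_group,
            trained_study["table_training"]["global_group"],
            check_names=False,
        )

    def test_patient_order_invariance(self, trained_study, rng):
        model = trained_study["model"]
        expr = trained_study["validation"].expression
        base = apply_frozen_model(expr, model).global_group
        perm = rng.permutation(len(expr))
        shuffled = apply_frozen_model(expr.iloc[perm], model).global_group
        pd.testing.assert_series_equal(shuffled.sort_index(), base.sort_index())

    def test_missing_probe_sets_listed(self, trained_study):
        model = trained_study["model"]
        expr = trained_study["validation"].expression
        victim = model.panel.probe_sets[0]
        with pytest.raises(KeyError, match=victim):
            apply_frozen_model(expr.drop(columns=[victim]), model)

    def test_json_round_trip_lossless(self, trained_study, tmp_path):
        model = trained_study["model"]
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = RiskModel.from_json(path)
        pd.testing.assert_frame_equal(
            loaded.panel.table, model.panel.table, check_exact=True
        )
        assert loaded.retained_pathways == model.retained_pathways
        assert loaded.merge_map == model.merge_map
        assert {
            k: v.score_cutpoint for k, v in loaded.pathway_models.items()
        } == {k: v.score_cutpoint for k, v in model.pathway_models.items()}

    def test_validation_group_iii_has_worse_survival(self, trained_study):
        from repairscore.survival import km_estimate, logrank_test

        model = trained_study["model"]
        va = trained_study["validation"]
        strat = apply_frozen_model(va.expression, model)
        surv = SurvivalData.from_frame(va.clinical)
        extremes = strat.global_group.isin(["I", "III"]).to_numpy()
        res = logrank_test(surv.subset(extremes), strat.global_group[extremes])
        assert res.p_value < 0.05
        med_iii = km_estimate(
            surv.subset((strat.global_group == "III").to_numpy())
        ).median
        med_i = km_estimate(surv.subset((strat.global_group == "I").to_numpy())).median
        assert med_i is None or med_iii < med_i
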