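"""Candidate generation, titer-threshold screening, diversity-aware
proposal selection, and in-silico validation."""

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from choopt.datastore import INPUT_FEATURES, OUTPUT_KPIS
from choopt.models import ModelSpec, fit_surrogate
from choopt.screening import (
    CandidateSpace,
    _greedy_maxmin,
    condition_from_row,
    generate_candidates,
    run_kpis,
    screen,
    select_proposals,
    validate_in_silico,
)
from choopt.simulator import STD_CONDITION, SimulatorParams, simulate_run


def _toy_space(m=1000, seed=0):
    return CandidateSpace(
        continuous={"ph_setpoint": (6.8, 7.5), "do_setpoint": (20, 100),
                    "vcd0": (0.1, 0.5), "glc_start": (6, 12), "gln_start": (1, 12)},
        discrete={"glc_feed_target": (0, 5, 9), "feed_start_day": (-1, 1, 3, 5),
                  "ph_shift_day": (-1, 0, 3, 4, 5),
                  "process_time": tuple(range(13))},
        m=m, seed=seed)


@pytest.fixture(scope="module")
def toy_model(full58_clean_module):
    return fit_surrogate(full58_clean_module, ModelSpec(family="tree_ensemble",
                                                        n_trees=20), seed=0)


@pytest.fixture(scope="module")
def full58_clean_module():
    # local lightweight dataset for screening tests (module-scoped to avoid
    # refitting per test)
    from choopt import datastore, preprocess
    from choopt.simulator import build_design, generate_dataset
    runs = generate_dataset(build_design("FULL_58"), SimulatorParams(noise_cv=0.05),
                            seed=21)
    return preprocess.clean_points(datastore.flatten_to_points(runs))


class TestGenerateCandidates:
    def test_reproducible_and_within_domains(self):
        space = _toy_space(m=10, seed=5)
        a, b = generate_candidates(space), generate_candidates(space)
        pd.testing.assert_frame_equal(a, b)
        assert a.shape == (10, 9)
        assert a["ph_setpoint"].between(6.8, 7.5).all()
        assert a["feed_start_day"].isin([-1, 1, 3, 5]).all()

    def test_degenerate_interval_constant(self):
        space = _toy_space(m=50)
        space = replace(space, continuous={**space.continuous, "vcd0": (0.3, 0.3)})
        cands = generate_candidates(space)
        assert (cands["vcd0"] == 0.3).all()

    def test_discrete_marginal_uniform(self):
        """Chi-square on a discrete input over 1e5 draws."""
        cands = generate_candidates(_toy_space(m=100_000, seed=3))
        counts = cands["glc_feed_target"].value_counts()
        chi2, p = stats.chisquare(counts.to_numpy())
        assert p > 0.001

    def test_empty_discrete_set_rejected(self):
        with pytest.raises(ValueError, match="empty discrete"):
            _toy_space().__class__(
                continuous={"ph_setpoint": (6.8, 7.5)},
                discrete={"feed_start_day": ()}, m=10)


class _QuadraticTiterModel:
    """Analytic stand-in: titer = 4.8 - (pH - 7.4)^2 * 20, other KPIs 0."""

    feature_names = tuple(INPUT_FEATURES)
    target_names = tuple(OUTPUT_KPIS)

    def predict_frame(self, candidates):
        ph = candidates["ph_setpoint"].to_numpy()
        out = pd.DataFrame(0.0, index=range(len(candidates)),
                           columns=list(OUTPUT_KPIS))
        out["titer_at_t"] = 4.8 - 20.0 * (ph - 7.4) ** 2
        return out


def test_screen_survivors_match_closed_form(monkeypatch):
    """|pH - 7.4| < 0.1 survives the 4.6 g/L filter under the toy model."""
    import choopt.screening as scr
    toy = _QuadraticTiterModel()

    def fake_predict(model, chunk):
        preds = toy.predict_frame(chunk)
        return preds, np.zeros(len(chunk), dtype=bool)

    monkeypatch.setattr(scr, "predict_kpis", fake_predict)
    cands = generate_candidates(_toy_space(m=1000, seed=8))
    result = scr.screen(toy, cands, threshold=4.6)
    expected = int((np.abs(cands["ph_setpoint"] - 7.4) < np.sqrt(0.2 / 20)).sum())
    assert len(result.survivors) == expected


class TestScreen:
    def test_threshold_minus_inf_keeps_all(self, toy_model, full58_clean_module):
        cands = generate_candidates(_toy_space(m=500, seed=2))
        result = screen(toy_model, cands, threshold=-np.inf)
        assert len(result.survivors) == 500

    def test_filter_monotone_in_threshold(self, toy_model):
        cands = generate_candidates(_toy_space(m=2000, seed=4))
        counts = [len(screen(toy_model, cands, threshold=t).survivors)
                  for t in (1.0, 2.0, 3.0, 4.0)]
        assert counts == sorted(counts, reverse=True)

    def test_batch_splitting_equivalence(self, toy_model):
        cands = generate_candidates(_toy_space(m=3000, seed=6))
        whole = screen(toy_model, cands, threshold=3.0)
        parts = screen(toy_model, cands, threshold=3.0, batch_size=700)
        pd.testing.assert_frame_equal(whole.survivors, parts.survivors)

    def test_survivors_equal_brute_force(self, toy_model):
        """Row-by-row recomputation reproduces the survivor set exactly."""
        from choopt.models import predict_kpis
        cands = generate_candidates(_toy_space(m=2000, seed=7))
        result = screen(toy_model, cands, threshold=3.2)
        pred, _ = predict_kpis(toy_model, cands)
        brute = {i for i in range(len(cands))
                 if pred.iloc[i]["titer_at_t"] > 3.2}
        assert set(result.survivors["candidate_index"]) == brute

    def test_titer_ranking_sorted(self, toy_model):
        cands = generate_candidates(_toy_space(m=2000, seed=9))
        result = screen(toy_model, cands, threshold=2.5)
        ranked = result.survivors.iloc[result.rankings["titer_at_t"]]
        vals = ranked["pred_titer_at_t"].to_numpy()
        assert np.all(np.diff(vals) <= 1e-12)


class TestSelectProposals:
    def test_collinear_pool_selection_includes_extremes(self):
        """Greedy max-min on 10 collinear points picks both segment ends and
        stays within factor 2 of the exhaustive optimum."""
        pts = np.linspace(0, 1, 10).reshape(-1, 1)

        def min_pairwise(idx):
            return min(abs(pts[a, 0] - pts[b, 0]) for a, b in combinations(idx, 2))

        chosen = _greedy_maxmin(pts, 4)
        assert 0 in chosen and 9 in chosen
        best = max(min_pairwise(c) for c in combinations(range(10), 4))
        assert min_pairwise(chosen) >= best / 2

    def test_picks_equal_pool_returns_pool_in_rank_order(self, toy_model):
        cands = generate_candidates(_toy_space(m=3000, seed=1))
        result = screen(toy_model, cands, threshold=2.0)
        picks = {kpi: 10 for kpi in OUTPUT_KPIS}
        props = select_proposals(result, toy_model, per_kpi_pool=10, picks=picks)
        sub = props[props["target_kpi"] == "titer_at_t"]
        assert len(sub) == 10
        top10 = result.survivors.iloc[result.rankings["titer_at_t"][:10]]
        assert set(sub["candidate_index"]) == set(top10["candidate_index"])

    def test_pool_too_small_raises(self, toy_model):
        cands = generate_candidates(_toy_space(m=200, seed=1))
        result = screen(toy_model, cands, threshold=100.0)  # nobody survives
        with pytest.raises(ValueError, match="per_kpi_pool"):
            select_proposals(result, toy_model, per_kpi_pool=10)

    def test_identical_pool_warns(self, toy_model):
        cands = generate_candidates(_toy_space(m=1, seed=3))
        cands = pd.concat([cands] * 12, ignore_index=True)
        result = screen(toy_model, cands, threshold=-np.inf)
        with pytest.warns(UserWarning, match="identical"):
            props = select_proposals(result, toy_model, per_kpi_pool=10)
        assert len(props) > 0


class TestValidateInSilico:
    def test_std_proposal_reproduces_std_kpis(self):
        """Validating the standard condition itself (noise-free) returns the
        standard KPIs exactly."""
        params = SimulatorParams(noise_cv=0.0)
        row = {"name": "std", "block": "II",
               "ph_setpoint": STD_CONDITION.ph_setpoint,
               "do_setpoint": STD_CONDITION.do_setpoint,
               "vcd0": STD_CONDITION.vcd0, "glc_start": STD_CONDITION.glc_start,
               "gln_start": STD_CONDITION.gln_start,
               "glc_feed_target": STD_CONDITION.glc_feed_target,
               "feed_start_day": STD_CONDITION.feed_start_day,
               "ph_shift_day": STD_CONDITION.ph_shift_day,
               "process_time": 12.0}
        props = pd.DataFrame([row])
        table = validate_in_silico(props, params, n_std_replicates=2, seed=0,
                                   ph_shift_value=STD_CONDITION.ph_shift_value)
        expected = run_kpis(simulate_run(STD_CONDITION, params, seed=0))
        for kpi in OUTPUT_KPIS:
            assert table.iloc[0][f"valid_{kpi}"] == pytest.approx(expected[kpi])
            assert table.iloc[0][f"pct_change_{kpi}"] == pytest.approx(0.0, abs=1e-9)

    def test_deviation_column_definition(self, toy_model):
        cands = generate_candidates(_toy_space(m=3000, seed=2))
        result = screen(toy_model, cands, threshold=2.0)
        props = select_proposals(result, toy_model, per_kpi_pool=10)
        table = validate_in_silico(props, SimulatorParams(noise_cv=0.0), seed=1)
        for kpi in OUTPUT_KPIS:
            np.testing.assert_allclose(
                table[f"dev_{kpi}"],
                (table[f"pred_{kpi}"] - table[f"valid_{kpi}"]).abs())

    def test_condition_from_row_roundtrip(self):
        cands = generate_candidates(_toy_space(m=5, seed=4))
        for _, row in cands.iterrows():
            cond = condition_from_row(row)
            cond.validate()
            assert cond.ph_setpoint == row["ph_setpoint"]
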