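"""Cohen's kappa, aggregation arithmetic, experiment harness audits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from somnet.evaluation import (
    CrossPredictionMatrix,
    cohens_kappa,
    external_stats,
    global_aggregate,
    load_published_benchmark,
    pooled_kappa,
    round_half_away,
    run_experiment1,
    run_experiment2,
    run_experiment3,
)
from somnet.model import ModelConfig
from somnet.psg_io import AASM_STAGES, ValidationError


def _brute_force_kappa(ref, pred):
    """Contingency-table definition, written independently."""
    pairs = [(r, p) for r, p in zip(ref, pred)
             if r in AASM_STAGES and p in AASM_STAGES]
    n = len(pairs)
    p_o = sum(1 for r, p in pairs if r == p) / n
    p_e = 0.0
    for c in AASM_STAGES:
        row = sum(1 for r, _ in pairs if r == c) / n
        col = sum(1 for _, p in pairs if p == c) / n
        p_e += row * col
    if p_e >= 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


class TestCohensKappa:
    def test_perfect_agreement(self):
        seq = ["W", "N1", "N2", "N3", "R", "N2"]
        assert cohens_kappa(seq, list(seq)).kappa == 1.0

    def test_chance_level_examples(self):
        assert cohens_kappa(["W", "W", "N2", "N2"],
                            ["W", "N2", "N2", "W"]).kappa == pytest.approx(0.0)
        assert cohens_kappa(["W", "N2"], ["W", "W"]).kappa == pytest.approx(0.0)

    def test_unknown_epochs_excluded_pairwise(self):
        rep = cohens_kappa(["W", "UNKNOWN", "N2", "N2"],
                           ["W", "W", "UNKNOWN", "N2"])
        assert rep.n_epochs_scored == 2
        assert rep.n_excluded_unknown == 2
        assert rep.confusion.sum() == 2

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValidationError):
            cohens_kappa(["W"], ["W", "N1"])
        with pytest.raises(ValidationError):
            cohens_kappa(["UNKNOWN"], ["W"])

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(2000):
            n = int(rng.integers(2, 200))
            ref = [AASM_STAGES[i] for i in rng.integers(0, 5, n)]
            pred = [AASM_STAGES[i] for i in rng.integers(0, 5, n)]
            assert cohens_kappa(ref, pred).kappa == pytest.approx(
                _brute_force_kappa(ref, pred), abs=1e-12
            )

    def test_matches_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(200):
            n = int(rng.integers(2, 100))
            ref = [AASM_STAGES[i] for i in rng.integers(0, 5, n)]
            pred = [AASM_STAGES[i] for i in rng.integers(0, 5, n)]
            if len(set(ref) | set(pred)) < 2:
                continue
            assert cohens_kappa(ref, pred).kappa == pytest.approx(
                sklearn_metrics.cohen_kappa_score(ref, pred), abs=1e-12
            )

    @given(st.lists(st.integers(0, 4), min_size=2, max_size=60),
           st.lists(st.integers(0, 4), min_size=2, max_size=60))
    def test_symmetry(self, a, b):
        n = min(len(a), len(b))
        ref = [AASM_STAGES[i] for i in a[:n]]
        pred = [AASM_STAGES[i] for i in b[:n]]
        assert cohens_kappa(ref, pred).kappa == pytest.approx(
            cohens_kappa(pred, ref).kappa, abs=1e-12
        )


class TestAggregationArithmetic:
    def test_published_external_row_average(self):
        # external kappas of one benchmark dataset under the base variant
        mn, mx, avg = external_stats([0.51, 0.56, 0.53, 0.52, 0.60])
        assert (mn, mx) == (0.51, 0.60)
        assert avg == pytest.approx(0.544)
        assert round_half_away(avg, 2) == pytest.approx(0.54)

    def test_degenerate_inputs(self):
        assert external_stats([0.5] * 5) == (0.5, 0.5, 0.5)
        assert external_stats([0.37]) == (0.37, 0.37, 0.37)

    def test_published_global_row(self):
        agg = global_aggregate(
            local=[0.74, 0.68, 0.75, 0.76, 0.76, 0.76],
            external_avg=[0.54, 0.49, 0.54, 0.56, 0.54, 0.53],
            ensemble=[0.61, 0.6, 0.62, 0.67, 0.61, 0.59],
        )
        assert round_half_away(agg["I"], 4) == pytest.approx(0.7417)
        assert round_half_away(agg["II"], 4) == pytest.approx(0.5333)
        assert round_half_away(agg["III"], 4) == pytest.approx(0.6167)
        assert round_half_away(agg["I_vs_II"], 4) == pytest.approx(-0.2083)
        assert round_half_away(agg["II_vs_III"], 4) == pytest.approx(0.0833)

    def test_identical_columns_give_zero_differences(self):
        agg = global_aggregate([0.7] * 3, [0.7] * 3, [0.7] * 3)
        assert agg["I_vs_II"] == agg["I_vs_III"] == agg["II_vs_III"] == 0.0

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.125, 2) == pytest.approx(0.13)
        assert round_half_away(-0.125, 2) == pytest.approx(-0.13)
        assert round_half_away(0.5333333, 4) == pytest.approx(0.5333)


class TestCrossPredictionMatrix:
    def test_external_column_excludes_diagonal(self):
        m = CrossPredictionMatrix(
            values=np.arange(9).reshape(3, 3) / 10.0,
            origin_ids=["a", "b", "c"],
        )
        np.testing.assert_allclose(m.external_column("b"), [0.1, 0.7])
        assert m.diagonal_biased

    def test_rejects_non_square(self):
        with pytest.raises(ValidationError):
            CrossPredictionMatrix(values=np.zeros((2, 3)), origin_ids=["a", "b"])


class TestPublishedBenchmark:
    def test_tables_are_complete(self):
        t = load_published_benchmark()
        assert len(t["local"]) == 6 * 14
        assert len(t["cross"]) == 6 * 14
        assert len(t["comparison"]) == 6 * 14
        assert len(t["global"]) == 14
        assert set(t["cross"]["dataset"]) == {
            "HMC", "Dublin", "SHHS", "Telemetry", "DREAMS", "ISRUC"
        }


@pytest.fixture(scope="module")
def micro_experiment():
    """Three tiny sites, one shared CNN_1 run of all three experiments."""
    from somnet.synthetic_psg import SimConfig, SiteConfig, site_patterns
    from somnet.training import TrainSettings

    sites = {}
    for i, name in enumerate(("u", "v", "w")):
        cfg = SimConfig(n_recordings=3, epochs_per_recording=8,
                        site=SiteConfig(name=name, fs=100), seed=100 + i)
        sites[name] = site_patterns(cfg)
    table, models, splits = run_experiment1(
        sites, ModelConfig(mode="CNN", L=1), seed=5,
        settings=TrainSettings(max_epochs=2), min_recordings=3,
    )
    matrix, cache = run_experiment2(models, sites)
    ens = run_experiment3(models, sites, cache)
    return sites, table, models, splits, matrix, cache, ens


class TestExperimentHarness:
    def test_experiment1_reports_one_row_per_site(self, micro_experiment):
        _, table, _, splits, _, _, _ = micro_experiment
        assert list(table["dataset"]) == ["u", "v", "w"]
        assert set(table.columns) >= {"iterations", "kappa_tr", "kappa_val", "kappa_ts"}
        for name, split in splits.items():
            assert not (set(split.train_ids) & set(split.test_ids))

    def test_experiment2_entry_is_direct_kappa(self, micro_experiment):
        sites, _, models, _, matrix, _, _ = micro_experiment
        origin, target = "u", "v"
        preds = [models[origin].predict_recording(r)[0].stages
                 for r in sites[target]]
        direct = pooled_kappa([r.stages for r in sites[target]], preds).kappa
        i, j = matrix.origin_ids.index(origin), matrix.origin_ids.index(target)
        assert matrix.values[i, j] == pytest.approx(direct)
        assert matrix.values.shape == (3, 3) and matrix.diagonal_biased

    def test_experiment3_excludes_own_model(self, micro_experiment):
        sites, _, models, _, matrix, cache, ens = micro_experiment
        assert set(ens) == set(sites)
        # recompute one target without the cache and without its own model
        from somnet.ensemble import EnsembleSpec, ensemble_predict

        target = "w"
        spec = EnsembleSpec(
            members=[(models[n], n) for n in sites if n != target],
            excluded_origin=target,
        )
        preds = [ensemble_predict(spec, r).stages for r in sites[target]]
        direct = pooled_kappa([r.stages for r in sites[target]], preds).kappa
        assert ens[target] == pytest.approx(direct)

    def test_experiment_repeat_is_deterministic(self, micro_experiment):
        sites, table, _, _, _, _, _ = micro_experiment
        from somnet.training import TrainSettings

        table2, _, _ = run_experiment1(
            sites, ModelConfig(mode="CNN", L=1), seed=5,
            settings=TrainSettings(max_epochs=2), min_recordings=3,
        )
        assert table.equals(table2)
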