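"""K-shot protocol, metrics, bootstrap comparison, FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import metamatch as mm
from metamatch.exceptions import ProtocolError, ValidationError


class TestSplits:
    def test_no_evaluation_participants_rejected(self):
        with pytest.raises(ProtocolError, match="evaluation"):
            mm.make_kshot_splits(10, 10, np.ones(10, dtype=bool))

    def test_insufficient_observed_rejected(self):
        mask = np.zeros(50, dtype=bool)
        mask[:5] = True
        with pytest.raises(ProtocolError, match="observed"):
            mm.make_kshot_splits(50, 10, mask)

    def test_deterministic_given_seed(self):
        mask = np.ones(100, dtype=bool)
        a = mm.make_kshot_splits(100, 20, mask, n_repetitions=5, seed=1)
        b = mm.make_kshot_splits(100, 20, mask, n_repetitions=5, seed=1)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.shot_idx, sb.shot_idx)
            np.testing.assert_array_equal(sa.eval_idx, sb.eval_idx)

    def test_shots_respect_observedness_and_partition(self):
        rng = np.random.default_rng(2)
        mask = rng.random(200) > 0.3
        splits = mm.make_kshot_splits(200, 30, mask, n_repetitions=10, seed=2)
        for s in splits:
            assert mask[s.shot_idx].all()
            assert s.shot_idx.size == 30
            union = np.union1d(s.shot_idx, s.eval_idx)
            np.testing.assert_array_equal(union, np.arange(200))

    def test_shot_frequency_within_binomial_band(self):
        """Over 100 repetitions with N = 1000, K = 100, each participant's
        shot frequency stays inside a 99% binomial band around 0.1."""
        n, k, reps = 1000, 100, 100
        splits = mm.make_kshot_splits(n, k, np.ones(n, dtype=bool), reps, seed=3)
        counts = np.zeros(n)
        for s in splits:
            counts[s.shot_idx] += 1
        lo, hi = stats.binom.ppf([0.005, 0.995], reps, k / n)
        # pointwise 99% band: ~1% of participants are expected outside it
        inside = np.mean((counts >= lo) & (counts <= hi))
        assert inside >= 0.97


class TestMetrics:
    def test_pearson_extremes(self):
        y = np.array([1.0, 2.0, 4.0, 3.0])
        assert mm.pearson_metric(y, y) == pytest.approx(1.0)
        assert mm.pearson_metric(y, -y) == pytest.approx(-1.0)

    def test_pearson_matches_independent_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=50), rng.normal(size=50)
        cov = np.sum((a - a.mean()) * (b - b.mean())) / 50
        expected = cov / (a.std() * b.std())
        assert mm.pearson_metric(a, b) == pytest.approx(expected, abs=1e-12)

    def test_pearson_undefined_is_missing_not_zero(self):
        assert np.isnan(mm.pearson_metric(np.ones(5), np.arange(5.0)))
        assert np.isnan(mm.pearson_metric(np.arange(2.0), np.arange(2.0)))

    def test_cod_perfect_and_baseline(self):
        y = np.array([1.0, 2.0, 3.0])
        assert mm.cod_metric(y, y, baseline_mean=1.5) == pytest.approx(1.0)
        assert mm.cod_metric(y, np.full(3, 1.5), 1.5) == pytest.approx(0.0)

    def test_cod_five_point_hand_computation(self):
        y = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        pred = np.array([3.0, 4.0, 5.0, 9.0, 10.0])
        baseline = 5.0  # from some hypothetical K-shot sample
        expected = 1 - ((1 + 0 + 1 + 1 + 0) / ((9 + 1 + 1 + 9 + 25)))
        assert mm.cod_metric(y, pred, baseline) == pytest.approx(expected)

    def test_cod_zero_denominator_is_missing(self):
        y = np.full(4, 2.0)
        assert np.isnan(mm.cod_metric(y, y + 1, baseline_mean=2.0))


class _MeanApproach:
    """Predicts the K-shot mean everywhere (the COD zero point)."""

    name = "shot_mean"

    def adapt_and_predict(self, shot, ev, y_shot, phenotype, seed):
        return np.full(ev.size, y_shot.mean())


def _toy_target(n=120, t=2, seed=5):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n, t))
    mask = np.ones((n, t), dtype=bool)
    names = [f"ph{j}" for j in range(t)]
    return values, mask, names


class TestExperiment:
    def test_identical_seeds_reproduce_results(self):
        values, mask, names = _toy_target()
        runs = [
            mm.run_kshot_experiment(
                [_MeanApproach()], values, mask, names, ks=[10], n_repetitions=4,
                seed=6,
            )
            for _ in range(2)
        ]
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_shot_mean_predictor_scores_zero_cod(self):
        values, mask, names = _toy_target()
        res = mm.run_kshot_experiment(
            [_MeanApproach()], values, mask, names, ks=[10, 20], n_repetitions=5,
            seed=7,
        )
        np.testing.assert_allclose(res["cod"], 0.0, atol=1e-12)

    def test_failing_approach_recorded_not_fatal(self):
        class Boom:
            name = "boom"

            def adapt_and_predict(self, *args):
                raise RuntimeError("deliberate")

        values, mask, names = _toy_target()
        res = mm.run_kshot_experiment(
            [Boom()], values, mask, names, ks=[10], n_repetitions=2, seed=8
        )
        assert res["pearson_r"].isna().all()
        assert len(res.attrs["failures"]) == 4  # 2 phenotypes x 2 repetitions

    def test_mean_r_non_decreasing_in_k(self):
        """More shots never hurt a consistent learner, within sampling error."""
        values, mask, names = _toy_target(n=300, t=2, seed=9)
        from metamatch.approaches import ClassicalKRRApproach

        rng = np.random.default_rng(10)
        lat = rng.normal(size=(300, 3))
        feats = lat @ rng.normal(size=(3, 40)) + rng.normal(size=(300, 40)) * 2
        values = lat @ rng.normal(size=(3, 2)) + rng.normal(size=(300, 2)) * 0.5
        res = mm.run_kshot_experiment(
            [ClassicalKRRApproach(feats)], values, np.ones_like(values, bool),
            names, ks=[10, 50, 150], n_repetitions=10, seed=11,
        )
        means = res.groupby("K")["pearson_r"].mean()
        assert means[50] >= means[10] - 0.05
        assert means[150] >= means[50] - 0.05


class TestBootstrap:
    def _paired_frame(self, seed=12, delta=0.0, n_pheno=6, n_rep=10):
        rng = np.random.default_rng(seed)
        rows = []
        for ph in range(n_pheno):
            base = rng.normal(scale=0.2, size=n_rep)
            for rep in range(n_rep):
                rows.append(dict(approach="a", K=10, repetition=rep,
                                 phenotype=f"p{ph}", pearson_r=base[rep] + delta,
                                 cod=base[rep] + delta))
                rows.append(dict(approach="b", K=10, repetition=rep,
                                 phenotype=f"p{ph}", pearson_r=base[rep],
                                 cod=base[rep]))
        return pd.DataFrame(rows)

    def test_self_comparison_gives_maximal_p(self):
        df = self._paired_frame()
        p = mm.bootstrap_compare(df, "a", "a", 10, n_boot=200, seed=13)
        assert p == 1.0

    def test_large_shift_gives_minimal_p(self):
        df = self._paired_frame(delta=5.0)
        p = mm.bootstrap_compare(df, "a", "b", 10, n_boot=200, seed=14)
        assert p == pytest.approx(2.0 / 201)

    def test_unpaired_grids_rejected(self):
        df = self._paired_frame()
        df = df[~((df["approach"] == "b") & (df["phenotype"] == "p0"))]
        with pytest.raises(ProtocolError, match="unpaired"):
            mm.bootstrap_compare(df, "a", "b", 10)

    def test_null_pvalues_approximately_uniform(self):
        """Under the null (both approaches identical processes), the p-value
        distribution is near-uniform: KS statistic < 0.15 at 200 draws."""
        rng = np.random.default_rng(15)
        ps = []
        for i in range(200):
            rows = []
            for ph in range(6):
                for rep in range(10):
                    rows.append(dict(approach="a", K=10, repetition=rep,
                                     phenotype=f"p{ph}",
                                     pearson_r=rng.normal(), cod=0.0))
                    rows.append(dict(approach="b", K=10, repetition=rep,
                                     phenotype=f"p{ph}",
                                     pearson_r=rng.normal(), cod=0.0))
            df = pd.DataFrame(rows)
            ps.append(mm.bootstrap_compare(df, "a", "b", 10, n_boot=1000,
                                           seed=1000 + i))
        ks = stats.kstest(ps, "uniform").statistic
        assert ks < 0.15


class TestFDR:
    def test_single_small_p_rejected(self):
        rej, adj = mm.fdr_correct(np.array([0.01]))
        assert rej[0] and adj[0] == pytest.approx(0.01)

    def test_all_ones_nothing_rejected(self):
        rej, _ = mm.fdr_correct(np.ones(10))
        assert not rej.any()

    def test_empty_input_empty_output(self):
        rej, adj = mm.fdr_correct(np.array([]))
        assert rej.size == 0 and adj.size == 0

    def test_matches_independent_step_up_oracle(self):
        """Agreement with a directly coded Benjamini-Hochberg step-up."""
        rng = np.random.default_rng(16)
        p = rng.uniform(size=20)
        rej, adj = mm.fdr_correct(p, q=0.05)

        order = np.argsort(p)
        m = p.size
        ranked = p[order] * m / (np.arange(m) + 1)
        adj_oracle = np.minimum.accumulate(ranked[::-1])[::-1]
        adj_oracle = np.minimum(adj_oracle, 1.0)
        out = np.empty(m)
        out[order] = adj_oracle
        np.testing.assert_allclose(adj, out, atol=1e-12)
        np.testing.assert_array_equal(rej, out <= 0.05)
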