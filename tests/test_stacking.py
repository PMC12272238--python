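"""Meta-matching: column bookkeeping, stacking behavior, adaptation."""

import numpy as np
import pytest

import metamatch as mm
from helpers import make_latent_collection, make_noise_dataset
from metamatch.exceptions import (
    ConfigurationError,
    ProtocolError,
    ValidationError,
)
from metamatch.mlp import MLPConfig
from metamatch.stacking import fit_stacking, train_multilayer

TINY_MLP = MLPConfig(hidden_sizes=(16, 8, 4), max_epochs=20, patience=4)
#: enough capacity/epochs for the network to actually learn the small
#: directional-recovery instances
ORACLE_MLP = MLPConfig(hidden_sizes=(64, 32, 16), max_epochs=100, patience=10)


class TestColumnCensus:
    def test_tiny_configuration_counts_and_labels(self, tiny_model, tiny_collection):
        """T = 4/3/2 gives multilayer 2*4 + 2*3 + 2*2 = 18 columns,
        dataset stacking 2*4 + 3 + 2 = 13, verified label by label."""
        _, target = tiny_collection
        f, labels = tiny_model.features(target.features[:5])
        assert f.shape == (5, 18)
        assert tiny_model.total_feature_count == 18
        expected = (
            [("src_xl", "mlp", f"src_xl_pheno_{j:02d}") for j in range(4)]
            + [("src_xl", "lrr", f"src_xl_pheno_{j:02d}") for j in range(4)]
            + [("src_large", "lrr", f"src_large_pheno_{j:02d}") for j in range(3)]
            + [("src_large", "stack", f"src_large_pheno_{j:02d}") for j in range(3)]
            + [("src_med", "lrr", f"src_med_pheno_{j:02d}") for j in range(2)]
            + [("src_med", "stack", f"src_med_pheno_{j:02d}") for j in range(2)]
        )
        assert labels == expected
        assert len(set(labels)) == len(labels)

        ds, ds_labels = tiny_model.dataset_stacking_features(target.features[:5])
        assert ds.shape == (5, 13)
        assert tiny_model.dataset_stacking_count == 13
        assert [lab for lab in ds_labels if lab[1] == "stack"] == []

        ss, ss_labels = tiny_model.single_source_features(target.features[:5])
        assert ss.shape == (5, 4)
        both, _ = tiny_model.single_source_features(
            target.features[:5], include_lrr=True
        )
        assert both.shape == (5, 8)

    def test_count_conservation(self, tiny_model):
        """multilayer - dataset_stacking = sum of non-extra-large T."""
        diff = tiny_model.total_feature_count - tiny_model.dataset_stacking_count
        assert diff == 3 + 2

    def test_xl_only_configuration_has_no_stackers(self):
        sources, target = make_latent_collection(
            1, specs=[("xl", 120, 4, "extra_large")]
        )
        model = train_multilayer(sources, seed=1, mlp_config=TINY_MLP)
        assert model.stackers == {}
        f, _ = model.features(target.features[:3])
        assert f.shape == (3, 8)

    def test_no_extra_large_dataset_rejected(self):
        sources, _ = make_latent_collection(
            2, specs=[("big", 120, 4, "large")]
        )
        with pytest.raises(ConfigurationError, match="extra-large"):
            train_multilayer(sources, seed=2)


class TestFitStacking:
    def _instance(self, k=30, c=6, seed=3):
        rng = np.random.default_rng(seed)
        f = rng.normal(size=(k, c))
        y = f[:, 0] * 2 + rng.normal(size=k) * 0.1
        return f, y, rng

    def test_too_few_participants_rejected(self):
        f, y, _ = self._instance(k=4)
        with pytest.raises(ProtocolError, match="5"):
            fit_stacking(f[:4], y[:4])

    def test_single_column_rejected(self):
        f, y, _ = self._instance()
        with pytest.raises(ValidationError, match="2 columns"):
            fit_stacking(f[:, :1], y)

    def test_all_columns_retained_below_column_count(self):
        """K = 10 < C = 67 runs with no feature truncation."""
        rng = np.random.default_rng(4)
        f = rng.normal(size=(10, 67))
        model = fit_stacking(f, rng.normal(size=10), seed=4)
        assert len(model.input_labels) == 67
        assert model.krr.train_features.shape == (10, 67)

    def test_column_permutation_covariance(self):
        """Permuting input columns together with labels leaves predictions
        unchanged (the correlation kernel sees the same row profiles)."""
        f, y, rng = self._instance()
        model = fit_stacking(f, y, seed=5)
        perm = rng.permutation(f.shape[1])
        model_p = fit_stacking(f[:, perm], y, seed=5)
        f_new = rng.normal(size=(8, f.shape[1]))
        np.testing.assert_allclose(
            model.predict(f_new), model_p.predict(f_new[:, perm]), atol=1e-10
        )

    def test_matches_best_informative_column(self):
        """Held-out accuracy approaches the best single column's when the
        columns load heterogeneously on one underlying signal.

        Heterogeneity matters: the correlation kernel centers each
        participant's prediction profile, so a signal shifting all columns
        equally is invisible to it — as with real prediction columns, the
        informative variation must differ across columns.
        """
        rng = np.random.default_rng(6)
        signal = rng.normal(size=400)
        loadings = np.array([1.0, -0.8, 0.6, -0.4, 0.2, 0, 0, 0, 0, 0])
        f = signal[:, None] * loadings + rng.normal(size=(400, 10)) * 0.5
        y = signal + rng.normal(size=400) * 0.3
        model = fit_stacking(f[:100], y[:100], seed=6)
        r_stack = mm.pearson_metric(y[100:], model.predict(f[100:]))
        r_best = max(
            mm.pearson_metric(y[100:], f[100:, j]) for j in range(10)
        )
        assert r_stack >= r_best - 0.05


class TestAdapt:
    def test_variant_feature_counts(self, tiny_model, tiny_collection):
        _, target = tiny_collection
        y = target.phenotypes.values[:, 0]
        for variant, count in [
            ("stacking", 4), ("dataset_stacking", 13), ("multilayer", 18),
        ]:
            adapted = mm.adapt(
                variant, tiny_model, target.features[:20], y[:20], seed=7
            )
            assert len(adapted.stacker.input_labels) == count
            preds = adapted.predict(target.features[20:])
            assert preds.shape == (target.n_participants - 20,)

    def test_unknown_variant_rejected(self, tiny_model, tiny_collection):
        _, target = tiny_collection
        with pytest.raises(ConfigurationError, match="variant"):
            tiny_model.features_for_variant("bogus", target.features[:5])

    def test_adaptation_uses_only_shot_participants(self, tiny_model, tiny_collection):
        """The adapted model is a function of the K shots alone."""
        _, target = tiny_collection
        y = target.phenotypes.values[:, 0]
        a = mm.adapt("multilayer", tiny_model, target.features[:20], y[:20], seed=8)
        b = mm.adapt("multilayer", tiny_model, target.features[:20], y[:20], seed=8)
        np.testing.assert_array_equal(
            a.stacker.krr.dual_coefs[0], b.stacker.krr.dual_coefs[0]
        )


class TestDirectionalRecovery:
    def test_meta_matching_beats_classical_krr_on_oracle_phenotype(self):
        """When the target phenotype is a noisy copy of a source phenotype,
        every meta-matching variant at K = 20 outperforms KRR trained on the
        same 20 participants (mean over 20 repetitions)."""
        from metamatch.approaches import (
            ClassicalKRRApproach,
            MetaMatchingApproach,
        )

        sources, target = make_latent_collection(
            9,
            specs=[
                ("xl", 400, 4, "extra_large"),
                ("lg", 150, 3, "large"),
                ("md", 80, 2, "medium"),
            ],
            target_spec=("tgt", 220, 1),
            noise_sd_features=3.0,
            cross_loading=1.0,  # target phenotype = source phenotype + noise
        )
        model = train_multilayer(sources, seed=9, mlp_config=ORACLE_MLP)
        approaches = [
            ClassicalKRRApproach(target.features),
            MetaMatchingApproach(model, target.features, "stacking"),
            MetaMatchingApproach(model, target.features, "dataset_stacking"),
            MetaMatchingApproach(model, target.features, "multilayer"),
        ]
        res = mm.run_kshot_experiment(
            approaches, target.phenotypes.values, target.phenotypes.mask,
            target.phenotypes.phenotype_names, ks=[20], n_repetitions=20,
            seed=9, on_error="raise",
        )
        means = res.groupby("approach")["pearson_r"].mean()
        for variant in ("stacking", "dataset_stacking", "multilayer"):
            assert means[variant] > means["classical_krr"], means

    def test_uninformative_extra_dataset_is_harmless(self):
        """Adding a pure-noise medium dataset moves multilayer mean r by
        less than 0.05 (stacking robustness)."""
        from metamatch.approaches import MetaMatchingApproach

        specs = [
            ("xl", 300, 4, "extra_large"),
            ("lg", 150, 3, "large"),
            ("md", 80, 2, "medium"),
        ]
        sources, target = make_latent_collection(
            10, specs=specs, target_spec=("tgt", 220, 2), noise_sd_features=4.0
        )
        noise = make_noise_dataset(np.random.default_rng(11), sources[0].n_features)
        model_a = train_multilayer(sources, seed=11, mlp_config=TINY_MLP)
        model_b = train_multilayer(sources + [noise], seed=11, mlp_config=TINY_MLP)

        def mean_r(model):
            res = mm.run_kshot_experiment(
                [MetaMatchingApproach(model, target.features, "multilayer")],
                target.phenotypes.values, target.phenotypes.mask,
                target.phenotypes.phenotype_names, ks=[20], n_repetitions=10,
                seed=12, on_error="raise",
            )
            return res["pearson_r"].mean()

        assert abs(mean_r(model_a) - mean_r(model_b)) < 0.05
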