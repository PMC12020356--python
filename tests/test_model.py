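import numpy as np
import pandas as pd
import pytest

from pfasorption.fixtures import EffectSpec, gen_sorption_dataset
from pfasorption.model import (
    FEATURES,
    PSSMConfig,
    ScalingBounds,
    StackedModel,
    ablate,
    assemble_features,
    fit_pssm,
    minmax_scale,
    split_holdout,
)
from pfasorption.metrics import evaluate


@pytest.fixture(scope="module")
def dataset(registry):
    """Complete (no gaps) synthetic dataset with a monotone ground truth."""
    entries, _ = gen_sorption_dataset(600, seed=101, registry=registry,
                                      missing_rate=0.0)
    return assemble_features(entries, registry)


@pytest.fixture(scope="module")
def fitted(dataset, fast_config):
    train, test = split_holdout(dataset, 0.2, seed=5)
    return fit_pssm(train, seed=5, config=fast_config), train, test


class TestAssembleFeatures:
    def test_neutral_compound_zero_charge_density(self, registry):
        entries, _ = gen_sorption_dataset(
            60, seed=1, registry=registry, compounds=["6-2FTOH"], missing_rate=0.0
        )
        df = assemble_features(entries, registry)
        assert (df["charge_density"] == 0.0).all()

    def test_trifluoroacetate_charge_density(self, registry):
        entries, _ = gen_sorption_dataset(
            40, seed=2, registry=registry, compounds=["TFA"], missing_rate=0.0
        )
        df = assemble_features(entries, registry)
        # TFA is essentially fully dissociated across the generated soil pH
        # range; two pH units above the pKa the descriptor sits at its floor
        assert df["charge_density"].between(-854.0, -840.0).all()
        well_above_pka = df.loc[df["ph"] >= 5.0, "charge_density"]
        assert np.allclose(well_above_pka, -853.7, atol=0.1)

    def test_speciation_dependence_on_soil_ph(self, registry):
        """A sulfonamide with pKa near neutral pH gets different charge
        density in acidic vs alkaline soils."""
        entries, _ = gen_sorption_dataset(
            200, seed=3, registry=registry, compounds=["PFOSA"], missing_rate=0.0
        )
        df = assemble_features(entries, registry)
        acidic = df.loc[df["ph"] < 4.5, "charge_density"]
        alkaline = df.loc[df["ph"] > 7.5, "charge_density"]
        assert acidic.abs().max() < 50.0
        assert alkaline.max() < -100.0

    def test_target_is_log10_kd(self, registry):
        entries, _ = gen_sorption_dataset(30, seed=4, registry=registry,
                                          missing_rate=0.0)
        df = assemble_features(entries, registry)
        assert np.allclose(df["log_kd"], np.log10([e.kd for e in entries]))

    def test_incomplete_soil_rejected(self, registry):
        entries, _ = gen_sorption_dataset(50, seed=5, registry=registry,
                                          missing_rate=0.5)
        with pytest.raises(ValueError, match="impute"):
            assemble_features(entries, registry)


class TestMinMaxScale:
    def test_unit_interval_mapping(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        scaled, bounds = minmax_scale(df, features=["a"])
        assert scaled[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_round_trip_inverse(self, dataset):
        scaled, bounds = minmax_scale(dataset)
        back = bounds.inverse(scaled)
        assert np.allclose(back, dataset[FEATURES].to_numpy(), rtol=1e-12)

    def test_constant_column_error_names_column(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 3.0]})
        with pytest.raises(ValueError, match="b"):
            minmax_scale(df, features=["a", "b"])

    def test_out_of_bounds_values_warn_and_extrapolate(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        _, bounds = minmax_scale(train, features=["a"])
        with pytest.warns(UserWarning, match="outside training bounds"):
            scaled = bounds.transform(pd.DataFrame({"a": [20.0]}))
        assert scaled[0, 0] == pytest.approx(2.0)


class TestSplitHoldout:
    def test_sizes(self, dataset):
        train, test = split_holdout(dataset, 0.2, seed=0)
        assert len(test) == 120 and len(train) == 480

    def test_floor_rule_on_odd_sizes(self, dataset):
        # floor(501 * 0.2) = 100 test, 401 train
        train, test = split_holdout(dataset.iloc[:501], 0.2, seed=0)
        assert (len(train), len(test)) == (401, 100)

    def test_disjoint_and_exhaustive(self, dataset):
        for seed in (0, 1, 99):
            train, test = split_holdout(dataset, 0.2, seed=seed)
            ids = set(train["entry_id"]) | set(test["entry_id"])
            assert ids == set(dataset["entry_id"])
            assert not set(train["entry_id"]) & set(test["entry_id"])

    def test_seed_reproducibility(self, dataset):
        a = split_holdout(dataset, 0.2, seed=7)[1]["entry_id"].tolist()
        b = split_holdout(dataset, 0.2, seed=7)[1]["entry_id"].tolist()
        c = split_holdout(dataset, 0.2, seed=8)[1]["entry_id"].tolist()
        assert a == b
        assert a != c

    def test_bad_fraction_rejected(self, dataset):
        for fraction in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                split_holdout(dataset, fraction, seed=0)


class TestStackedModel:
    def test_noiseless_recovery(self, registry, fast_config):
        """On noise-free data from a monotone rule the stack recovers the
        target: holdout RPD > 3."""
        entries, _ = gen_sorption_dataset(
            600, seed=201, effect=EffectSpec(sigma=0.0), registry=registry,
            missing_rate=0.0)
        df = assemble_features(entries, registry)
        train, test = split_holdout(df, 0.2, seed=201)
        model = fit_pssm(train, seed=201, config=fast_config)
        report = evaluate(test["log_kd"], model.predict(test))
        assert report.rpd > 3.0
        assert report.nrmse < 0.05

    def test_constant_target_predicts_constant(self, dataset, fast_config):
        train = dataset.iloc[:100].copy()
        train["log_kd"] = 1.7
        model = fit_pssm(train, seed=0, config=fast_config)
        pred = model.predict(dataset.iloc[200:220])
        assert np.allclose(pred, 1.7)

    def test_determinism_bit_for_bit(self, dataset, fast_config):
        train, test = split_holdout(dataset, 0.2, seed=3)
        a = fit_pssm(train, seed=3, config=fast_config).predict(test)
        b = fit_pssm(train, seed=3, config=fast_config).predict(test)
        assert np.array_equal(a, b)

    def test_monotone_in_log_kow(self, fitted):
        """Raising hydrophobicity at fixed soil raises the mean prediction
        (the generator's planted direction)."""
        model, train, _ = fitted
        base = train[FEATURES].iloc[:50].copy()
        lo, hi = base.copy(), base.copy()
        lo["log_kow"] = 2.0
        hi["log_kow"] = 7.0
        assert model.predict(hi).mean() > model.predict(lo).mean() + 0.5

    def test_batch_of_one_equals_row_of_batch(self, fitted):
        model, _, test = fitted
        batch = model.predict(test.iloc[:10])
        single = model.predict(test.iloc[[3]])
        assert single[0] == pytest.approx(batch[3], rel=1e-12)

    def test_predict_kd_is_power_of_ten(self, fitted):
        model, _, test = fitted
        assert np.allclose(model.predict_kd(test.iloc[:5]),
                           10 ** model.predict(test.iloc[:5]))

    def test_unfitted_predict_rejected(self, fast_config):
        with pytest.raises(RuntimeError):
            StackedModel(fast_config, seed=0).predict(pd.DataFrame())

    def test_missing_feature_column_rejected(self, fitted):
        model, _, test = fitted
        with pytest.raises(ValueError, match="charge_density"):
            model.predict(test.drop(columns=["charge_density"]))

    def test_too_small_training_set_rejected(self, dataset, fast_config):
        with pytest.raises(ValueError, match=">= 50"):
            fit_pssm(dataset.iloc[:20], seed=0, config=fast_config)

    def test_oof_meta_training_no_leakage(self, dataset, fast_config):
        """Shuffling test labels cannot systematically improve test NRMSE:
        the metric under true labels beats the label-shuffled one."""
        train, test = split_holdout(dataset, 0.2, seed=13)
        model = fit_pssm(train, seed=13, config=fast_config)
        pred = model.predict(test)
        true_nrmse = evaluate(test["log_kd"], pred).nrmse
        rng = np.random.default_rng(13)
        shuffled = [evaluate(rng.permutation(test["log_kd"].to_numpy()), pred).nrmse
                    for _ in range(5)]
        assert true_nrmse < min(shuffled)

    def test_save_load_round_trip(self, fitted, tmp_path):
        model, _, test = fitted
        model.save(tmp_path / "m")
        loaded = StackedModel.load(tmp_path / "m")
        assert np.allclose(loaded.predict(test), model.predict(test))
        assert loaded.manifest["n_train"] == model.manifest["n_train"]

    def test_out_of_domain_flagging(self, fitted):
        model, train, _ = fitted
        inside = train[FEATURES].iloc[:3].copy()
        outside = inside.copy()
        outside["corg"] = 1e4
        assert not model.out_of_domain(inside).any()
        assert model.out_of_domain(outside).all()


class TestAblate:
    def test_unknown_feature_rejected(self, dataset):
        with pytest.raises(ValueError):
            ablate(dataset, "not_a_feature", seed=0)

    def test_dropping_pure_noise_feature_is_harmless(self, registry, fast_config):
        """silt is irrelevant in the generating rule; removing it moves NRMSE
        by < 0.01."""
        entries, _ = gen_sorption_dataset(500, seed=301, registry=registry,
                                          missing_rate=0.0)
        df = assemble_features(entries, registry)
        train, test = split_holdout(df, 0.2, seed=301)
        full = evaluate(test["log_kd"],
                        fit_pssm(train, seed=301, config=fast_config).predict(test))
        dropped = ablate(df, "silt", seed=301, config=fast_config)
        assert abs(dropped.nrmse - full.nrmse) < 0.01

    def test_dropping_the_informative_feature_degrades(self, registry, fast_config):
        """With a ground truth driven almost entirely by log KOW, removing it
        collapses performance."""
        effect = EffectSpec(b_log_corg=0.0, b_charge_density=0.0, b_ph=0.0,
                            sigma=0.1)
        entries, _ = gen_sorption_dataset(400, seed=302, effect=effect,
                                          registry=registry, missing_rate=0.0)
        df = assemble_features(entries, registry)
        report = ablate(df, "log_kow", seed=302, config=fast_config)
        # mw_effective remains a strong chain-length proxy, so drop both
        train, test = split_holdout(df, 0.2, seed=302)
        full = evaluate(test["log_kd"],
                        fit_pssm(train, seed=302, config=fast_config).predict(test))
        assert report.nrmse >= full.nrmse


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = PSSMConfig(rf_n_estimators=77, stacking="insample")
        cfg.to_yaml(tmp_path / "c.yaml")
        assert PSSMConfig.from_yaml(tmp_path / "c.yaml") == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        (tmp_path / "c.yaml").write_text("definitely_not_a_knob: 1\n")
        with pytest.raises(ValueError):
            PSSMConfig.from_yaml(tmp_path / "c.yaml")

    def test_insample_stacking_mode_runs(self, dataset):
        cfg = PSSMConfig(rf_n_estimators=30, et_n_estimators=30,
                         gb_n_estimators=30, stacking="insample",
                         mlp_max_iter=500)
        train, test = split_holdout(dataset, 0.2, seed=1)
        model = fit_pssm(train, seed=1, config=cfg)
        assert np.isfinite(model.predict(test)).all()
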