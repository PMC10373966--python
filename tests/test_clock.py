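import numpy as np
import pandas as pd
import pytest

from epoch import clock, de
from epoch.sim_counts import CountMatrix, SimCountConfig, simulate_clock_cohort
from .test_de import brute_force_bh


def _cohort(seed=0, n=80, n_age=100, slope_sd=0.03, n_genes=600, ages=None):
    cfg = SimCountConfig(
        n_genes=n_genes,
        samples_per_group=n,
        groups=("cohort",),
        n_senescence_genes_up=0,
        n_senescence_genes_down=0,
        n_age_genes=n_age,
        age_slope_sd=slope_sd,
        ages=ages,
        seed=seed,
    )
    return simulate_clock_cohort(cfg)


def _split(cm, n_hold, seed=0):
    ids = list(cm.counts.columns)
    order = np.random.default_rng(seed).permutation(len(ids))
    hold = [ids[i] for i in order[:n_hold]]
    train = [ids[i] for i in order[n_hold:]]

    def sub(keep):
        return CountMatrix(
            counts=cm.counts[keep], sample_metadata=cm.sample_metadata.loc[keep]
        )

    return sub(train), sub(hold)


class TestPreprocess:
    def test_training_mode_zero_mean_unit_sd(self, two_group_matrix):
        scaled = clock.preprocess_expression(two_group_matrix)
        z = scaled.z.to_numpy()
        assert np.allclose(z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(z.std(axis=1), 1.0, atol=1e-9)

    def test_zero_sd_genes_excluded(self):
        arr = np.vstack([np.full((1, 6), 100), np.random.default_rng(0).integers(50, 200, (20, 6))])
        samples = [f"s{i}" for i in range(6)]
        md = pd.DataFrame(
            {"group": "a", "age": np.nan, "library_size": arr.sum(0)},
            index=pd.Index(samples, name="sample_id"),
        )
        cm = CountMatrix(
            counts=pd.DataFrame(arr, index=[f"g{i}" for i in range(21)], columns=samples),
            sample_metadata=md,
        )
        # g0 constant only if size factors are equal; force that case
        cm.counts.iloc[1:] = 77
        scaled = clock.preprocess_expression(cm)
        assert "g0" not in scaled.z.index or (scaled.gene_sds > 0).all()

    def test_application_mode_shift_maps_to_z_units(self):
        """Quadrupling one gene's counts moves its z by ~2 / training SD."""
        cohort = _cohort(seed=1, n=30)
        scaled = clock.preprocess_expression(cohort)
        model = clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)
        app = clock.preprocess_expression(cohort, model)
        gene = max(model.genes, key=lambda g: cohort.counts.loc[g].min())
        bumped_counts = cohort.counts.copy()
        bumped_counts.loc[gene] *= 4
        bumped = CountMatrix(
            counts=bumped_counts, sample_metadata=cohort.sample_metadata
        )
        app_b = clock.preprocess_expression(bumped, model)
        i = model.genes.index(gene)
        shift = (app_b.z.loc[gene] - app.z.loc[gene]).mean()
        assert shift == pytest.approx(2.0 / model.gene_sds[i], rel=0.05)


class TestImpute:
    def test_no_missing_genes_is_identity(self):
        cohort = _cohort(seed=2, n=20)
        scaled = clock.preprocess_expression(cohort)
        model = clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)
        app = clock.preprocess_expression(cohort, model)
        imputed = clock.impute_missing(app, model)
        assert imputed.n_imputed == 0
        pd.testing.assert_frame_equal(imputed.z, app.z.reindex(model.genes))

    def test_all_clock_genes_missing_predicts_intercept(self):
        cohort = _cohort(seed=3, n=20)
        scaled = clock.preprocess_expression(cohort)
        model = clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)
        # a cohort sharing no gene ids with the clock
        other = cohort.counts.copy()
        other.index = [f"X{i}" for i in range(len(other))]
        cm = CountMatrix(counts=other, sample_metadata=cohort.sample_metadata)
        app = clock.impute_missing(clock.preprocess_expression(cm, model), model)
        assert app.n_imputed == len(model.genes)
        pred = clock.predict_tage(model, app)
        assert np.allclose(pred, model.intercept)

    def test_partial_dropout_degrades_gracefully(self):
        cohort = _cohort(seed=4, n=120, n_age=150)
        train, hold = _split(cohort, n_hold=30, seed=4)
        scaled = clock.preprocess_expression(train)
        model = clock.train_clock(scaled, train.sample_metadata["age"], seed=0)
        rng = np.random.default_rng(5)
        drop = rng.choice(hold.counts.index, size=len(hold.counts) // 5, replace=False)
        reduced = CountMatrix(
            counts=hold.counts.drop(index=drop),
            sample_metadata=hold.sample_metadata,
        )
        app = clock.impute_missing(clock.preprocess_expression(reduced, model), model)
        pred = clock.predict_tage(model, app)
        r = np.corrcoef(pred, hold.sample_metadata["age"])[0, 1]
        assert r >= 0.7


class TestTrainPredict:
    def test_parameter_recovery_on_held_out_samples(self):
        cohort = _cohort(seed=6, n=120, n_age=150)
        train, hold = _split(cohort, n_hold=30, seed=6)
        scaled = clock.preprocess_expression(train)
        model = clock.train_clock(scaled, train.sample_metadata["age"], seed=0)
        app = clock.impute_missing(clock.preprocess_expression(hold, model), model)
        pred = clock.predict_tage(model, app)
        r = np.corrcoef(pred, hold.sample_metadata["age"])[0, 1]
        assert r >= 0.9

    def test_null_cohort_fits_near_intercept_only(self):
        cohort = _cohort(seed=7, n=60, slope_sd=0.0)
        train, hold = _split(cohort, n_hold=20, seed=7)
        scaled = clock.preprocess_expression(train)
        model = clock.train_clock(scaled, train.sample_metadata["age"], seed=0)
        app = clock.impute_missing(clock.preprocess_expression(hold, model), model)
        pred = clock.predict_tage(model, app)
        true = hold.sample_metadata["age"].to_numpy()
        ss_res = ((pred - true) ** 2).sum()
        ss_tot = ((true - true.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot < 0.3  # no better than noise

    def test_training_is_deterministic(self):
        cohort = _cohort(seed=8, n=30)
        scaled = clock.preprocess_expression(cohort)
        ages = cohort.sample_metadata["age"]
        m1 = clock.train_clock(scaled, ages, seed=3)
        m2 = clock.train_clock(scaled, ages, seed=3)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        assert m1.intercept == m2.intercept

    def test_constant_ages_rejected(self):
        cohort = _cohort(seed=9, n=20, ages=tuple([50.0] * 20))
        scaled = clock.preprocess_expression(cohort)
        with pytest.raises(ValueError, match="constant ages"):
            clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)

    def test_prediction_linear_in_z(self):
        cohort = _cohort(seed=10, n=30)
        scaled = clock.preprocess_expression(cohort)
        model = clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)
        app = clock.impute_missing(clock.preprocess_expression(cohort, model), model)
        base = clock.predict_tage(model, app)
        active = int(np.flatnonzero(model.coef)[0]) if (model.coef != 0).any() else 0
        bumped = app.z.copy()
        bumped.iloc[active] += 1.0
        app2 = clock.ScaledExpression(
            z=bumped, gene_means=app.gene_means, gene_sds=app.gene_sds, from_model=True
        )
        pred2 = clock.predict_tage(model, app2)
        np.testing.assert_allclose(pred2 - base, model.coef[active], atol=1e-9)

    def test_prediction_invariant_to_row_and_column_order(self):
        cohort = _cohort(seed=11, n=24)
        scaled = clock.preprocess_expression(cohort)
        model = clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)
        app = clock.impute_missing(clock.preprocess_expression(cohort, model), model)
        pred = clock.predict_tage(model, app)
        shuffled = CountMatrix(
            counts=cohort.counts.iloc[::-1, ::-1],
            sample_metadata=cohort.sample_metadata.iloc[::-1],
        )
        app_s = clock.impute_missing(clock.preprocess_expression(shuffled, model), model)
        pred_s = clock.predict_tage(model, app_s)
        np.testing.assert_allclose(pred_s.loc[pred.index], pred, rtol=1e-10)

    def test_unpreprocessed_input_rejected(self):
        cohort = _cohort(seed=12, n=20)
        scaled = clock.preprocess_expression(cohort)  # training mode
        model = clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)
        with pytest.raises(ValueError, match="preprocessed"):
            clock.predict_tage(model, scaled)

    def test_model_json_roundtrip(self, tmp_path):
        cohort = _cohort(seed=13, n=20)
        scaled = clock.preprocess_expression(cohort)
        model = clock.train_clock(scaled, cohort.sample_metadata["age"], seed=0)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = clock.ClockModel.from_json(path)
        np.testing.assert_array_equal(loaded.coef, model.coef)
        assert loaded.genes == model.genes
        assert loaded.intercept == model.intercept


class TestCenterAndCompare:
    def test_single_control_has_zero_delta(self):
        t = pd.Series([25.0, 40.0], index=["c1", "x1"])
        delta = clock.center_tage(t, ["c1"])
        assert delta["c1"] == 0.0
        assert delta["x1"] == 15.0

    def test_known_median_arithmetic(self):
        t = pd.Series([10.0, 20.0, 30.0, 25.0], index=["a", "b", "c", "s"])
        delta = clock.center_tage(t, ["a", "b", "c"])
        assert delta["s"] == 5.0

    def test_shift_invariance_and_idempotence(self):
        t = pd.Series([10.0, 20.0, 30.0, 25.0], index=["a", "b", "c", "s"])
        d1 = clock.center_tage(t, ["a", "b", "c"])
        d2 = clock.center_tage(t + 100.0, ["a", "b", "c"])
        pd.testing.assert_series_equal(d1, d2)
        pd.testing.assert_series_equal(clock.center_tage(d1, ["a", "b", "c"]), d1)

    def test_control_median_exactly_zero(self):
        rng = np.random.default_rng(1)
        t = pd.Series(rng.normal(50, 5, 9), index=[f"s{i}" for i in range(9)])
        delta = clock.center_tage(t, [f"s{i}" for i in range(5)])
        assert np.median(delta.iloc[:5]) == 0.0

    def test_empty_control_set_rejected(self):
        with pytest.raises(ValueError):
            clock.center_tage(pd.Series([1.0], index=["a"]), [])

    def test_identical_groups_give_null_comparison(self):
        table = pd.DataFrame(
            {
                "group": ["ref"] * 3 + ["t"] * 3,
                "tAge": [50.0, 51.0, 52.0] * 2,
                "delta_tAge": [0.0, 1.0, 2.0] * 2,
            },
            index=[f"s{i}" for i in range(6)],
        )
        comp = clock.compare_tage_groups(table, "ref")
        assert comp["statistic"].iloc[0] == pytest.approx(0.0)
        assert comp["p"].iloc[0] == pytest.approx(1.0)

    def test_bh_matches_brute_force(self, rng):
        table = pd.DataFrame(
            {
                "group": np.repeat(["ref", "a", "b", "c", "d"], 4),
                "tAge": rng.normal(50, 3, 20),
            },
            index=[f"s{i}" for i in range(20)],
        )
        table["delta_tAge"] = table["tAge"] - 50
        comp = clock.compare_tage_groups(table, "ref")
        np.testing.assert_allclose(
            comp["p_adj"], brute_force_bh(comp["p"].to_numpy()), rtol=1e-12
        )

    def test_detection_power_matches_analytic(self, rng):
        """-3 year shift at SD 1, n=3/group: rejection rate near closed form."""
        from statsmodels.stats.power import TTestIndPower

        reps, n, shift = 200, 3, -3.0
        hits = 0
        for _ in range(reps):
            table = pd.DataFrame(
                {
                    "group": ["ref"] * n + ["t"] * n,
                    "delta_tAge": np.concatenate(
                        [rng.normal(0, 1, n), rng.normal(shift, 1, n)]
                    ),
                },
                index=[f"s{i}" for i in range(2 * n)],
            )
            table["tAge"] = table["delta_tAge"] + 50
            comp = clock.compare_tage_groups(table, "ref", equal_var=True)
            hits += comp["p"].iloc[0] < 0.05
        power = TTestIndPower().power(effect_size=abs(shift), nobs1=n, alpha=0.05)
        assert abs(hits / reps - power) < 0.10
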