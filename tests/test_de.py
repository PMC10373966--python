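import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epoch import de
from epoch.sim_counts import CountMatrix, SimCountConfig, simulate_counts


def brute_force_bh(p):
    """Literal step-up definition: adj_i = min_{k>=i} min(1, p_k * m / k)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj_sorted = np.empty(m)
    for rank0, idx in enumerate(order):
        candidates = [
            min(1.0, p[order[k]] * m / (k + 1)) for k in range(rank0, m)
        ]
        adj_sorted[rank0] = min(candidates)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def _matrix(arr, groups=None):
    arr = np.asarray(arr)
    samples = [f"s{i}" for i in range(arr.shape[1])]
    md = pd.DataFrame(
        {
            "group": groups or ["a"] * arr.shape[1],
            "age": np.nan,
            "library_size": arr.sum(axis=0),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    counts = pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])], columns=samples)
    return CountMatrix(counts=counts, sample_metadata=md)


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _matrix(np.tile([[10], [20], [7]], (1, 4)))
        assert np.allclose(de.size_factors(cm), 1.0)

    def test_known_two_sample_case(self):
        cm = _matrix([[10, 20], [30, 60]])
        np.testing.assert_allclose(
            de.size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_zero_containing_genes_excluded_from_reference(self):
        # the zero-containing row would otherwise drag the medians down
        cm = _matrix([[10, 20], [30, 60], [0, 1000]])
        np.testing.assert_allclose(
            de.size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_no_zero_free_gene_rejected(self):
        cm = _matrix([[0, 5], [3, 0]])
        with pytest.raises(ValueError):
            de.size_factors(cm)

    def test_scaling_one_sample_scales_relative_factors(self):
        """Tripling one sample's counts triples its factor relative to the
        others (the geometric-mean reference rescales all factors by a
        common constant, so only ratios are identified)."""
        base = np.array([[10, 20], [30, 60], [5, 9]])
        scaled = base.astype(float).copy()
        scaled[:, 1] *= 3.0
        f_base = de.size_factors(_matrix(base))
        f_scaled = de.size_factors(_matrix(scaled.astype(int)))
        ratio_base = f_base.iloc[1] / f_base.iloc[0]
        ratio_scaled = f_scaled.iloc[1] / f_scaled.iloc[0]
        assert ratio_scaled / ratio_base == pytest.approx(3.0, rel=1e-9)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.02], [0.02]),
            ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
            ([0.04, 0.5], [0.08, 0.5]),
        ],
    )
    def test_known_cases(self, p, expected):
        np.testing.assert_allclose(de.bh_adjust(p), expected, rtol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_matches_brute_force_definition(self, p):
        np.testing.assert_allclose(de.bh_adjust(p), brute_force_bh(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.2])


class TestDETest:
    def test_fourfold_change_gives_log2fc_two(self):
        rng = np.random.default_rng(1)
        base = np.tile(rng.integers(500, 2000, size=(50, 1)), (1, 8))
        arr = base.copy()
        arr[0, 4:] = base[0, 4:] * 4
        cm = _matrix(arr, groups=["a"] * 4 + ["b"] * 4)
        res = de.de_test(cm, "a", "b")
        assert res.table.loc["g0", "log2fc"] == pytest.approx(2.0, abs=0.1)

    def test_identical_groups_give_zero_log2fc(self):
        arr = np.tile(np.arange(1, 21)[:, None] * 10, (1, 6))
        cm = _matrix(arr, groups=["a"] * 3 + ["b"] * 3)
        res = de.de_test(cm, "a", "b")
        assert np.allclose(res.table["log2fc"], 0.0)
        assert np.allclose(res.table["p"], 1.0)

    def test_all_zero_genes_dropped(self):
        arr = np.vstack([np.full((3, 6), 50), np.zeros((1, 6), dtype=int)])
        cm = _matrix(arr, groups=["a"] * 3 + ["b"] * 3)
        res = de.de_test(cm, "a", "b")
        assert "g3" not in res.table.index

    def test_unknown_group_rejected(self, two_group_matrix):
        with pytest.raises(ValueError):
            de.de_test(two_group_matrix, "quiescent", "nonexistent")

    def test_welch_engine_available(self, two_group_matrix):
        res = de.de_test(two_group_matrix, "quiescent", "senescent", method="welch")
        assert ((res.table["p"] >= 0) & (res.table["p"] <= 1)).all()

    def test_padj_never_below_p(self, two_group_matrix):
        res = de.de_test(two_group_matrix, "quiescent", "senescent")
        assert (res.table["p_adj"] >= res.table["p"] - 1e-12).all()


class TestExtractSignature:
    @staticmethod
    def _de(rows):
        table = pd.DataFrame(rows).set_index("gene")
        table["base_mean"] = 100.0
        return de.DEResult(table=table, contrast="test")

    def test_threshold_boundaries(self):
        res = self._de(
            [
                {"gene": "in_up", "log2fc": 1.3, "p": 1e-4, "p_adj": 0.005},
                {"gene": "weak_p", "log2fc": 3.0, "p": 0.01, "p_adj": 0.02},
                {"gene": "weak_fc", "log2fc": 0.9, "p": 1e-4, "p_adj": 0.005},
                {"gene": "in_down", "log2fc": -2.0, "p": 1e-4, "p_adj": 0.004},
            ]
        )
        sig = de.extract_signature(res, p_adj_cutoff=0.01, fc_cutoff=2.0)
        assert sig.up_genes == ["in_up"]  # FC ~ 2.46 > 2
        assert sig.down_genes == ["in_down"]

    def test_up_and_down_disjoint(self, two_group_matrix):
        res = de.de_test(two_group_matrix, "quiescent", "senescent")
        sig = de.extract_signature(res)
        assert not set(sig.up_genes) & set(sig.down_genes)

    def test_signature_recovery_from_simulation(self):
        """Planted genes at log2fc 2.5, n=4/group are nearly all recovered."""
        recovered, false = [], []
        for seed in range(3):
            cfg = SimCountConfig(
                n_genes=2000, samples_per_group=4, senescence_log2fc=2.5, seed=seed
            )
            cm = simulate_counts(cfg)
            res = de.de_test(cm, "quiescent", "senescent")
            sig = de.extract_signature(res)
            truth = cm.truth["genes"]
            true_up = set(truth.index[truth["sen_direction"] == "up"])
            found = set(sig.up_genes)
            recovered.append(len(found & true_up))
            false.append(len(found - true_up))
        assert min(recovered) >= 80
        assert max(false) <= 5


class TestClassifyReversal:
    @staticmethod
    def _treatment_de(genes, n_reversed, direction_sign):
        rows = []
        for i, g in enumerate(genes):
            if i < n_reversed:
                rows.append({"gene": g, "log2fc": -direction_sign * 2.0, "p": 1e-6, "p_adj": 1e-5})
            else:
                rows.append({"gene": g, "log2fc": 0.05 * direction_sign, "p": 0.8, "p_adj": 0.9})
        table = pd.DataFrame(rows).set_index("gene")
        table["base_mean"] = 10.0
        return de.DEResult(table=table, contrast="treated_vs_senescent")

    def test_reported_percentages_at_printed_counts(self):
        """82 of 190 up genes reversed -> 43.2%; 213 of 326 down -> 65.3%."""
        up_genes = [f"u{i}" for i in range(190)]
        down_genes = [f"d{i}" for i in range(326)]
        sig = de.SenescenceSignature(
            up=pd.DataFrame({"log2fc": 2.5}, index=up_genes),
            down=pd.DataFrame({"log2fc": -2.5}, index=down_genes),
            p_adj_cutoff=0.01,
            fc_cutoff=2.0,
        )
        t_up = self._treatment_de(up_genes, 82, +1)
        t_down = self._treatment_de(down_genes, 213, -1)
        combined = de.DEResult(
            table=pd.concat([t_up.table, t_down.table]), contrast="treated_vs_senescent"
        )
        summary = de.classify_reversal(sig, combined, p_adj_cutoff=0.05)
        assert summary.reversed_pct("up") == 43.2
        assert summary.reversed_pct("down") == 65.3
        assert summary.table.loc["up", "reversed"] == 82
        assert summary.table.loc["down", "reversed"] == 213

    def test_no_treatment_effect_leaves_all_unchanged(self):
        genes = [f"u{i}" for i in range(10)]
        sig = de.SenescenceSignature(
            up=pd.DataFrame({"log2fc": 2.0}, index=genes),
            down=pd.DataFrame({"log2fc": []}, index=pd.Index([], dtype=object)),
            p_adj_cutoff=0.01,
            fc_cutoff=2.0,
        )
        table = pd.DataFrame(
            {"log2fc": 1.0, "p": 1.0, "p_adj": 1.0, "base_mean": 5.0}, index=genes
        )
        summary = de.classify_reversal(
            sig, de.DEResult(table=table, contrast="t"), p_adj_cutoff=0.05
        )
        assert summary.table.loc["up", "unchanged"] == 10
        assert summary.table.loc["up", "reversed"] == 0

    def test_classes_partition_signature(self, two_group_matrix):
        res = de.de_test(two_group_matrix, "quiescent", "senescent")
        sig = de.extract_signature(res, p_adj_cutoff=0.05)
        summary = de.classify_reversal(sig, res)  # any same-universe contrast
        t = summary.table
        assert (t["reversed"] + t["exacerbated"] + t["unchanged"] == t["total"]).all()

    def test_missing_gene_rejected(self):
        sig = de.SenescenceSignature(
            up=pd.DataFrame({"log2fc": 2.0}, index=["absent"]),
            down=pd.DataFrame({"log2fc": []}, index=pd.Index([], dtype=object)),
            p_adj_cutoff=0.01,
            fc_cutoff=2.0,
        )
        table = pd.DataFrame(
            {"log2fc": [0.1], "p": [0.5], "p_adj": [0.5], "base_mean": [1.0]},
            index=["other"],
        )
        with pytest.raises(KeyError):
            de.classify_reversal(sig, de.DEResult(table=table, contrast="t"))


def test_reversal_percentage_rounding():
    assert de.reversal_percentage(82, 190) == 43.2
    assert de.reversal_percentage(213, 326) == 65.3
    with pytest.raises(ValueError):
        de.reversal_percentage(5, 0)
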