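import numpy as np
import pytest

from atlas_scrub.coexpression import (
    correlate,
    differential_table,
    export_heatmap_data,
    one_vs_all,
)
from atlas_scrub.matrix_io import ExpressionMatrix
from atlas_scrub.synthdata import ModuleSpec, SampleSpec, SimConfig, simulate_matrix

from oracles import kendall_tau_b_brute, pearson_two_pass, spearman_brute


def _matrix(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"H{j}_1" for j in range(values.shape[1])]
    return ExpressionMatrix(
        probe_ids=[f"p{i}" for i in range(values.shape[0])],
        column_labels=labels,
        values=values,
    )


@pytest.fixture(scope="module")
def random_matrix():
    rng = np.random.default_rng(7)
    return _matrix(rng.lognormal(3.0, 1.0, (20, 30)))


class TestCorrelateAgainstBruteForce:
    def test_pearson_linear_within_1e12(self, random_matrix):
        m = random_matrix
        table = correlate(m, m.probe_ids, method="pearson", scale="linear")
        for i in range(m.n_probes):
            for j in range(0, m.n_probes, 3):
                expected = pearson_two_pass(m.values[i], m.values[j])
                assert table.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_pearson_log_within_1e12(self, random_matrix):
        m = random_matrix
        table = correlate(m, m.probe_ids, method="pearson", scale="log")
        logged = np.log2(m.values + 1.0)
        for i in range(0, m.n_probes, 2):
            for j in range(0, m.n_probes, 5):
                expected = pearson_two_pass(logged[i], logged[j])
                assert table.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_spearman_within_1e12(self, random_matrix):
        m = random_matrix
        table = correlate(m, m.probe_ids, method="spearman")
        for i in range(0, m.n_probes, 2):
            for j in range(0, m.n_probes, 5):
                expected = spearman_brute(m.values[i], m.values[j])
                assert table.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_kendall_within_1e12(self):
        rng = np.random.default_rng(8)
        m = _matrix(np.round(rng.lognormal(3, 1, (6, 15)), 1))  # force ties
        table = correlate(m, m.probe_ids, method="kendall")
        for i in range(6):
            for j in range(6):
                expected = kendall_tau_b_brute(m.values[i], m.values[j])
                assert table.values[i, j] == pytest.approx(expected, abs=1e-12)


class TestClosedFormExamples:
    def test_probe_against_itself_is_one_for_all_methods(self, random_matrix):
        for method in ("pearson", "spearman", "kendall"):
            t = correlate(random_matrix, ["p3"], ["p3"], method=method)
            assert t.values[0, 0] == pytest.approx(1.0)

    def test_spearman_and_kendall_hand_values(self):
        m = _matrix(np.array([[1, 2, 3, 4, 5], [3, 1, 2, 5, 4]], dtype=float))
        s = correlate(m, ["p0"], ["p1"], method="spearman")
        k = correlate(m, ["p0"], ["p1"], method="kendall")
        assert s.values[0, 0] == pytest.approx(0.6)
        assert k.values[0, 0] == pytest.approx(0.4)

    def test_rank_methods_invariant_under_exp(self):
        x = np.linspace(0.0, 5.0, 12)
        m = _matrix(np.vstack([x, np.exp(x)]))
        s = correlate(m, ["p0"], ["p1"], method="spearman").values[0, 0]
        p = correlate(m, ["p0"], ["p1"], method="pearson").values[0, 0]
        assert s == pytest.approx(1.0)
        assert p < 1.0


class TestInvariances:
    def test_pearson_affine_invariance(self, random_matrix):
        m = random_matrix
        base = correlate(m, ["p0"], ["p1"]).values[0, 0]
        shifted = _matrix(
            np.vstack([3.5 * m.values[0] + 11.0, m.values[1]])
        )
        assert correlate(shifted, ["p0"], ["p1"]).values[0, 0] == pytest.approx(
            base, abs=1e-12
        )

    def test_log_pearson_base_invariance(self, random_matrix):
        m = random_matrix
        via_log2 = correlate(m, ["p0"], ["p1"], scale="log").values[0, 0]
        # same pseudocount, base 10: differs from log2 by a positive scalar
        log10 = _matrix(np.log10(m.values[:2] + 1.0))
        assert correlate(log10, ["p0"], ["p1"]).values[0, 0] == pytest.approx(
            via_log2, abs=1e-12
        )

    def test_rank_methods_invariant_under_monotone_transform(self, random_matrix):
        m = random_matrix
        warped = _matrix(np.vstack([m.values[0] ** 3, np.sqrt(m.values[1])]))
        for method in ("spearman", "kendall"):
            orig = correlate(m, ["p0"], ["p1"], method=method).values[0, 0]
            new = correlate(warped, ["p0"], ["p1"], method=method).values[0, 0]
            assert new == pytest.approx(orig, abs=1e-12)


class TestEdgeCases:
    def test_fewer_than_three_columns_is_an_error(self):
        m = _matrix(np.ones((2, 2)))
        with pytest.raises(ValueError, match=">= 3"):
            correlate(m, ["p0"], ["p1"])

    def test_zero_variance_probe_reports_nan_not_zero(self):
        m = _matrix(np.vstack([np.ones(5), np.arange(5.0)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            t = correlate(m, ["p0"], ["p1"])
        assert np.isnan(t.values[0, 0])

    def test_unknown_probe_is_an_error(self, random_matrix):
        with pytest.raises(KeyError):
            correlate(random_matrix, ["nope"])


class TestOneVsAll:
    def test_planted_module_members_rank_at_top(self):
        config = SimConfig(
            samples=[SampleSpec(f"S{i:02d}", 2) for i in range(15)],
            n_probes=200,
            modules=[ModuleSpec("mod", 10, loading=0.9, idio_sd=0.25)],
        )
        matrix, truth = simulate_matrix(config, seed=21, with_means=False)
        members = [p for p, m in truth.module_of_probe.items() if m == "mod"]
        ranking = one_vs_all(matrix, members[0], method="pearson", scale="log")
        top20 = {p for p, _ in ranking.top(20)}
        assert set(members[1:]) <= top20

    def test_duplicated_probe_ranks_first_with_r_one(self, random_matrix):
        m = random_matrix
        vals = np.vstack([m.values, m.values[4]])
        dup = ExpressionMatrix(
            probe_ids=[*m.probe_ids, "p4_copy"],
            column_labels=list(m.column_labels),
            values=vals,
        )
        ranking = one_vs_all(dup, "p4")
        probe, r = ranking.top(1)[0]
        assert probe == "p4_copy"
        assert r == pytest.approx(1.0)

    def test_query_excluded_and_order_deterministic(self, random_matrix):
        ranking = one_vs_all(random_matrix, "p0")
        assert "p0" not in ranking.probes
        assert len(ranking.probes) == random_matrix.n_probes - 1
        rs = ranking.r
        assert np.all(np.diff(rs) <= 1e-15)  # non-increasing

    def test_independent_noise_yields_no_strong_correlators(self):
        rng = np.random.default_rng(33)
        m = _matrix(rng.lognormal(3, 1, (40, 200)))
        ranking = one_vs_all(m, "p0")
        assert abs(ranking.r[0]) < 0.5


class TestDifferentialTable:
    def test_identical_inputs_give_zeros(self, random_matrix):
        t = correlate(random_matrix, ["p0", "p1", "p2"])
        d = differential_table(t, t)
        np.testing.assert_allclose(d.values, 0.0)
        assert d.mean_difference == 0.0

    def test_hand_built_two_by_two(self):
        t1 = correlate(
            _matrix([[1, 2, 3.0], [1, 2, 4.0]]), ["p0", "p1"]
        )
        t2 = correlate(
            _matrix([[1, 2, 3.0], [3, 2, 1.0]]), ["p0", "p1"]
        )
        d = differential_table(t1, t2)
        expected = t1.values - t2.values
        np.testing.assert_allclose(d.values, expected)
        off = [expected[0, 1], expected[1, 0]]
        assert d.mean_difference == pytest.approx(np.mean(off))

    def test_axis_mismatch_is_an_error(self, random_matrix):
        a = correlate(random_matrix, ["p0", "p1"])
        b = correlate(random_matrix, ["p0", "p2"])
        with pytest.raises(ValueError, match="axes"):
            differential_table(a, b)

    def test_cleaning_artifact_columns_lowers_log_pearson(self):
        """Removing a block of low-sum artifact columns (which inflate every
        log-scale correlation by acting as shared leverage points) must drop
        the mean log-Pearson over a gene list."""
        from atlas_scrub.cleaner import CleaningConfig, clean
        from atlas_scrub.synthdata import (
            DefectSpec,
            LowSumPlant,
            scaled_sum_threshold,
        )

        samples = [SampleSpec(f"S{i:02d}", 2) for i in range(12)] + [
            SampleSpec("Artifact", 3)
        ]
        config = SimConfig(samples=samples, n_probes=300)
        defects = DefectSpec(low_sum=[LowSumPlant("Artifact", log_base=2.0)])
        matrix, _ = simulate_matrix(config, defects, seed=13, with_means=False)
        cleaned, _ = clean(
            matrix,
            config=CleaningConfig(sum_min=scaled_sum_threshold(300)),
        )
        probes = matrix.probe_ids[:25]
        before = correlate(matrix, probes, method="pearson", scale="log")
        after = correlate(cleaned, probes, method="pearson", scale="log")
        d = differential_table(after, before)
        assert d.mean_difference < 0


class TestHeatmapExport:
    def test_round_trip_and_size(self, tmp_path, random_matrix):
        probes = random_matrix.probe_ids  # 20x20; also check a 54-ish table
        table = correlate(random_matrix, probes)
        out = tmp_path / "table.tsv"
        export_heatmap_data(table, out)
        import pandas as pd

        back = pd.read_csv(out, sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), table.values, atol=1e-12)
        assert list(back.index) == probes

    def test_54_probe_table_exports_untruncated(self, tmp_path):
        rng = np.random.default_rng(5)
        m = _matrix(rng.lognormal(3, 1, (54, 10)))
        table = correlate(m, m.probe_ids)
        out = tmp_path / "sap.tsv"
        export_heatmap_data(table, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 55  # header + 54 rows

    def test_non_square_table_is_an_error(self, tmp_path, random_matrix):
        t = correlate(random_matrix, ["p0"], ["p1", "p2"])
        with pytest.raises(ValueError, match="square"):
            export_heatmap_data(t, tmp_path / "x.tsv")
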