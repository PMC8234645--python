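import numpy as np
import pytest

from atlas_scrub.cleaner import CleaningConfig, clean, resolve_replicate_rule
from atlas_scrub.matrix_io import ExpressionMatrix
from atlas_scrub.synthdata import (
    BadReplicatePlant,
    DefectSpec,
    LowSumPlant,
    SampleSpec,
    SimConfig,
    scaled_sum_threshold,
    simulate_matrix,
)

from oracles import replicate_rule_oracle


def _pairs(members, rs):
    """Map sorted member pairs to the given correlation values."""
    from itertools import combinations

    keys = [tuple(sorted(p)) for p in combinations(members, 2)]
    return dict(zip(keys, rs))


class TestReplicateRule:
    def test_three_reps_one_failing_pair_keeps_best_pair(self):
        kept, dropped = resolve_replicate_rule(
            [1, 2, 3], _pairs([1, 2, 3], [0.95, 0.92, 0.85]), 0.90
        )
        assert (kept, dropped) == ([1, 2], [3])

    def test_two_reps_below_threshold_drops_both(self):
        kept, dropped = resolve_replicate_rule([0, 1], {(0, 1): 0.80}, 0.90)
        assert (kept, dropped) == ([], [0, 1])

    def test_three_reps_all_passing_keeps_all(self):
        kept, dropped = resolve_replicate_rule(
            [0, 1, 2], _pairs([0, 1, 2], [0.96, 0.95, 0.97]), 0.90
        )
        assert (kept, dropped) == ([0, 1, 2], [])

    def test_three_reps_single_passing_pair_kept(self):
        kept, dropped = resolve_replicate_rule(
            [0, 1, 2], _pairs([0, 1, 2], [0.91, 0.40, 0.35]), 0.90
        )
        assert (kept, dropped) == ([0, 1], [2])

    def test_nan_counts_as_below_threshold(self):
        kept, dropped = resolve_replicate_rule(
            [0, 1], {(0, 1): float("nan")}, 0.90
        )
        assert kept == []

    def test_truth_table_matches_oracle_over_random_configs(self):
        """Exhaustive randomized check of the four cases at n=2 and n=3."""
        rng = np.random.default_rng(42)
        for _ in range(2000):
            n = int(rng.integers(2, 4))
            members = list(range(10, 10 + n))
            rs = rng.uniform(-0.2, 1.0, size=n * (n - 1) // 2)
            pair_r = _pairs(members, rs)
            assert resolve_replicate_rule(
                members, pair_r, 0.90
            ) == replicate_rule_oracle(members, pair_r, 0.90)

    def test_tie_break_prefers_lowest_indices(self):
        kept, _ = resolve_replicate_rule(
            [0, 1, 2], _pairs([0, 1, 2], [0.95, 0.95, 0.5]), 0.90
        )
        assert kept == [0, 1]

    def test_generalisation_beyond_three_drops_worst_member(self):
        # member 3 is discordant with everyone; the rest agree
        pair_r = {
            (0, 1): 0.96, (0, 2): 0.95, (1, 2): 0.97,
            (0, 3): 0.2, (1, 3): 0.3, (2, 3): 0.1,
        }
        kept, dropped = resolve_replicate_rule([0, 1, 2, 3], pair_r, 0.90)
        assert (kept, dropped) == ([0, 1, 2], [3])

    def test_generalisation_all_discordant_drops_all(self):
        pair_r = {
            (0, 1): 0.2, (0, 2): 0.1, (1, 2): 0.3,
            (0, 3): 0.2, (1, 3): 0.3, (2, 3): 0.1,
        }
        kept, dropped = resolve_replicate_rule([0, 1, 2, 3], pair_r, 0.90)
        assert kept == []
        assert dropped == [0, 1, 2, 3]

    def test_requires_two_members(self):
        with pytest.raises(ValueError):
            resolve_replicate_rule([0], {}, 0.9)


def _sim(samples, defects=None, seed=0, n_probes=500):
    config = SimConfig(samples=samples, n_probes=n_probes)
    matrix, truth = simulate_matrix(config, defects, seed=seed, with_means=False)
    cfg = CleaningConfig(sum_min=scaled_sum_threshold(n_probes))
    return matrix, truth, cfg


class TestClean:
    def test_defect_free_matrix_is_untouched(self):
        matrix, _, cfg = _sim([SampleSpec(f"S{i}", 3) for i in range(5)])
        cleaned, ledger = clean(matrix, config=cfg)
        assert ledger.entries == []
        assert cleaned.column_labels == matrix.column_labels
        np.testing.assert_array_equal(cleaned.values, matrix.values)

    def test_ledger_partitions_columns(self):
        matrix, _, cfg = _sim(
            [SampleSpec(f"S{i}", 3) for i in range(4)]
            + [SampleSpec("Solo", 1), SampleSpec("Dark", 3)],
            DefectSpec(
                low_sum=[LowSumPlant("Dark", factor=0.02)],
                bad_replicates=[BadReplicatePlant("S0", 1)],
            ),
        )
        cleaned, ledger = clean(matrix, config=cfg)
        removed = set(ledger.removed_indices)
        kept = set(ledger.kept_indices)
        assert removed | kept == set(range(matrix.n_columns))
        assert removed & kept == set()
        assert len(ledger.entries) == len(removed)  # one category per column

    def test_categories_assigned_as_planted(self):
        matrix, truth, cfg = _sim(
            [SampleSpec(f"S{i}", 3) for i in range(4)]
            + [SampleSpec("Solo", 1), SampleSpec("Dark", 3)],
            DefectSpec(
                low_sum=[LowSumPlant("Dark", log_base=2.0)],
                bad_replicates=[BadReplicatePlant("S0", 1)],
            ),
        )
        _, ledger = clean(matrix, config=cfg)
        assert ledger.counts["low_sum"] == 3
        assert ledger.counts["singleton"] == 1
        assert ledger.counts["low_correlation_replicate"] == 1
        by_cat = {
            c: {e.column_label for e in ledger.entries if e.category == c}
            for c in ("low_sum", "singleton")
        }
        assert by_cat["low_sum"] == {"Dark_1", "Dark_2", "Dark_3"}
        assert by_cat["singleton"] == {"Solo"}

    def test_low_sum_singleton_is_charged_to_low_sum(self):
        # priority order: the whole-group low-sum rule fires before the
        # singleton rule, so a low-sum singleton is categorised low_sum
        matrix, _, cfg = _sim(
            [SampleSpec("S", 2), SampleSpec("DimSolo", 1)],
            DefectSpec(low_sum=[LowSumPlant("DimSolo", factor=0.01)]),
        )
        _, ledger = clean(matrix, config=cfg)
        (entry,) = [e for e in ledger.entries if e.column_label == "DimSolo"]
        assert entry.category == "low_sum"

    def test_duplicate_name_repair_keeps_first_block(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(5, 0.5, (50, 4))
        vals[:, 1] = vals[:, 0] * 1.01  # high-r sibling, not identical
        vals[:, 3] = vals[:, 2] * 1.01
        matrix = ExpressionMatrix(
            probe_ids=[f"p{i}" for i in range(50)],
            column_labels=["N_1", "N_2", "N_1", "N_2"],
            values=vals,
        )
        cleaned, ledger = clean(matrix, config=CleaningConfig(sum_min=1.0))
        assert ledger.counts["duplicate_name"] == 2
        assert [e.column_index for e in ledger.entries] == [2, 3]

    def test_clean_is_idempotent(self):
        matrix, _, cfg = _sim(
            [SampleSpec(f"S{i}", 3) for i in range(6)] + [SampleSpec("Solo", 1)],
            DefectSpec(bad_replicates=[BadReplicatePlant("S1", 3)]),
            seed=9,
        )
        once, ledger1 = clean(matrix, config=cfg)
        twice, ledger2 = clean(once, config=cfg)
        assert ledger2.entries == []
        assert twice.column_labels == once.column_labels

    def test_raising_r_min_never_removes_fewer_columns(self):
        matrix, _, cfg = _sim(
            [SampleSpec(f"S{i}", 3) for i in range(8)],
            DefectSpec(bad_replicates=[BadReplicatePlant("S2", 1)]),
            seed=3,
        )
        import warnings

        removed = []
        for r_min in (0.2, 0.9, 0.995, 0.9999):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                _, ledger = clean(
                    matrix,
                    config=CleaningConfig(r_min=r_min, sum_min=cfg.sum_min),
                )
            removed.append(ledger.n_removed)
        assert removed == sorted(removed)

    def test_all_columns_removed_warns_but_returns(self):
        matrix, _, _ = _sim([SampleSpec("S", 2)])
        with pytest.warns(UserWarning, match="every column"):
            cleaned, ledger = clean(
                matrix, config=CleaningConfig(r_min=1.0, sum_min=1.0)
            )
        assert cleaned.n_columns == 0
        assert ledger.n_removed == 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CleaningConfig(r_min=1.5)
        with pytest.raises(ValueError):
            CleaningConfig(sum_min=0)
        with pytest.raises(ValueError):
            CleaningConfig(duplicate_policy="maybe")
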