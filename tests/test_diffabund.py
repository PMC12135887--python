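"""Bootstrap median fold-change machinery: pair construction, resampling
against the exhaustive enumeration oracle, percentile/FCR intervals, and the
multiple-testing adjustments against an independent reference."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from tmtboot import (
    Effect,
    SimulationConfig,
    between_group_pairs,
    bh_adjust,
    bootstrap_ci_table,
    bootstrap_medians,
    by_adjust,
    fcr_adjust,
    percentile_ci,
    simulate_cohort,
    timepoint_log2,
    within_group_mean_test,
    within_subject_log2fc,
)
from tmtboot.diffabund import PairFoldChanges


def enumeration_median_distribution(values, k):
    """Exact distribution of the median of k draws-with-replacement."""
    values = np.asarray(values, dtype=float)
    counts = {}
    for combo in itertools.product(range(len(values)), repeat=k):
        med = float(np.median(values[list(combo)]))
        counts[med] = counts.get(med, 0) + 1
    total = len(values) ** k
    return {m: c / total for m, c in sorted(counts.items())}


class TestPairs:
    def test_pair_counts_default_design(self, small_cohort):
        matrix, meta, design, _, _ = small_cohort
        vals = timepoint_log2(matrix, meta, "T0")
        pairs = between_group_pairs(vals.iloc[0], meta, design, "p", "T0")
        assert sorted(len(v) for v in pairs.by_block.values()) == [6, 6, 9, 9]
        assert len(pairs.all_values) == 30
        assert sorted(pairs.k_by_block.values()) == [2, 2, 3, 3]

    def test_constant_block_gives_zeros(self, small_cohort):
        _, meta, design, _, _ = small_cohort
        subjects = {m.subject_id for m in meta}
        vals = pd.Series(1.7, index=sorted(subjects))
        pairs = between_group_pairs(vals, meta, design)
        assert np.allclose(pairs.all_values, 0.0)

    def test_shifted_cases_give_unit_differences(self, small_cohort):
        _, meta, design, _, _ = small_cohort
        subjects = sorted({m.subject_id for m in meta})
        vals = pd.Series([1.0 if s.startswith("case") else 0.0 for s in subjects],
                         index=subjects)
        pairs = between_group_pairs(vals, meta, design)
        assert np.allclose(pairs.all_values, 1.0)


class TestBootstrapMedians:
    def test_constant_input_constant_medians(self):
        pairs = PairFoldChanges("p", "T0", {"B1": np.full(9, 2.5)}, {"B1": 3})
        med = bootstrap_medians(pairs, 500, seed=0)
        assert np.all(med == 2.5)

    def test_matches_exhaustive_enumeration(self):
        values = np.arange(1.0, 10.0)
        exact = enumeration_median_distribution(values, k=3)
        pairs = PairFoldChanges("p", "T0", {"B1": values}, {"B1": 3})
        B = 10_000
        med = bootstrap_medians(pairs, B, seed=42)
        for m, p_exact in exact.items():
            p_emp = np.mean(med == m)
            se = np.sqrt(p_exact * (1 - p_exact) / B)
            assert abs(p_emp - p_exact) < 3.5 * se + 1e-12, f"median {m}"

    def test_negation_antisymmetry_same_seed(self):
        values = np.linspace(-2, 3, 9)
        p1 = PairFoldChanges("p", "T0", {"B1": values}, {"B1": 3})
        p2 = PairFoldChanges("p", "T0", {"B1": -values}, {"B1": 3})
        m1 = bootstrap_medians(p1, 1000, seed=5)
        m2 = bootstrap_medians(p2, 1000, seed=5)
        assert np.array_equal(m1, -m2)

    def test_group_swap_mirrors_results(self):
        # swapping case/control labels in an all-3:3 design negates the
        # medians bitwise (same seed stream)
        cfg = SimulationConfig(n_proteins=6, blocks=((3, 3), (3, 3)))
        matrix, meta, design, _, _ = simulate_cohort(cfg, seed=11)
        vals = timepoint_log2(matrix, meta, "T15m")
        from dataclasses import replace
        from tmtboot.types import Block, BlockDesign, Group, Plex
        swapped_meta = [
            replace(m, group=Group.control if m.group is Group.case else Group.case)
            for m in meta
        ]
        swapped_design = BlockDesign(
            [Plex(p.plex_id,
                  Group.control if p.group is Group.case else Group.case,
                  p.reference_channel) for p in design.plexes],
            [Block(b.block_id, b.control_plex_id, b.case_plex_id)
             for b in design.blocks],
        )
        for pid in matrix.protein_ids:
            a = bootstrap_medians(
                between_group_pairs(vals.loc[pid], meta, design, pid), 200, seed=3)
            b = bootstrap_medians(
                between_group_pairs(vals.loc[pid], swapped_meta, swapped_design, pid),
                200, seed=3)
            assert np.array_equal(a, -b)

    def test_empty_group_in_block_errors(self, small_cohort):
        _, meta, design, _, _ = small_cohort
        ctrl_only = pd.Series(
            {m.subject_id: 0.0 for m in meta if m.subject_id.startswith("ctrl")}
        )
        with pytest.raises(ValueError, match="block"):
            between_group_pairs(ctrl_only, meta, design)


class TestPercentileCI:
    def test_constant_vector(self):
        assert percentile_ci(np.full(100, 3.0)) == (3.0, 3.0)

    def test_nearest_rank_on_1_to_1000(self):
        lo, hi = percentile_ci(np.arange(1, 1001, dtype=float), 0.95)
        assert (lo, hi) == (25.0, 975.0)

    @pytest.mark.parametrize("level_pair", [(0.8, 0.9), (0.9, 0.95), (0.95, 0.99)])
    def test_wider_level_nests(self, rng, level_pair):
        x = rng.normal(size=501)
        narrow = percentile_ci(x, level_pair[0])
        wide = percentile_ci(x, level_pair[1])
        assert wide[0] <= narrow[0] and narrow[1] <= wide[1]


class TestFcrAdjust:
    def test_adjusted_level_formula(self, rng):
        # 2 of 10 nominal CIs exclude 0 -> adjusted level 0.98
        boots = [rng.normal(0, 1, 2000) for _ in range(8)]
        boots += [rng.normal(6, 1, 2000), rng.normal(-6, 1, 2000)]
        from tmtboot.diffabund import BootstrapCIResult
        results = []
        for i, b in enumerate(boots):
            lo, hi = percentile_ci(b, 0.95)
            results.append(BootstrapCIResult(
                protein_id=f"P{i}", contrast="T0",
                median_log2fc=float(np.median(b)), ci_nominal=(lo, hi),
                ci_adjusted=(lo, hi), significant=False, B=2000,
                ci_level=0.95, fcr_q=0.1, boot_medians=b,
            ))
        out = fcr_adjust(results, q=0.1)
        for r in out:
            expect = percentile_ci(r.boot_medians, 1 - 2 * 0.1 / 10)
            assert r.ci_adjusted == expect
            # adjusted CI contains the nominal one
            assert r.ci_adjusted[0] <= r.ci_nominal[0]
            assert r.ci_nominal[1] <= r.ci_adjusted[1]
        assert sum(r.significant for r in out) == 2

    def test_nothing_selected_keeps_nominal(self, rng):
        from tmtboot.diffabund import BootstrapCIResult
        results = [
            BootstrapCIResult(
                protein_id=f"P{i}", contrast="T0", median_log2fc=0.0,
                ci_nominal=(-1.0, 1.0), ci_adjusted=(0.0, 0.0),
                significant=True, B=100, ci_level=0.95, fcr_q=0.1,
                boot_medians=rng.normal(size=100),
            )
            for i in range(5)
        ]
        out = fcr_adjust(results, q=0.1)
        assert all(not r.significant for r in out)
        assert all(r.ci_adjusted == r.ci_nominal for r in out)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError, match="q"):
            fcr_adjust([], q=1.5)


class TestWithinGroupTest:
    def test_textbook_t_statistic(self, small_cohort):
        _, meta, design, _, _ = small_cohort
        from scipy import stats as ss
        x = np.array([0.8, 1.2, 1.0, 1.4, 0.6])
        cases = sorted({m.subject_id for m in meta if m.subject_id.startswith("case")})
        fc = pd.DataFrame({s: [v] for s, v in zip(cases[:5], x)}, index=["P1"])
        res = within_group_mean_test(fc, meta, "case")[0]
        t_expected = x.mean() / (x.std(ddof=1) / np.sqrt(5))
        p_expected = 2 * ss.t.sf(abs(t_expected), df=4)
        assert res.t_stat == pytest.approx(t_expected)
        assert res.p == pytest.approx(p_expected)

    def test_all_zero_fcs_give_p_one_flagged(self, small_cohort):
        _, meta, _, _, _ = small_cohort
        cases = sorted({m.subject_id for m in meta if m.subject_id.startswith("case")})
        fc = pd.DataFrame({s: [0.0] for s in cases}, index=["P1"])
        res = within_group_mean_test(fc, meta, "case")[0]
        assert res.p == 1.0
        assert res.degenerate

    def test_zero_variance_nonzero_mean_flagged(self, small_cohort):
        _, meta, _, _, _ = small_cohort
        cases = sorted({m.subject_id for m in meta if m.subject_id.startswith("case")})
        fc = pd.DataFrame({s: [1.0] for s in cases}, index=["P1"])
        res = within_group_mean_test(fc, meta, "case")[0]
        assert res.p == 0.0
        assert res.degenerate


class TestMultipleTesting:
    def test_bh_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_by_hand_example(self):
        q = by_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04 * (1 + 1 / 2 + 1 / 3 + 1 / 4))

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])
        assert by_adjust([0.37]) == pytest.approx([0.37])

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_statsmodels(self, trial):
        rng = np.random.default_rng(100 + trial)
        p = rng.uniform(size=rng.integers(2, 60))
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])
        assert np.allclose(by_adjust(p), multipletests(p, method="fdr_by")[1])

    def test_order_equivariance(self, rng):
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_by_dominates_bh(self, rng):
        p = rng.uniform(size=40)
        assert np.all(by_adjust(p) >= bh_adjust(p) - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestAdjustmentProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_step_up_bounds_and_reference(self, p):
        p = np.asarray(p)
        q_bh = bh_adjust(p)
        q_by = by_adjust(p)
        assert np.all(q_bh >= p - 1e-12) and np.all(q_bh <= 1)
        assert np.all(q_by >= q_bh - 1e-12)
        assert np.allclose(q_bh, multipletests(p, method="fdr_bh")[1])


class TestEndToEndInference:
    def test_planted_effect_detected_null_mostly_not(self):
        effects = tuple(Effect(f"PROT{i:04d}", "T15m", 1.0) for i in range(1, 6))
        cfg = SimulationConfig(n_proteins=60, effects=effects)
        matrix, meta, design, _, truth = simulate_cohort(cfg, seed=21)
        vals = timepoint_log2(matrix, meta, "T15m")
        pairs = [between_group_pairs(vals.loc[p], meta, design, p, "T15m")
                 for p in vals.index]
        res = bootstrap_ci_table(pairs, B=2000, seed=21)
        sig = {r.protein_id for r in res if r.significant}
        planted = set(truth.planted_proteins())
        assert len(sig & planted) >= 4
        assert len(sig - planted) <= 3
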