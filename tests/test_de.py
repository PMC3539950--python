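"""Pooled all-pairs and paired differential expression, BH step-up FDR,
conjunctive fold filters, and catalogue classification."""

import numpy as np
import pandas as pd
import pytest

from probestat.de import (
    all_pairs_comparisons,
    classify_catalog,
    compare_chips,
    conjunctive_fold_filter,
    fdr_step_up,
    paired_de,
    pooled_de,
)
from probestat.types import DEParamsPooled

from conftest import analyzed, matrix_from_arrays


def _detection_table(genes, call="Present", p=0.001):
    return pd.DataFrame({
        "gene_id": list(genes),
        "p_detect": [p] * len(genes),
        "call": [call] * len(genes),
    })


class TestCompareChips:
    def test_identical_chips_null(self, small_pair):
        genes, control, _ = small_pair
        a = analyzed("t", control)
        b = analyzed("c", control)
        res = compare_chips(a, b)
        np.testing.assert_allclose(res["fold"], 1.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_uniform_doubling(self, small_pair):
        """Treatment = 2x control (normalization bypassed): fold exactly
        2, p at the two-sided exact minimum for that probe count."""
        genes, control, treatment = small_pair
        res = compare_chips(analyzed("t", treatment), analyzed("c", control))
        np.testing.assert_allclose(res["fold"], 2.0, rtol=1e-9)
        n = 8
        np.testing.assert_allclose(res["p"], 2.0 * 0.5**n)

    def test_fold_invariant_to_probe_relabelling(self, rng):
        genes = ["g0"]
        for _ in range(20):
            pm = rng.uniform(300, 3000, size=(1, 12))
            mm = rng.uniform(50, 200, size=(1, 12))
            pm2 = rng.uniform(300, 3000, size=(1, 12))
            mm2 = rng.uniform(50, 200, size=(1, 12))
            perm = rng.permutation(12)
            base = compare_chips(
                analyzed("t", matrix_from_arrays(genes, pm, mm)),
                analyzed("c", matrix_from_arrays(genes, pm2, mm2)),
            )
            shuffled = compare_chips(
                analyzed("t", matrix_from_arrays(genes, pm[:, perm], mm[:, perm])),
                analyzed("c", matrix_from_arrays(genes, pm2[:, perm], mm2[:, perm])),
            )
            assert base["fold"].iloc[0] == pytest.approx(shuffled["fold"].iloc[0])

    def test_design_mismatch_rejected(self, small_pair, rng):
        genes, control, _ = small_pair
        other = matrix_from_arrays(["x"], rng.uniform(100, 500, (1, 8)),
                                   rng.uniform(100, 500, (1, 8)))
        with pytest.raises(ValueError):
            compare_chips(analyzed("t", control), analyzed("c", other))


class TestAllPairs:
    @pytest.mark.parametrize("n_t,n_c", [(3, 3), (2, 3), (2, 2)])
    def test_grid_sizes(self, small_pair, n_t, n_c):
        genes, control, treatment = small_pair
        t = [analyzed(f"t{i}", treatment) for i in range(n_t)]
        c = [analyzed(f"c{i}", control) for i in range(n_c)]
        grid = all_pairs_comparisons(t, c)
        assert grid.n_cells == n_t * n_c
        assert grid.folds.shape == (len(genes), n_t * n_c)

    def test_empty_side_rejected(self, small_pair):
        genes, control, _ = small_pair
        with pytest.raises(ValueError):
            all_pairs_comparisons([], [analyzed("c", control)])


class TestConjunctiveFoldFilter:
    def test_rule_examples(self):
        assert conjunctive_fold_filter([0.60, 0.62, 0.58], 1.5) is True
        assert conjunctive_fold_filter([0.60, 0.65, 0.70], 1.5) is False
        assert conjunctive_fold_filter([1.6, 0.5], 1.5) is False
        # magnitude-only mode accepts mixed directions
        assert conjunctive_fold_filter(
            [1.6, 0.5], 1.5, require_direction_consistency=False
        ) is True

    def test_matches_brute_force_on_random_grids(self, rng):
        def brute(folds, thr, consistent):
            if consistent:
                return all(f >= thr for f in folds) or \
                    all(f <= 1 / thr for f in folds)
            return all(abs(np.log2(f)) >= np.log2(thr) for f in folds)

        for _ in range(200):
            folds = np.exp(rng.normal(0, 0.5, size=rng.integers(1, 10)))
            thr = rng.uniform(1.0, 2.5)
            for consistent in (True, False):
                assert conjunctive_fold_filter(folds, thr, consistent) == \
                    brute(folds, thr, consistent)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            conjunctive_fold_filter([0.5, -1.0], 1.5)
        with pytest.raises(ValueError):
            conjunctive_fold_filter([0.5], 0.8)


class TestFdrStepUp:
    def test_enumerated_example(self):
        out = fdr_step_up(np.array([0.001, 0.01, 0.02, 0.8]), q=0.05)
        assert out["passes_fdr"].tolist() == [True, True, True, False]
        np.testing.assert_allclose(out["fdr_threshold"],
                                   [0.0125, 0.025, 0.0375, 0.05])

    def test_degenerate_cases(self):
        assert not fdr_step_up(np.ones(5), q=0.05)["passes_fdr"].any()
        assert fdr_step_up(np.array([0.04]), q=0.05)["passes_fdr"].all()

    def test_ties_share_better_outcome(self):
        p = np.array([0.01, 0.01, 0.9, 0.9])
        out = fdr_step_up(p, q=0.05)
        assert out["passes_fdr"].tolist() == [True, True, False, False]

    def test_matches_brute_force_oracle(self, rng):
        """Independent step-up enumeration on 500 random p-vectors."""
        def brute(p, q):
            m = len(p)
            order = np.argsort(p)
            k = 0
            for i in range(1, m + 1):
                if p[order[i - 1]] <= i / m * q:
                    k = i
            passes = np.zeros(m, dtype=bool)
            if k:
                passes[order[:k]] = True
                # ties with the critical p also pass
                passes |= p <= p[order[k - 1]]
            return passes

        for _ in range(500):
            m = int(rng.integers(1, 51))
            p = rng.uniform(1e-6, 1.0, size=m)
            q = rng.uniform(0.01, 0.2)
            np.testing.assert_array_equal(
                fdr_step_up(p, q)["passes_fdr"].to_numpy(), brute(p, q)
            )

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=40)
            ours = fdr_step_up(p, 0.05)["passes_fdr"].to_numpy()
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, ref)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fdr_step_up(np.array([0.0, 0.5]), 0.05)
        with pytest.raises(ValueError):
            fdr_step_up(np.array([]), 0.05)


class TestPooledDE:
    def _grid_and_detections(self, small_pair, fold_value):
        genes, control, treatment = small_pair
        t = [analyzed(f"t{i}", treatment, condition="inactive") for i in range(3)]
        c = [analyzed(f"c{i}", control) for i in range(3)]
        grid = all_pairs_comparisons(t, c)
        detections = {
            a.chip_id: _detection_table(sorted(genes)) for a in t + c
        }
        return genes, grid, detections

    def test_strong_uniform_effect_is_de(self, small_pair):
        """2x everywhere with minimal p in all 9 cells passes every
        filter."""
        genes, grid, detections = self._grid_and_detections(small_pair, 2.0)
        out = pooled_de(grid, detections)
        assert out["differentially_expressed"].all()
        assert out["passes_fold_all"].all()
        assert out["passes_fdr"].all()
        np.testing.assert_allclose(out["mean_fold"], 2.0, rtol=1e-9)

    def test_absent_everywhere_blocks_de(self, small_pair):
        genes, grid, _ = self._grid_and_detections(small_pair, 2.0)
        absent = {
            cid: _detection_table(sorted(genes), call="Absent", p=0.8)
            for cid in set(t for t, _ in grid.cells) | set(c for _, c in grid.cells)
        }
        out = pooled_de(grid, absent)
        assert not out["differentially_expressed"].any()
        assert not out["passes_present"].any()

    def test_decision_is_conjunction_of_components(self, small_pair):
        genes, grid, detections = self._grid_and_detections(small_pair, 2.0)
        out = pooled_de(grid, detections)
        np.testing.assert_array_equal(
            out["differentially_expressed"],
            out["passes_fdr"] & out["passes_fold_all"] & out["passes_present"],
        )

    def test_strengthening_filters_shrinks_de_set(self):
        """Monotonicity on a fixed simulated data set."""
        from probestat.pipeline import RunConfig, analyze_chipset
        from probestat.simulate import (make_default_truth, make_scenario,
                                        simulate_experiment)

        cfg = RunConfig(scenario="rat_chronic", seed=2, n_genes=60)
        sc = make_scenario("rat_chronic", seed=2)
        truth = make_default_truth(sc, n_genes=60,
                                   affected_folds={"inactive": 0.3})
        chipset = simulate_experiment(sc, truth, cfg.noise_model())
        chips, detections, _ = analyze_chipset(chipset, cfg)
        treat = [a for a in chips if a.condition == "inactive"]
        ctrl = [a for a in chips if a.condition == "control"]
        grid = all_pairs_comparisons(treat, ctrl)
        base = pooled_de(grid, detections, DEParamsPooled())
        for params in (DEParamsPooled(fold_threshold=2.5),
                       DEParamsPooled(fdr_q=0.005)):
            tighter = pooled_de(grid, detections, params)
            assert set(tighter.index[tighter["differentially_expressed"]]) \
                <= set(base.index[base["differentially_expressed"]])


class TestPairedDE:
    def _signals(self, folds, genes=("g0",)):
        """Subject signal pairs with exact per-subject folds for gene g0
        and nulls elsewhere."""
        out = {}
        for i, f in enumerate(folds):
            control = pd.Series(8.0, index=pd.Index(genes, name="gene_id"))
            treat = control.copy()
            treat.iloc[0] = 8.0 + np.log2(f)
            out[f"S{i + 1}"] = (treat, control)
        return out

    def test_percent_of_control_summary(self):
        """Subjects at 48/57/66% of control: mean 57, SEM 5.196."""
        res = paired_de(self._signals([0.48, 0.57, 0.66]))
        assert res.loc["g0", "percent_of_control_mean"] == pytest.approx(57.0)
        assert res.loc["g0", "percent_of_control_sem"] == pytest.approx(
            9.0 / np.sqrt(3), rel=1e-9
        )

    def test_fold_rule(self):
        res = paired_de(self._signals([0.50, 0.57, 0.64]))
        assert bool(res.loc["g0", "all_subjects_pass_fold"])
        res = paired_de(self._signals([0.50, 0.57, 0.70]))
        assert not bool(res.loc["g0", "all_subjects_pass_fold"])

    def test_null_case(self):
        res = paired_de(self._signals([1.0, 1.0, 1.0]))
        assert res.loc["g0", "paired_t_p"] == 1.0
        assert not bool(res.loc["g0", "all_subjects_pass_fold"])
        assert not bool(res.loc["g0", "differentially_expressed"])

    def test_requires_two_subjects(self):
        with pytest.raises(ValueError):
            paired_de(self._signals([0.5]))

    def test_flag_equals_conjunction(self, rng):
        genes = [f"g{i}" for i in range(30)]
        idx = pd.Index(genes, name="gene_id")
        subject_signals = {
            f"S{j}": (pd.Series(rng.normal(8, 1, 30), index=idx),
                      pd.Series(rng.normal(8, 1, 30), index=idx))
            for j in range(3)
        }
        expressed = pd.Series(rng.random(30) < 0.5, index=idx)
        res = paired_de(subject_signals, expressed=expressed)
        np.testing.assert_array_equal(
            res["differentially_expressed"],
            res["expressed"] & res["all_subjects_pass_fold"]
            & (res["paired_t_p"] < 0.05),
        )


class TestCatalog:
    def _detections(self, pattern, p):
        """pattern: list over 8 chips of Present/Absent for gene g."""
        return {
            f"chip{i}": pd.DataFrame({
                "gene_id": ["g"],
                "p_detect": [p],
                "call": [pattern[i]],
            })
            for i in range(len(pattern))
        }

    def test_strong_moderate_notdetected(self):
        strong = classify_catalog(self._detections(["Present"] * 8, 0.004))
        assert strong.loc["g", "class"] == "Strong"
        assert strong.loc["g", "frequency"] == "8/8"
        none = classify_catalog(self._detections(["Absent"] * 8, 0.47))
        assert none.loc["g", "class"] == "NotDetected"
        assert none.loc["g", "frequency"] == "0/8"
        seven = classify_catalog(
            self._detections(["Present"] * 7 + ["Absent"], 0.024)
        )
        assert seven.loc["g", "class"] == "Moderate"
        assert seven.loc["g", "frequency"] == "7/8"

    def test_strong_boundary_is_configurable(self):
        full = self._detections(["Present"] * 8, 0.02)
        assert classify_catalog(full, strong_p=0.01).loc["g", "class"] == "Moderate"
        assert classify_catalog(full, strong_p=0.03).loc["g", "class"] == "Strong"

    def test_requires_chips(self):
        with pytest.raises(ValueError):
            classify_catalog({})
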