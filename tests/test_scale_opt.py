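import numpy as np
import pytest
from scipy.stats import spearmanr

from sevc.core import mc_cv
from sevc.features import FeatureMatrix, residue_count_matrix
from sevc.scales import (
    CANONICAL_RESIDUES,
    AminoAcidScale,
    DegenerateScaleError,
    random_scale,
)
from sevc.scale_opt import (
    EmptyGroupError,
    compute_group_stats,
    modify_scale,
    optimize_scale,
    synthesize_scale_table,
)


def scale_from(values: dict, name="s"):
    full = {aa: 0.0 for aa in CANONICAL_RESIDUES}
    full.update(values)
    return AminoAcidScale(name, full)


class TestComputeGroupStats:
    def test_worked_example_as_printed(self):
        # FN = {"AA"}, FP = {"RR"}, s(A)=1, s(R)=-1; the printed product
        # m = delta_f * delta_a gives (A:+8, R:-8) under modifier_sign=+1.
        s = scale_from({"A": 1.0, "R": -1.0})
        fn = residue_count_matrix(["AA"])
        fp = residue_count_matrix(["RR"])
        stats = compute_group_stats(fn, fp, s, modifier_sign=1)
        a_idx = CANONICAL_RESIDUES.index("A")
        r_idx = CANONICAL_RESIDUES.index("R")
        assert stats.a_fn[a_idx] == 2 and stats.a_fp[r_idx] == 2
        assert stats.f_fn == pytest.approx(2.0)
        assert stats.f_fp == pytest.approx(-2.0)
        assert stats.delta_f == pytest.approx(4.0)
        assert stats.delta_a[a_idx] == pytest.approx(2.0)
        assert stats.delta_a[r_idx] == pytest.approx(-2.0)
        assert stats.m[a_idx] == pytest.approx(8.0)
        assert stats.m[r_idx] == pytest.approx(-8.0)
        assert np.count_nonzero(stats.m) == 2

    def test_default_sign_negates_printed_product(self):
        s = scale_from({"A": 1.0, "R": -1.0})
        fn = residue_count_matrix(["AA"])
        fp = residue_count_matrix(["RR"])
        printed = compute_group_stats(fn, fp, s, modifier_sign=1)
        corrective = compute_group_stats(fn, fp, s)
        assert np.allclose(corrective.m, -printed.m)

    def test_identical_composition_null(self):
        s = scale_from({"A": 1.0})
        rows = residue_count_matrix(["ACD", "ACD"])
        stats = compute_group_stats(rows[:1], rows[1:], s)
        assert np.allclose(stats.delta_a, 0.0)
        assert not stats.defined

    def test_f_values_match_dot_product_oracle(self, rng):
        # Independent recomputation: f = mean-count vector dot scale values.
        seqs_fn = ["ACDW", "KKLM", "PQRS"]
        seqs_fp = ["YY", "GHI"]
        s = random_scale(5, name="s")
        stats = compute_group_stats(
            residue_count_matrix(seqs_fn), residue_count_matrix(seqs_fp), s
        )
        counts = {aa: i for i, aa in enumerate(CANONICAL_RESIDUES)}
        f_fn = np.mean(
            [sum(s[aa] for aa in seq) for seq in seqs_fn]
        )
        f_fp = np.mean([sum(s[aa] for aa in seq) for seq in seqs_fp])
        assert stats.f_fn == pytest.approx(f_fn)
        assert stats.f_fp == pytest.approx(f_fp)

    def test_empty_group_raises(self):
        s = scale_from({"A": 1.0})
        rows = residue_count_matrix(["ACD"])
        with pytest.raises(EmptyGroupError):
            compute_group_stats(rows[:0], rows, s)


class TestModifyScale:
    def test_rate_zero_identity(self, rng):
        s = random_scale(1)
        out = modify_scale(s, rng.normal(size=20), rate=0.0)
        assert np.array_equal(out.as_array(), s.as_array())

    def test_output_normalized(self, rng):
        out = modify_scale(random_scale(2), rng.normal(size=20), rate=0.05)
        arr = out.as_array()
        assert abs(arr.mean()) < 1e-9
        assert abs(arr.var(ddof=1) - 1.0) < 1e-9

    def test_step_variance_contribution(self, rng):
        # Algebraic check: the standardized modifier scaled by r carries
        # variance r^2 before renormalization.
        m = rng.normal(size=20)
        r = 0.01
        m_bar = (m - m.mean()) / m.std(ddof=1)
        assert (r * m_bar).var(ddof=1) == pytest.approx(r**2)

    def test_constant_modifier_rejected(self):
        with pytest.raises(DegenerateScaleError):
            modify_scale(random_scale(3), np.full(20, 1.5), rate=0.01)


class TestOptimizeScale:
    def test_deterministic(self, split_dataset):
        counts = split_dataset["train_counts"][:96]
        labels = split_dataset["train_labels"][:96]
        kw = dict(stats_runs=5, eval_runs=10, patience=10, max_iterations=40)
        b1, t1 = optimize_scale(random_scale(4, "i"), counts, labels, seed=9, **kw)
        b2, t2 = optimize_scale(random_scale(4, "i"), counts, labels, seed=9, **kw)
        assert np.array_equal(b1.as_array(), b2.as_array())
        assert t1.to_frame().equals(t2.to_frame())

    def test_improves_on_noise_free_data(self):
        from sevc.simulate import SyntheticConfig, generate_dataset

        cons, gt = generate_dataset(SyntheticConfig(noise_sd=0.0, seed=41, n_inserts=24))
        counts = residue_count_matrix(c.sequence for c in cons)
        labels = np.array([c.label for c in cons])
        best, trace = optimize_scale(
            random_scale(42, "init"), counts, labels, seed=43,
            stats_runs=10, eval_runs=30,
        )
        assert trace.best_so_far()[-1] >= trace.initial_mcc

    def test_best_curve_nondecreasing(self, split_dataset):
        counts = split_dataset["train_counts"]
        labels = split_dataset["train_labels"]
        _, trace = optimize_scale(
            random_scale(44, "init"), counts, labels, seed=45,
            stats_runs=5, eval_runs=10, patience=15, max_iterations=60,
        )
        assert np.all(np.diff(trace.best_so_far()) >= 0)

    def test_accepted_scales_normalized(self, split_dataset):
        best, _ = optimize_scale(
            random_scale(46, "init"),
            split_dataset["train_counts"][:96],
            split_dataset["train_labels"][:96],
            seed=47,
            stats_runs=5, eval_runs=10, patience=5, max_iterations=20,
        )
        arr = best.as_array()
        assert abs(arr.mean()) < 1e-9
        assert abs(arr.var(ddof=1) - 1.0) < 1e-9

    def test_single_class_subset_rejected(self, split_dataset):
        counts = split_dataset["train_counts"][:10]
        with pytest.raises(ValueError, match="both classes"):
            optimize_scale(random_scale(1), counts, np.ones(10, dtype=int), seed=1)

    def test_recovers_generating_scale(self, split_dataset):
        # Parameter-recovery harness: moderate noise, reduced run counts.
        best, trace = optimize_scale(
            random_scale(48, "init"),
            split_dataset["train_counts"],
            split_dataset["train_labels"],
            seed=49,
            stats_runs=10,
            eval_runs=30,
        )
        rho = spearmanr(best.as_array(), split_dataset["gt"].scale.as_array()).statistic
        assert abs(rho) >= 0.6
        assert trace.best_so_far()[-1] > trace.initial_mcc


class TestSynthesizeScaleTable:
    kw = dict(stats_runs=3, eval_runs=5, patience=3, max_iterations=8)

    def test_random_mode_subset_sizes(self, split_dataset):
        table, traces = synthesize_scale_table(
            split_dataset["train_counts"], split_dataset["train_labels"],
            seed=51, k_subsets=8, **self.kw,
        )
        assert len(table) == 8
        assert len(traces) == 8
        assert table.provenance == "synthesized"
        assert table.names == [f"S8_{i}" for i in range(1, 9)]

    def test_k1_uses_full_set(self, split_dataset):
        table, _ = synthesize_scale_table(
            split_dataset["train_counts"], split_dataset["train_labels"],
            seed=52, k_subsets=1, **self.kw,
        )
        assert len(table) == 1

    def test_by_strategy_mode(self, split_dataset):
        table, _ = synthesize_scale_table(
            split_dataset["train_counts"], split_dataset["train_labels"],
            seed=53, k_subsets=8, mode="by_strategy",
            strategy_ids=split_dataset["train_strategies"], **self.kw,
        )
        assert len(table) == 8

    def test_by_strategy_wrong_k(self, split_dataset):
        with pytest.raises(ValueError, match="by_strategy"):
            synthesize_scale_table(
                split_dataset["train_counts"], split_dataset["train_labels"],
                seed=54, k_subsets=3, mode="by_strategy",
                strategy_ids=split_dataset["train_strategies"], **self.kw,
            )

    def test_minimum_subset_size(self, split_dataset):
        with pytest.raises(ValueError, match="subsets"):
            synthesize_scale_table(
                split_dataset["train_counts"][:100], split_dataset["train_labels"][:100],
                seed=55, k_subsets=8, **self.kw,
            )

    def test_synthesized_scales_not_identical(self, split_dataset):
        # Orthogonality: independently synthesized scales differ, so PC1 of
        # the pair explains less than a duplicated scale's trivial 100%.
        from sevc.evaluation import pc1_explained_variance
        from sevc.scales import ScaleTable

        table, _ = synthesize_scale_table(
            split_dataset["train_counts"], split_dataset["train_labels"],
            seed=56, k_subsets=2, stats_runs=5, eval_runs=10, patience=10,
            max_iterations=40,
        )
        frac = pc1_explained_variance(table)
        dup = ScaleTable([table.scales[0],
                          AminoAcidScale.from_array("copy", table.scales[0].as_array())])
        assert frac < pc1_explained_variance(dup) == pytest.approx(1.0)
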