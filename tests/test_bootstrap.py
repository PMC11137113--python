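import numpy as np
import pytest

from coslir import StageSample, resample_stage
from coslir.bootstrap import aggregate_replicates, bootstrap_grn
from coslir.solver import SolverConfig


def make_stage(p=3, n=5, seed=0, label="t"):
    rng = np.random.default_rng(seed)
    return StageSample(values=rng.standard_normal((p, n)),
                       gene_names=[f"g{i}" for i in range(p)],
                       stage_label=label)


class TestResample:
    def test_single_cell_rejected(self):
        s = StageSample(values=[[1.0], [2.0]], gene_names=["a", "b"],
                        stage_label="t")
        with pytest.raises(ValueError, match="insufficient cells"):
            resample_stage(s, 0)

    def test_deterministic_given_seed(self):
        s = make_stage()
        r1 = resample_stage(s, 7)
        r2 = resample_stage(s, 7)
        assert np.array_equal(r1.values, r2.values)

    def test_columns_come_from_original(self):
        s = make_stage()
        r = resample_stage(s, 3)
        cols = {tuple(c) for c in s.values.T}
        assert all(tuple(c) in cols for c in r.values.T)

    def test_inclusion_frequency_matches_theory(self):
        """P(cell included) = 1 - (1 - 1/n)^n ~ 0.672 for n = 5."""
        s = make_stage(n=5)
        included = np.zeros(5)
        reps = 2000
        originals = [tuple(c) for c in s.values.T]
        for r in range(reps):
            drawn = {tuple(c) for c in resample_stage(s, r).values.T}
            for i, c in enumerate(originals):
                included[i] += c in drawn
        freq = included / reps
        expect = 1 - (1 - 1 / 5) ** 5
        assert np.all(np.abs(freq - expect) < 0.03)


class TestAggregate:
    def test_identical_replicates_pass_through(self):
        M = np.array([[0.0, 1.5], [-2.0, 0.0]])
        reps = np.stack([M] * 10)
        final, conf = aggregate_replicates(reps, 0.9)
        assert np.array_equal(final, M)
        assert np.all(conf[M != 0] == 1.0)

    def test_split_signs_zeroed(self):
        plus = np.array([[1.0]])
        minus = np.array([[-1.0]])
        reps = np.stack([plus, minus] * 5)
        final, conf = aggregate_replicates(reps, 0.51)
        assert conf[0, 0] == pytest.approx(0.5)
        assert final[0, 0] == 0.0

    def test_majority_sign_mean_excludes_minority(self):
        reps = np.stack([np.array([[2.0]])] * 8 + [np.array([[-1.0]])] * 2)
        final, conf = aggregate_replicates(reps, 0.7)
        assert conf[0, 0] == pytest.approx(0.8)
        assert final[0, 0] == pytest.approx(2.0)

    def test_mean_mode_all_includes_everything(self):
        reps = np.stack([np.array([[2.0]])] * 8 + [np.array([[-1.0]])] * 2)
        final, _ = aggregate_replicates(reps, 0.7, mean_mode="all")
        assert final[0, 0] == pytest.approx((2.0 * 8 - 1.0 * 2) / 10)

    def test_raising_threshold_only_removes_edges(self, rng):
        reps = np.where(rng.random((20, 4, 4)) < 0.7,
                        rng.standard_normal((20, 4, 4)), 0.0)
        lo, _ = aggregate_replicates(reps, 0.6)
        hi, _ = aggregate_replicates(reps, 0.9)
        surviving = hi != 0
        assert np.all(lo[surviving] == hi[surviving])
        assert np.all((hi != 0) <= (lo != 0))

    def test_replicate_order_invariance(self, rng):
        reps = np.where(rng.random((15, 3, 3)) < 0.5,
                        rng.standard_normal((15, 3, 3)), 0.0)
        f1, c1 = aggregate_replicates(reps, 0.6)
        perm = rng.permutation(15)
        f2, c2 = aggregate_replicates(reps[perm], 0.6)
        assert np.allclose(f1, f2)
        assert np.allclose(c1, c2)

    @pytest.mark.parametrize("bad", [0.5, 0.2, 1.2])
    def test_threshold_must_exceed_half(self, bad):
        with pytest.raises(ValueError):
            aggregate_replicates(np.zeros((3, 2, 2)), bad)


class TestBootstrapGrn:
    def test_high_confidence_on_large_sample_truth(self):
        """With abundant cells, every resolvable true edge is detected
        with near-total sign stability."""
        from coslir import generate_truth, sample_cells
        truth = generate_truth(p=5, sparsity=0.2, seed=3)
        s_t, s_t1 = sample_cells(truth, 20_000, 20_000, seed=0)
        cfg = SolverConfig(max_iter=2000)
        res = bootstrap_grn(s_t, s_t1, cfg, epsilon=0.01, n_reps=8,
                            conf_threshold=0.6, base_seed=0)
        strong = np.abs(truth.A_true) >= 0.05
        assert np.all(res.confidence[strong] >= 0.95)

    def test_filtered_reuses_replicates(self):
        from coslir import generate_truth, sample_cells
        truth = generate_truth(p=4, sparsity=0.2, seed=1)
        s_t, s_t1 = sample_cells(truth, 2000, 2000, seed=2)
        cfg = SolverConfig(max_iter=1000)
        res = bootstrap_grn(s_t, s_t1, cfg, epsilon=0.01, n_reps=6,
                            conf_threshold=0.6, base_seed=5)
        strict = res.filtered(0.99)
        keep = strict != 0
        assert np.all(strict[keep] == res.final[keep])

    def test_seeded_determinism(self):
        from coslir import generate_truth, sample_cells
        truth = generate_truth(p=4, sparsity=0.2, seed=2)
        s_t, s_t1 = sample_cells(truth, 500, 500, seed=3)
        cfg = SolverConfig(max_iter=800)
        r1 = bootstrap_grn(s_t, s_t1, cfg, epsilon=0.01, n_reps=4,
                           conf_threshold=0.6, base_seed=11)
        r2 = bootstrap_grn(s_t, s_t1, cfg, epsilon=0.01, n_reps=4,
                           conf_threshold=0.6, base_seed=11)
        assert np.array_equal(r1.final, r2.final)

    def test_invalid_parameters(self):
        s = make_stage(n=10)
        with pytest.raises(ValueError):
            bootstrap_grn(s, s, None, n_reps=1)
        with pytest.raises(ValueError):
            bootstrap_grn(s, s, None, conf_threshold=0.5)
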