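import numpy as np
import pytest

from gsabench import (
    BaselineSpec,
    GeneSet,
    SimulationSpec,
    bootstrap_replicate,
    generate_baseline,
    inject_signal,
    null_iid_normal,
    null_permuted_labels,
)
from gsabench.expression import center_genes
from gsabench.simulate import random_collection, spawn_rngs


class TestSpecs:
    def test_simulation_spec_validation(self):
        SimulationSpec("T", pi=0.5, tau=1.0)
        with pytest.raises(ValueError):
            SimulationSpec("T", pi=0.0, tau=1.0)
        with pytest.raises(ValueError):
            SimulationSpec("T", pi=0.5, tau=-1.0)
        with pytest.raises(ValueError):
            SimulationSpec("T", pi=0.5, tau=1.0, n_replicates=0)

    def test_baseline_spec_validation(self):
        with pytest.raises(ValueError):
            BaselineSpec(n_genes=10, block_sizes=[20])
        with pytest.raises(ValueError):
            BaselineSpec(within_block_rho=1.0)


class TestInjectSignal:
    def test_tau_zero_is_identity(self, iid_ds, small_collection):
        out, altered = inject_signal(iid_ds, small_collection.sets[0], 1.0, 0.0, rng=0)
        np.testing.assert_array_equal(out.values, iid_ds.values)
        assert len(altered) == len(small_collection.sets[0])

    def test_rounding_rule(self, iid_ds):
        genes = tuple(iid_ds.gene_ids[:10])
        s = GeneSet("S", "na", genes)
        _, altered = inject_signal(iid_ds, s, 0.5, 1.0, rng=1)
        assert len(altered) == 5
        _, tiny = inject_signal(iid_ds, s, 0.01, 1.0, rng=1)
        assert len(tiny) == 1  # floor of one altered gene for pi > 0

    def test_shift_is_exactly_tau_times_sd(self, iid_ds):
        s = GeneSet("S", "na", (iid_ds.gene_ids[3],))
        out, altered = inject_signal(iid_ds, s, 1.0, 1.0, rng=2)
        row = iid_ds.gene_index(altered)[0]
        sd = iid_ds.values[row].std(ddof=1)
        diff = out.values[row] - iid_ds.values[row]
        np.testing.assert_allclose(diff[iid_ds.case_mask], sd)
        np.testing.assert_allclose(diff[iid_ds.control_mask], 0.0)

    def test_down_direction_and_untouched_genes(self, iid_ds):
        s = GeneSet("S", "na", tuple(iid_ds.gene_ids[:4]))
        out, altered = inject_signal(iid_ds, s, 1.0, 2.0, direction="down", rng=3)
        rows = iid_ds.gene_index(altered)
        others = np.setdiff1d(np.arange(iid_ds.n_genes), rows)
        np.testing.assert_array_equal(out.values[others], iid_ds.values[others])
        assert np.all(
            out.values[np.ix_(rows, np.flatnonzero(iid_ds.case_mask))]
            < iid_ds.values[np.ix_(rows, np.flatnonzero(iid_ds.case_mask))]
        )

    def test_mean_shift_recovery(self):
        """Estimated shift / sd recovers tau; non-altered genes stay at 0."""
        ds = center_genes(null_iid_normal(400, 50, 50, rng=4))
        s = GeneSet("S", "na", tuple(ds.gene_ids[:100]))
        tau = 1.5
        out, altered = inject_signal(ds, s, 1.0, tau, rng=5)
        rows = ds.gene_index(altered)
        case, ctrl = out.case_mask, out.control_mask
        shift = (
            out.values[:, case].mean(axis=1) - out.values[:, ctrl].mean(axis=1)
        ) / ds.values.std(axis=1, ddof=1)
        se = np.sqrt(1 / case.sum() + 1 / ctrl.sum())
        assert abs(shift[rows].mean() - tau) < 2 * se / np.sqrt(len(rows)) + 0.02
        others = np.setdiff1d(np.arange(ds.n_genes), rows)
        assert abs(shift[others].mean()) < 3 * se / np.sqrt(len(others))

    def test_errors(self, iid_ds):
        s = GeneSet("S", "na", ("not_a_gene",))
        with pytest.raises(ValueError, match="no genes"):
            inject_signal(iid_ds, s, 1.0, 1.0, rng=0)
        with pytest.raises(ValueError):
            inject_signal(iid_ds, GeneSet("S", "na", (iid_ds.gene_ids[0],)), 1.0, -1.0)


class TestBootstrapReplicate:
    def test_class_sizes_conserved(self, iid_ds):
        rep = bootstrap_replicate(iid_ds, rng=0)
        assert rep.case_mask.sum() == iid_ds.case_mask.sum()
        assert rep.control_mask.sum() == iid_ds.control_mask.sum()

    def test_large_unbalanced_design_conserved(self):
        ds = null_iid_normal(5, 264, 160, rng=1)
        rep = bootstrap_replicate(ds, rng=2)
        assert int(rep.case_mask.sum()) == 264
        assert int(rep.control_mask.sum()) == 160

    def test_resampling_stays_within_class(self, iid_ds):
        rep = bootstrap_replicate(iid_ds, rng=3)
        # every case column of the replicate must equal some original case column
        case_pool = iid_ds.values[:, iid_ds.case_mask].T
        for col in rep.values[:, rep.case_mask].T:
            assert any(np.array_equal(col, c) for c in case_pool)

    def test_seed_determinism(self, iid_ds):
        r1 = bootstrap_replicate(iid_ds, rng=7)
        r2 = bootstrap_replicate(iid_ds, rng=7)
        np.testing.assert_array_equal(r1.values, r2.values)
        assert r1.sample_ids == r2.sample_ids


class TestNullConstructions:
    def test_permuted_labels_conserve_counts_and_matrix(self, iid_ds):
        out = null_permuted_labels(iid_ds, rng=0)
        assert out.values is iid_ds.values or np.array_equal(out.values, iid_ds.values)
        assert out.case_mask.sum() == iid_ds.case_mask.sum()

    def test_two_sample_permutation_enumerable(self):
        ds = null_iid_normal(3, 1, 1, rng=0)
        outcomes = {
            tuple(null_permuted_labels(ds, rng=s).labels) for s in range(20)
        }
        assert outcomes <= {(0, 1), (1, 0)}
        assert len(outcomes) == 2

    def test_iid_normal_moments(self):
        ds = null_iid_normal(500, 30, 30, rng=5)
        G, n = ds.n_genes, ds.n_samples
        assert abs(ds.values.mean()) < 4 / np.sqrt(G * n)
        assert abs(ds.values.var() - 1.0) < 0.05

    def test_iid_normal_off_diagonal_correlation_scale(self):
        ds = null_iid_normal(200, 25, 25, rng=6)
        C = np.corrcoef(ds.values)
        off = np.abs(C[np.triu_indices_from(C, k=1)])
        # |r| of independent pairs has mean ~ sqrt(2/pi)/sqrt(n)
        expected = np.sqrt(2 / np.pi) / np.sqrt(50)
        assert off.mean() == pytest.approx(expected, rel=0.1)


class TestGenerateBaseline:
    def test_zero_rho_uncorrelated(self):
        spec = BaselineSpec(
            n_genes=100, n_samples=300, block_sizes=[50], within_block_rho=0.0, seed=0
        )
        ds = generate_baseline(spec)
        C = np.corrcoef(ds.values[:50])
        off = C[np.triu_indices(50, k=1)]
        assert abs(off.mean()) < 0.02

    def test_block_correlation_matches_parameter(self):
        spec = BaselineSpec(
            n_genes=100, n_samples=200, block_sizes=[50], within_block_rho=0.4, seed=1
        )
        ds = generate_baseline(spec)
        C = np.corrcoef(ds.values[:50])
        off = C[np.triu_indices(50, k=1)]
        assert off.mean() == pytest.approx(0.4, abs=0.05)

    def test_cross_block_independence(self):
        # cross-block correlations share the two block factors, so the mean
        # fluctuates at scale rho/sqrt(n) per draw; average over seeds
        means = []
        for seed in range(6):
            spec = BaselineSpec(
                n_genes=100, n_samples=400, block_sizes=[40, 40],
                within_block_rho=0.5, seed=seed,
            )
            ds = generate_baseline(spec)
            C = np.corrcoef(ds.values)
            means.append(C[:40, 40:80].mean())
        assert abs(np.mean(means)) < 0.04

    def test_deterministic_under_seed(self):
        spec = BaselineSpec(seed=9)
        np.testing.assert_array_equal(
            generate_baseline(spec).values, generate_baseline(spec).values
        )


class TestRandomStreams:
    def test_spawned_streams_independent_and_reproducible(self):
        a = [r.standard_normal() for r in spawn_rngs(3, 4)]
        b = [r.standard_normal() for r in spawn_rngs(3, 4)]
        assert a == b
        assert len(set(a)) == 4

    def test_random_collection_shapes(self):
        coll = random_collection([f"g{i}" for i in range(200)], 12, (5, 20), rng=1)
        assert len(coll) == 12
        assert all(5 <= len(s) <= 20 for s in coll)
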