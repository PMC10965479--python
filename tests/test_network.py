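import numpy as np
import pandas as pd
import pytest
from scipy.stats import linregress

from coexmod import (
    NetworkParams,
    adjacency,
    build_network,
    cluster_modules,
    correlation_matrix,
    merge_close_modules,
    module_eigengene,
    pick_soft_threshold,
    topological_overlap,
)
from coexmod.simulate import read_truth

from conftest import small_spec


def frame(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    names = [f"{prefix}{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=names, columns=[f"s{j}" for j in range(values.shape[1])])


def square(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes, columns=genes)


def random_adjacency(rng, n):
    raw = rng.uniform(0, 1, (n, n))
    a = (raw + raw.T) / 2
    np.fill_diagonal(a, 1.0)
    return square(a)


class TestCorrelation:
    def test_identical_and_negated_profiles(self, rng):
        base = rng.standard_normal(10)
        m = frame([base, base, -base])
        cor = correlation_matrix(m)
        assert cor.iloc[0, 1] == pytest.approx(1.0)
        assert cor.iloc[0, 2] == pytest.approx(-1.0)

    def test_matches_two_pass_textbook_formula(self, rng):
        m = frame(rng.standard_normal((6, 15)))
        cor = correlation_matrix(m).to_numpy()
        X = m.to_numpy()
        for i in range(6):
            for j in range(6):
                xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert cor[i, j] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete_with_missing(self, rng):
        values = rng.standard_normal((4, 12))
        values[0, :3] = np.nan
        cor = correlation_matrix(frame(values))
        shared = ~np.isnan(values[0]) & ~np.isnan(values[1])
        xi = values[0, shared] - values[0, shared].mean()
        xj = values[1, shared] - values[1, shared].mean()
        expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
        assert cor.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_observations_names_pair(self, rng):
        values = rng.standard_normal((3, 6))
        values[0, :4] = np.nan
        values[1, 4:] = np.nan
        with pytest.raises(ValueError, match=r"\(G0, G1\)"):
            correlation_matrix(frame(values))


class TestAdjacency:
    def test_unsigned_power_values(self):
        cor = square([[1.0, -0.5], [-0.5, 1.0]])
        a = adjacency(cor, NetworkParams(beta=6))
        assert a.iloc[0, 1] == pytest.approx(0.015625)

    def test_signed_maps_perfect_anticorrelation_to_zero(self):
        cor = square([[1.0, -1.0], [-1.0, 1.0]])
        a = adjacency(cor, NetworkParams(beta=6, network_type="signed"))
        assert a.iloc[0, 1] == pytest.approx(0.0)

    def test_beta_one_is_absolute_value(self, rng):
        raw = np.clip(rng.uniform(-1, 1, (5, 5)), -1, 1)
        cor = square((raw + raw.T) / 2)
        np.fill_diagonal(cor.values, 1.0)
        a = adjacency(cor, NetworkParams(beta=1))
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(a.to_numpy()[off], np.abs(cor.to_numpy())[off])

    def test_beta_below_one_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            adjacency(square([[1.0, 0.5], [0.5, 1.0]]), NetworkParams(beta=0))

    def test_unsigned_adjacency_strictly_decreases_with_beta(self, rng):
        raw = rng.uniform(-0.99, 0.99, (6, 6))
        cor = square((raw + raw.T) / 2)
        np.fill_diagonal(cor.values, 1.0)
        off = ~np.eye(6, dtype=bool)
        previous = None
        for beta in (1, 2, 4, 8):
            a = adjacency(cor, NetworkParams(beta=beta)).to_numpy()[off]
            if previous is not None:
                assert (a < previous).all()
            previous = a

    def test_output_bounds_and_symmetry(self, rng):
        for _ in range(20):
            raw = rng.uniform(-1, 1, (8, 8))
            cor = square((raw + raw.T) / 2)
            np.fill_diagonal(cor.values, 1.0)
            for kind in ("unsigned", "signed"):
                a = adjacency(cor, NetworkParams(beta=5, network_type=kind)).to_numpy()
                assert np.allclose(a, a.T)
                assert a.min() >= 0 and a.max() <= 1
                assert np.allclose(np.diag(a), 1.0)


def reference_scale_free_fit(cor, params):
    """Independent re-evaluation of the scale-free criterion for one power grid."""
    chosen = None
    for power in params.power_grid:
        A = np.abs(cor.to_numpy()) ** power
        np.fill_diagonal(A, 1.0)
        k = A.sum(axis=1) - 1
        if np.isclose(k.max(), k.min()) or k.max() <= 0:
            continue
        edges = np.linspace(k.min(), k.max(), 11)
        idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
        mids = (edges[:-1] + edges[1:]) / 2
        dk = np.array([k[idx == b].mean() if (idx == b).any() else mids[b] for b in range(10)])
        dk = np.where(dk <= 0, mids, dk)
        freq = np.array([(idx == b).mean() for b in range(10)])
        if (freq > 0).sum() < 3:
            continue
        fit = linregress(np.log10(dk), np.log10(freq + 1e-9))
        if -np.sign(fit.slope) * fit.rvalue**2 >= params.r2_threshold:
            chosen = power
            break
    return chosen


class TestSoftThreshold:
    def test_chosen_beta_matches_independent_evaluation(self, tmp_path):
        # a planted-module cohort whose connectivity spectrum genuinely
        # reaches the scale-free criterion at an interior grid power
        from coexmod import correlation_matrix as cormat
        from coexmod import generate_collection, preprocess_matrix, read_expression_matrix
        from coexmod.simulate import SyntheticSpec

        spec = small_spec(seed=5, n_datasets=1)
        spec = SyntheticSpec(**{**spec.__dict__, "samples_per_dataset": 120})
        coll = generate_collection(spec, tmp_path)
        m = preprocess_matrix(read_expression_matrix(coll.expression_paths["sim01"]))
        cor = cormat(m)
        params = NetworkParams()
        fit = pick_soft_threshold(cor, params)
        expected = reference_scale_free_fit(cor, params)
        assert expected is not None
        assert not fit.used_fallback
        assert fit.chosen_beta == expected

    def test_fallback_when_no_power_passes(self, rng):
        base = rng.standard_normal((25, 200))
        cor = correlation_matrix(frame(base))
        params = NetworkParams(r2_threshold=0.999999)
        fit = pick_soft_threshold(cor, params)
        assert fit.used_fallback and fit.chosen_beta == params.fallback_beta

    def test_one_row_per_grid_power(self, rng):
        cor = correlation_matrix(frame(rng.standard_normal((25, 30))))
        fit = pick_soft_threshold(cor, NetworkParams())
        assert fit.table["power"].tolist() == list(NetworkParams().power_grid)

    def test_too_few_genes_rejected(self, rng):
        cor = correlation_matrix(frame(rng.standard_normal((10, 30))))
        with pytest.raises(ValueError, match="20 genes"):
            pick_soft_threshold(cor, NetworkParams())


class TestTopologicalOverlap:
    def tom_bruteforce(self, A):
        n = len(A)
        out = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                ki = sum(A[i, u] for u in range(n) if u != i)
                kj = sum(A[j, u] for u in range(n) if u != j)
                out[i, j] = (l + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
        return out

    def test_identity_adjacency_gives_identity(self):
        a = square(np.eye(4))
        pd.testing.assert_frame_equal(topological_overlap(a), a)

    def test_complete_graph_closed_form(self):
        a = square(np.ones((4, 4)))
        assert np.allclose(topological_overlap(a).to_numpy(), 1.0)

    def test_matches_bruteforce_loop_oracle(self, rng):
        for _ in range(30):
            a = random_adjacency(rng, int(rng.integers(3, 11)))
            tom = topological_overlap(a).to_numpy()
            expected = self.tom_bruteforce(a.to_numpy())
            assert np.max(np.abs(tom - expected)) < 1e-10

    def test_output_invariants(self, rng):
        for _ in range(20):
            tom = topological_overlap(random_adjacency(rng, 9)).to_numpy()
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0 and tom.max() <= 1
            assert np.allclose(np.diag(tom), 1.0)

    def test_rejects_asymmetric_input(self, rng):
        a = random_adjacency(rng, 5)
        a.iloc[0, 1] += 0.2
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


class TestClusterModules:
    def two_block_diss(self, n=10):
        d = np.ones((2 * n, 2 * n))
        d[:n, :n] = 0.0
        d[n:, n:] = 0.0
        np.fill_diagonal(d, 0.0)
        return square(d)

    def test_two_perfect_blocks(self):
        part = cluster_modules(self.two_block_diss(), min_module_size=2, cut_height=0.5)
        assert len(part.module_labels) == 2
        assert (part.labels != 0).all()
        assert sorted(part.module_sizes.values()) == [10, 10]

    def test_all_distant_genes_unassigned(self):
        d = np.ones((6, 6))
        np.fill_diagonal(d, 0.0)
        part = cluster_modules(square(d), min_module_size=3)
        assert (part.labels == 0).all()

    def test_min_module_size_validated(self):
        with pytest.raises(ValueError, match="min_module_size"):
            cluster_modules(self.two_block_diss(), min_module_size=1)

    def test_gene_order_invariance(self, rng):
        diss = self.two_block_diss()
        noise = rng.uniform(0, 0.05, diss.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0.0)
        diss = square(np.clip(diss.to_numpy() + noise, 0, 1))
        part = cluster_modules(diss, min_module_size=2)
        perm = rng.permutation(len(diss))
        shuffled = diss.iloc[perm, perm]
        part2 = cluster_modules(shuffled, min_module_size=2)
        assert part.labels.sort_index().equals(part2.labels.sort_index())


class TestEigengene:
    def test_identical_profiles_recovered_exactly(self, rng):
        base = rng.standard_normal(30)
        m = frame([base * 2 + 1, base * 0.5 - 3, base])
        labels = pd.Series(1, index=m.index)
        eig = module_eigengene(m, labels, 1)
        standardized = (base - base.mean()) / base.std()
        assert abs(np.corrcoef(eig, standardized)[0, 1]) == pytest.approx(1.0)
        assert np.linalg.norm(eig) == pytest.approx(1.0)

    def test_sign_oriented_along_module_mean(self, rng):
        for _ in range(10):
            m = frame(rng.standard_normal((6, 25)))
            labels = pd.Series(1, index=m.index)
            eig = module_eigengene(m, labels, 1)
            X = m.to_numpy()
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            assert np.corrcoef(eig, Xs.mean(0))[0, 1] >= 0

    def test_recovers_planted_factor(self, small_collection):
        truth = read_truth(small_collection.truth_path)
        ds = "sim01"
        from coexmod import read_expression_matrix

        m = read_expression_matrix(small_collection.expression_paths[ds])
        members = sorted(truth.target_members(ds))
        labels = pd.Series(0, index=m.index)
        labels.loc[members] = 1
        eig = module_eigengene(m, labels, 1)
        factor = truth.factors[ds]["target"].loc[m.columns]
        assert abs(np.corrcoef(eig, factor)[0, 1]) >= 0.9

    def test_absent_label_rejected(self, rng):
        m = frame(rng.standard_normal((4, 10)))
        labels = pd.Series(1, index=m.index)
        with pytest.raises(KeyError):
            module_eigengene(m, labels, 7)


class TestMergeCloseModules:
    def partition_from(self, m, groups):
        from coexmod import ModulePartition

        labels = pd.Series(0, index=m.index)
        for label, genes in groups.items():
            labels.loc[genes] = label
        part = ModulePartition(labels=labels)
        for label in part.module_labels:
            part.eigengenes[label] = module_eigengene(m, labels, label)
        return part

    def test_identical_eigengene_modules_merge(self, rng):
        base = rng.standard_normal(40)
        rows = [base + rng.normal(0, 0.01, 40) for _ in range(6)]
        m = frame(rows)
        part = self.partition_from(m, {1: m.index[:3], 2: m.index[3:]})
        merged = merge_close_modules(m, part, merge_height=0.25)
        assert len(merged.module_labels) == 1
        assert merged.module_sizes[1] == 6

    def test_uncorrelated_modules_untouched(self, rng):
        m = frame(rng.standard_normal((8, 100)))
        part = self.partition_from(m, {1: m.index[:4], 2: m.index[4:]})
        merged = merge_close_modules(m, part, merge_height=0.25)
        assert len(merged.module_labels) == 2

    def test_three_way_merge_is_label_order_independent(self, rng):
        base = rng.standard_normal(50)
        m = frame([base + rng.normal(0, 0.01, 50) for _ in range(9)])
        for order in ([1, 2, 3], [3, 1, 2]):
            groups = {
                order[0]: m.index[:3],
                order[1]: m.index[3:6],
                order[2]: m.index[6:],
            }
            merged = merge_close_modules(m, self.partition_from(m, groups), 0.25)
            assert len(merged.module_labels) == 1

    def test_merge_height_validated(self, rng):
        m = frame(rng.standard_normal((4, 20)))
        part = self.partition_from(m, {1: m.index[:2], 2: m.index[2:]})
        with pytest.raises(ValueError, match="merge_height"):
            merge_close_modules(m, part, merge_height=1.5)


class TestBuildNetwork:
    def test_duplicated_profiles_collapse_to_one_module(self, rng):
        base = rng.standard_normal(30)
        m = frame([base.copy() for _ in range(25)])
        part = build_network(m, min_module_size=5)
        assert len(part.module_labels) == 1
        assert (part.labels == 1).all()
        assert part.log["used_fallback"]

    def test_deterministic(self, small_collection):
        from coexmod import preprocess_matrix, read_expression_matrix

        m = preprocess_matrix(
            read_expression_matrix(small_collection.expression_paths["sim01"])
        )
        p1 = build_network(m)
        p2 = build_network(m)
        assert p1.labels.equals(p2.labels)
        assert p1.log["beta"] == p2.log["beta"]

    def test_pure_noise_mostly_unassigned(self, rng):
        m = frame(rng.standard_normal((300, 60)))
        part = build_network(m, min_module_size=30)
        assert (part.labels == 0).mean() >= 0.8

    def test_planted_modules_recovered(self, small_collection, small_run):
        truth = read_truth(small_collection.truth_path)
        from sklearn.metrics import adjusted_rand_score

        assert len(small_run.partitions) == 3
        for ds, part in small_run.partitions.items():
            assert part.log["n_modules_premerge"] >= 3
            genes = list(part.labels.index)
            true_labels = [truth.membership[ds][g] for g in genes]
            assert adjusted_rand_score(true_labels, part.labels.to_numpy()) >= 0.95
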