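import itertools

import numpy as np
import pytest

import softpair as sp
from softpair.graphs import knn_weight_graph
from softpair.synthetic import GeneratorConfig, brute_force_best

from conftest import TINY, random_hard


class TestGenerateCoupledPair:
    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(**TINY, seed=9)
        p1, t1 = sp.generate_coupled_pair(cfg)
        p2, t2 = sp.generate_coupled_pair(cfg)
        assert p1.a.sequences() == p2.a.sequences()
        assert p1.b.sequences() == p2.b.sequences()
        for b1, b2 in zip(t1.blocks, t2.blocks):
            np.testing.assert_array_equal(b1, b2)

    def test_different_seeds_differ(self):
        cfg1 = GeneratorConfig(**TINY, seed=1)
        cfg2 = GeneratorConfig(**TINY, seed=2)
        assert (
            sp.generate_coupled_pair(cfg1)[0].a.sequences()
            != sp.generate_coupled_pair(cfg2)[0].a.sequences()
        )

    def test_full_coupling_makes_designated_columns_identical(self):
        cfg = GeneratorConfig(
            n_species=2, species_size=3, length_a=5, length_b=5,
            alphabet_size=4, n_coupled=25, coupling=1.0, seed=0,
        )
        pair, truth = sp.generate_coupled_pair(cfg)
        # C = L_A * L_B: every column pair is coupled, so under the true
        # pairing every A column equals every B column
        a = sp.apply_hard(truth, sp.one_hot_encode(pair.a))
        b = sp.one_hot_encode(pair.b)
        for i in range(5):
            for j in range(5):
                np.testing.assert_array_equal(a.data[:, i, :], b.data[:, j, :])

    def test_full_coupling_truth_attains_brute_force_optimum(self):
        for seed in range(3):
            cfg = GeneratorConfig(
                n_species=2, species_size=4, length_a=5, length_b=5,
                alphabet_size=4, n_coupled=25, coupling=1.0, seed=seed,
            )
            pair, truth = sp.generate_coupled_pair(cfg)
            _, opt = brute_force_best(pair.a, pair.b, "mi")
            a = sp.one_hot_encode(pair.a)
            b = sp.one_hot_encode(pair.b)
            truth_loss = sp.two_body_entropy_loss(sp.apply_hard(truth, a), b).value
            assert truth_loss == pytest.approx(opt, abs=1e-9)

    def test_zero_coupling_truth_indistinguishable_from_random(self):
        # with p = 0 the true pairing carries no excess MI signal
        diffs = []
        rng = np.random.default_rng(0)
        for seed in range(30):
            cfg = GeneratorConfig(
                n_species=4, species_size=3, length_a=6, length_b=6,
                alphabet_size=6, n_coupled=10, coupling=0.0, seed=seed,
            )
            pair, truth = sp.generate_coupled_pair(cfg)
            a, b = sp.one_hot_encode(pair.a), sp.one_hot_encode(pair.b)
            rand = random_hard(rng, pair.partition)
            diffs.append(sp.excess_loss(rand, truth, a, b))
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 1e-12

    def test_harmonized_structure_and_padding(self):
        cfg = GeneratorConfig(**TINY, unequal_prob=1.0, seed=1)
        pair, truth = sp.generate_coupled_pair(cfg)
        assert pair.a.partition == pair.partition == pair.b.partition
        assert pair.b.padding_mask().sum() == pair.partition.n_species
        # padding rows are all-gap and sit at block ends
        for off, size in zip(pair.partition.offsets, pair.partition.sizes):
            rec = pair.b.records[off + size - 1]
            assert rec.is_padding and set(rec.seq) == {"-"}


class TestGeneratePhyloPair:
    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(**TINY, phylogeny=True, mutation_rate=0.1, seed=3)
        p1, _ = sp.generate_phylo_pair(cfg)
        p2, _ = sp.generate_phylo_pair(cfg)
        assert p1.a.sequences() == p2.a.sequences()

    def test_requires_phylogeny_mode(self):
        with pytest.raises(ValueError, match="phylogeny"):
            sp.generate_phylo_pair(GeneratorConfig(**TINY))

    def test_zero_mutation_gives_identical_knn_supports(self):
        cfg = GeneratorConfig(
            n_species=4, species_size=4, length_a=20, length_b=20,
            alphabet_size=8, phylogeny=True, mutation_rate=0.0, seed=5,
        )
        pair, truth = sp.generate_phylo_pair(cfg)
        a_sorted = sp.apply_hard(truth, pair.a)
        wa = knn_weight_graph(a_sorted, k=4)
        wb = knn_weight_graph(pair.b, k=4)
        np.testing.assert_array_equal(wa.weights > 0, wb.weights > 0)
        np.testing.assert_allclose(wa.weights, wb.weights)

    def test_fully_random_mutation_removes_ga_signal(self):
        # at mutation rate 1 every site is redrawn uniformly, so the leaves
        # retain no ancestry and the true pairing carries no graph signal
        diffs = []
        rng = np.random.default_rng(1)
        for seed in range(30):
            cfg = GeneratorConfig(
                n_species=4, species_size=3, length_a=12, length_b=12,
                alphabet_size=8, phylogeny=True, mutation_rate=1.0, seed=seed,
            )
            pair, truth = sp.generate_phylo_pair(cfg)
            wa = knn_weight_graph(pair.a, k=3)
            wb = knn_weight_graph(pair.b, k=3)
            from softpair.graphs import ga_loss, permute_graph

            lt = ga_loss(permute_graph(truth, wa), wb.weights).value
            lr = ga_loss(
                permute_graph(random_hard(rng, pair.partition), wa), wb.weights
            ).value
            diffs.append(lt - lr)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 2 * se + 1e-12

    def test_nonaligned_mode_produces_variable_lengths(self):
        cfg = GeneratorConfig(
            n_species=10, species_size=4, length_a=25, length_b=25,
            alphabet_size=8, phylogeny=True, mutation_rate=0.3,
            aligned=False, seed=2,
        )
        pair, _ = sp.generate_phylo_pair(cfg)
        assert not pair.a.aligned
        assert len({len(s) for s in pair.a.sequences()}) > 1


class TestBruteForceBest:
    def test_singleton_species_trivially_identity(self):
        cfg = GeneratorConfig(
            n_species=4, species_size=1, length_a=6, length_b=6,
            alphabet_size=4, n_coupled=5, coupling=0.5, seed=0,
        )
        pair, _ = sp.generate_coupled_pair(cfg)
        perm, _ = brute_force_best(pair.a, pair.b, "mi")
        for blk in perm.blocks:
            np.testing.assert_array_equal(blk, [0])

    def test_enumerates_exactly_product_of_factorials(self, monkeypatch):
        cfg = GeneratorConfig(
            n_species=2, species_size=(2, 3), length_a=6, length_b=6,
            alphabet_size=4, n_coupled=5, coupling=0.5, seed=1,
        )
        rng_sizes_cfg = GeneratorConfig(
            n_species=2, species_size=3, length_a=6, length_b=6,
            alphabet_size=4, n_coupled=5, coupling=0.5, seed=1,
        )
        pair, _ = sp.generate_coupled_pair(rng_sizes_cfg)
        # count evaluations through the entropy kernel
        import softpair.synthetic as syn

        calls = {"n": 0}
        real = syn.entr

        def counting_entr(x):
            calls["n"] += 1
            return real(x)

        monkeypatch.setattr(syn, "entr", counting_entr)
        brute_force_best(pair.a, pair.b, "mi")
        assert calls["n"] == 36  # 3! * 3!

    def test_guard_rejects_large_search_space(self):
        cfg = GeneratorConfig(
            n_species=3, species_size=10, length_a=6, length_b=6,
            alphabet_size=4, n_coupled=5, coupling=0.5, seed=0,
        )
        pair, _ = sp.generate_coupled_pair(cfg)
        with pytest.raises(ValueError, match=r"47784725839872000000"):
            brute_force_best(pair.a, pair.b, "mi")

    def test_optimum_bounds_any_pairing_run(self, tiny_coupled):
        pair, _ = tiny_coupled
        _, opt = brute_force_best(pair.a, pair.b, "mi")
        res = sp.run_ipa(pair.a, pair.b, sp.BootstrapConfig(seed=0), n_ipa=2)
        assert opt <= res.final_loss + 1e-12

    def test_ga_optimum_bounds_ga_runs(self):
        cfg = GeneratorConfig(
            n_species=3, species_size=4, length_a=20, length_b=20,
            alphabet_size=8, phylogeny=True, mutation_rate=0.1, seed=4,
        )
        pair, _ = sp.generate_phylo_pair(cfg)
        _, opt = brute_force_best(pair.a, pair.b, "ga", knn_k=5)
        res = sp.run_ipa(
            pair.a, pair.b, sp.BootstrapConfig(seed=0, loss="ga", knn_k=5), n_ipa=2
        )
        assert opt <= res.final_loss + 1e-12


class TestCouplingMonotonicity:
    def test_recovery_improves_with_coupling_strength(self):
        # reduced-scale version: mean recovery non-decreasing in p (2-SE slack)
        means, ses = [], []
        for p in (0.3, 0.9):
            fracs = []
            for seed in range(8):
                cfg = GeneratorConfig(
                    n_species=6, species_size=4, length_a=20, length_b=20,
                    alphabet_size=10, n_coupled=30, coupling=p, seed=200 + seed,
                )
                pair, truth = sp.generate_coupled_pair(cfg)
                res = sp.run_ipa(pair.a, pair.b, sp.BootstrapConfig(seed=seed), n_ipa=2)
                fracs.append(sp.fraction_correct(res.final, truth, pair))
            means.append(np.mean(fracs))
            ses.append(np.std(fracs, ddof=1) / np.sqrt(len(fracs)))
        assert means[1] >= means[0] - 2 * (ses[0] + ses[1])


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="coupling"):
        GeneratorConfig(coupling=1.5)
    with pytest.raises(ValueError, match="n_coupled"):
        GeneratorConfig(length_a=2, length_b=2, n_coupled=5)
    with pytest.raises(ValueError, match="alphabet_size"):
        GeneratorConfig(alphabet_size=1)
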