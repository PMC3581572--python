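import numpy as np
import pytest
from scipy import stats as st

from orthosim import ScenarioConfig, simulate_dataset
from orthosim.evolver import (
    AlignmentTrack,
    TrackedSequence,
    evolve_gene_branch,
    sample_indel_length,
    sample_root_genome,
    simulate_genealogy,
)
from orthosim.phylo import parse_newick
from orthosim.substitution import sample_stationary


TWO_SPECIES = "(A:10,B:10):0;"
THREE_SPECIES = "((A:5,B:5):5,C:10):0;"


class TestRootGenome:
    def test_counts_and_min_length(self, model):
        cfg = ScenarioConfig(n_root_families=200, min_length=50)
        seqs = sample_root_genome(cfg, model, np.random.default_rng(0))
        assert len(seqs) == 200
        assert min(len(s) for s in seqs) >= 50

    def test_tight_gamma_concentrates(self, model):
        # mean 300, sd 3: all draws within +-10 of 300 for thousands of genes
        cfg = ScenarioConfig(
            n_root_families=2000, length_shape=10000.0, length_scale=0.03,
            min_length=1,
        )
        seqs = sample_root_genome(cfg, model, np.random.default_rng(1))
        lengths = np.array([len(s) for s in seqs])
        assert np.all(np.abs(lengths - 300) <= 10)

    def test_determinism(self, model):
        cfg = ScenarioConfig(n_root_families=20)
        a = sample_root_genome(cfg, model, np.random.default_rng(3))
        b = sample_root_genome(cfg, model, np.random.default_rng(3))
        assert a == b


class TestIndelLength:
    def test_lmax_one_is_constant(self):
        rng = np.random.default_rng(0)
        assert all(sample_indel_length(1.821, 1, rng) == 1 for _ in range(100))

    def test_pmf_matches_zipf(self):
        c, lmax, n = 1.821, 50, 10**6
        rng = np.random.default_rng(1)
        draws = np.array([sample_indel_length(c, lmax, rng) for _ in range(n)])
        expected_pmf = np.arange(1, lmax + 1, dtype=float) ** (-c)
        expected_pmf /= expected_pmf.sum()
        observed = np.bincount(draws, minlength=lmax + 1)[1:]
        chi2 = st.chisquare(observed, n * expected_pmf)
        assert chi2.pvalue > 0.01

    def test_mean_matches_closed_form(self):
        c, lmax, n = 1.821, 50, 10**6
        rng = np.random.default_rng(2)
        draws = np.array([sample_indel_length(c, lmax, rng) for _ in range(n)])
        ell = np.arange(1, lmax + 1, dtype=float)
        pmf = ell ** (-c) / np.sum(ell ** (-c))
        mean, var = np.sum(ell * pmf), np.sum(ell**2 * pmf) - np.sum(ell * pmf) ** 2
        assert abs(draws.mean() - mean) < 4 * np.sqrt(var / n)

    def test_invalid_exponent(self):
        with pytest.raises(ValueError):
            sample_indel_length(1.0, 50, np.random.default_rng(0))


class TestBranchEvolution:
    def test_zero_indel_rates_preserve_columns(self, model):
        cfg = ScenarioConfig(ins_rate=0.0, del_rate=0.0)
        seq = sample_stationary(120, model, np.random.default_rng(0))
        ts = TrackedSequence.from_string(seq)
        out = evolve_gene_branch(ts, 50.0, cfg, model, np.random.default_rng(1))
        assert out.columns == ts.columns
        assert len(out.residues) == 120

    def test_insertion_only_never_shrinks(self, model):
        cfg = ScenarioConfig(ins_rate=0.002, del_rate=0.0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            seq = sample_stationary(80, model, rng)
            ts = TrackedSequence.from_string(seq)
            out = evolve_gene_branch(ts, 60.0, cfg, model, rng)
            assert len(out.residues) >= 80

    def test_event_count_matches_analytic_rate(self, model):
        # symmetric rates keep E[L] constant, so E[events] ~ 2*r*L0*b
        r, b, L0, trials = 0.001, 100.0, 300, 400
        cfg = ScenarioConfig(ins_rate=r, del_rate=r, max_indel_len=1)
        rng = np.random.default_rng(3)
        base = sample_stationary(L0, model, rng)
        growth = []
        for _ in range(trials):
            ts = TrackedSequence.from_string(base)
            out = evolve_gene_branch(ts, b, cfg, model, rng)
            # with unit indels, |columns added| counts insertions
            growth.append(out.track._counter - L0)
        mean_ins = np.mean(growth)
        expected = r * L0 * b  # first-order: insertions alone
        assert abs(mean_ins - expected) < 4 * np.sqrt(expected / trials) + 0.05 * expected

    def test_input_not_mutated(self, model):
        cfg = ScenarioConfig(ins_rate=0.005, del_rate=0.005)
        seq = sample_stationary(100, model, np.random.default_rng(4))
        ts = TrackedSequence.from_string(seq)
        before = (list(ts.columns), ts.residues.copy())
        evolve_gene_branch(ts, 40.0, cfg, model, np.random.default_rng(5))
        assert ts.columns == before[0]
        assert np.array_equal(ts.residues, before[1])


class TestGenealogy:
    def test_zero_rates_congruent_with_species_tree(self):
        tree = parse_newick(THREE_SPECIES)
        cfg = ScenarioConfig()
        gt, events = simulate_genealogy(tree, cfg, np.random.default_rng(0), "F0")
        leaves = gt.leaves()
        assert sorted(l.species for l in leaves) == ["A", "B", "C"]
        assert all(n.event == "speciation" for n in gt.internal_nodes())
        assert events == []
        # leaf depths equal species leaf depths
        depths = {l.species: l.depth for l in leaves}
        assert depths == {"A": 10.0, "B": 10.0, "C": 10.0}

    def test_transfer_node_has_two_children(self):
        tree = parse_newick(THREE_SPECIES)
        cfg = ScenarioConfig(lgt_rate=0.02)
        found = 0
        for seed in range(40):
            gt, _ = simulate_genealogy(tree, cfg, np.random.default_rng(seed), "F0")
            if gt is None:
                continue
            for n in gt.internal_nodes():
                if n.event == "transfer":
                    assert len(n.children) == 2
                    found += 1
        assert found > 0

    def test_conservation_against_event_log(self, small_tree):
        """Extant leaves = root lineages + duplications + transfers
        - losses - replacements, with every event weighted by the number of
        species leaves below its branch (an event on an internal branch
        propagates through all later speciations; a transfer and its
        replacement fall on the same recipient branch and cancel)."""
        cfg = ScenarioConfig(
            n_root_families=50, dup_rate=0.004, loss_rate=0.004, lgt_rate=0.002,
        )
        rng = np.random.default_rng(6)
        weight = {
            node.name: sum(1 for _ in node.leaves())
            for node in small_tree.root.preorder()
        }
        n_species = small_tree.n_leaves
        for i in range(50):
            gt, events = simulate_genealogy(small_tree, cfg, rng, f"F{i}")
            expected = n_species
            for e in events:
                if e.event == "duplication":
                    expected += weight[e.species_branch]
                elif e.event == "loss":
                    expected -= weight[e.species_branch]
                elif e.event == "transfer":
                    pass  # adds on the recipient branch ...
                elif e.event == "replaced":
                    pass  # ... and removes on the same branch: net zero
            observed = len(gt.leaves()) if gt is not None else 0
            assert observed == expected

    def test_dup_background_monotone_in_rate(self, small_tree):
        fractions = []
        for rate in (0.002, 0.006, 0.018):
            cfg = ScenarioConfig(n_root_families=300, dup_rate=rate, loss_rate=rate)
            ds = simulate_dataset(
                small_tree, cfg, rng=np.random.default_rng(42),
                evolve_sequences=False,
            )
            genes = list(ds.all_genes())
            fractions.append(sum(g.n_dup >= 1 for g in genes) / len(genes))
        assert fractions[0] < fractions[1] < fractions[2]


class TestDataset:
    def test_zero_rate_two_species(self, model):
        tree = parse_newick(TWO_SPECIES)
        cfg = ScenarioConfig(n_root_families=10)
        ds = simulate_dataset(tree, cfg, rng=np.random.default_rng(0))
        assert len(ds.genomes["A"]) == 10
        assert len(ds.genomes["B"]) == 10
        from orthosim import true_ortholog_pairs

        truth = true_ortholog_pairs(ds.gene_trees.values())
        assert len(truth) == 10  # one cross-species pair per family

    def test_msa_rows_reproduce_sequences(self, dup_dataset):
        seqs = {g.qualified_id: g.sequence for g in dup_dataset.all_genes()}
        n_checked = 0
        for family, (row_ids, rows) in dup_dataset.true_msas.items():
            for rid, row in zip(row_ids, rows):
                assert row.replace("-", "") == seqs[rid]
                n_checked += 1
        assert n_checked == dup_dataset.n_genes()

    def test_every_gene_in_exactly_one_tree_and_msa(self, dup_dataset):
        tree_leaves = [
            f"{l.species}|{l.gene_id}"
            for t in dup_dataset.gene_trees.values()
            for l in t.leaves()
        ]
        assert len(tree_leaves) == len(set(tree_leaves)) == dup_dataset.n_genes()
        msa_rows = [r for ids, _ in dup_dataset.true_msas.values() for r in ids]
        assert sorted(msa_rows) == sorted(tree_leaves)

    def test_genome_size_roughly_constant_with_equal_rates(self, small_tree):
        cfg = ScenarioConfig(n_root_families=400, dup_rate=0.006, loss_rate=0.006)
        ds = simulate_dataset(
            small_tree, cfg, rng=np.random.default_rng(9), evolve_sequences=False
        )
        sizes = [len(g) for g in ds.genomes.values()]
        assert abs(np.mean(sizes) - 400) / 400 < 0.10

    def test_same_seed_reproduces_identically(self, small_tree):
        cfg = ScenarioConfig(n_root_families=15, dup_rate=0.005, loss_rate=0.005)
        d1 = simulate_dataset(small_tree, cfg, rng=np.random.default_rng(5))
        d2 = simulate_dataset(small_tree, cfg, rng=np.random.default_rng(5))
        s1 = [(g.qualified_id, g.sequence) for g in d1.all_genes()]
        s2 = [(g.qualified_id, g.sequence) for g in d2.all_genes()]
        assert s1 == s2

    def test_zero_rate_gap_free(self, small_tree):
        cfg = ScenarioConfig(n_root_families=10, ins_rate=0.0, del_rate=0.0)
        ds = simulate_dataset(small_tree, cfg, rng=np.random.default_rng(12))
        from orthosim import dataset_statistics

        assert dataset_statistics(ds).gap_fraction == 0.0
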