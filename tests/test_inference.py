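import itertools

import numpy as np
import pytest

from orthosim import ScenarioConfig, simulate_dataset
from orthosim.inference import (
    AlignmentResult,
    Hit,
    HitTable,
    all_vs_all,
    bbh,
    default_scoring,
    rsd,
    smith_waterman,
)
from orthosim.phylo import parse_newick
from orthosim.substitution import DistanceEstimate, sample_stationary
from orthosim.truth import true_ortholog_pairs


def brute_force_local_score(a, b, scoring):
    """Exhaustive enumeration of all local alignments (lengths <= 5).

    A local alignment is a pair of equal-size strictly increasing index
    tuples; gaps between consecutive matched columns pay affine costs in
    each sequence independently.  The empty alignment scores 0.
    """
    M = scoring.matrix
    alpha = "ARNDCQEGHILKMFPSTWYVX"
    idx = {c: i for i, c in enumerate(alpha)}

    def gap_cost(g):
        return 0.0 if g == 0 else scoring.gap_open + (g - 1) * scoring.gap_extend

    best = 0.0
    na, nb = len(a), len(b)
    for k in range(1, min(na, nb) + 1):
        for ai in itertools.combinations(range(na), k):
            for bi in itertools.combinations(range(nb), k):
                score = sum(M[idx[a[i]], idx[b[j]]] for i, j in zip(ai, bi))
                for t in range(k - 1):
                    score -= gap_cost(ai[t + 1] - ai[t] - 1)
                    score -= gap_cost(bi[t + 1] - bi[t] - 1)
                best = max(best, score)
    return best


class TestSmithWaterman:
    def test_self_alignment_is_diagonal_sum(self, model):
        scoring = default_scoring()
        seq = sample_stationary(40, model, np.random.default_rng(0))
        res = smith_waterman(seq, seq, scoring)
        alpha = "ARNDCQEGHILKMFPSTWYVX"
        idx = {c: i for i, c in enumerate(alpha)}
        expected = sum(scoring.matrix[idx[c], idx[c]] for c in seq)
        assert res.score == pytest.approx(expected)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACD")

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_short_pairs(self, seed):
        """100 random pairs of length <= 5 against exhaustive enumeration."""
        scoring = default_scoring()
        rng = np.random.default_rng(seed)
        alpha = "ARNDCQEGHILKMFPSTWYV"
        for _ in range(25):
            a = "".join(alpha[i] for i in rng.integers(0, 20, rng.integers(1, 6)))
            b = "".join(alpha[i] for i in rng.integers(0, 20, rng.integers(1, 6)))
            res = smith_waterman(a, b, scoring)
            assert res.score == pytest.approx(
                brute_force_local_score(a, b, scoring)
            ), (a, b)

    def test_score_symmetry(self, model):
        scoring = default_scoring()
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = sample_stationary(30, model, rng)
            b = sample_stationary(25, model, rng)
            assert smith_waterman(a, b, scoring).score == pytest.approx(
                smith_waterman(b, a, scoring).score
            )

    def test_x_columns_excluded_from_normalisation_and_pairs(self, model):
        scoring = default_scoring()
        seq = sample_stationary(60, model, np.random.default_rng(6))
        masked = seq[:20] + "X" * 10 + seq[30:]
        res = smith_waterman(seq, masked, scoring)
        assert all(ca != "X" and cb != "X" for ca, cb in res.residue_pairs)
        # X scores zero, so the masked self-alignment scores lower but the
        # non-X characters still dominate
        full = smith_waterman(seq, seq, scoring)
        assert res.score < full.score


def table_from_scores(scores, distances=None):
    """Build a 1-genome-pair HitTable from a dense score matrix."""
    table = HitTable()
    n, m = scores.shape
    for i in range(n):
        for j in range(m):
            res = AlignmentResult(
                score=float(scores[i, j]), normalized_score=0.0, aligned_columns=1
            )
            if distances is not None:
                res.distance = DistanceEstimate(
                    d_hat=float(distances[i, j]), variance=0.0, loglik=0.0
                )
            table.add("A", "B", Hit(f"A|{i}", f"B|{j}", res))
    return table


def reciprocal_oracle(values, minimize=False):
    """Double-loop argmax/argmin with strict-uniqueness ties."""
    v = -values if minimize else values
    out = set()
    for i in range(v.shape[0]):
        row = v[i]
        j = int(np.argmax(row))
        if (row == row[j]).sum() > 1:
            continue
        col = v[:, j]
        if (col == col[i]).sum() > 1:
            continue
        if int(np.argmax(col)) == i:
            out.add((f"A|{i}", f"B|{j}"))
    return out


class TestBBHAndRSD:
    def test_single_hit_table(self):
        table = table_from_scores(np.array([[99.0]]))
        assert set(map(tuple, bbh(table))) == {("A|0", "B|0")}

    @pytest.mark.parametrize("seed", range(4))
    def test_bbh_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            scores = rng.integers(0, 50, size=(5, 5)).astype(float)
            got = {tuple(sorted(p)) for p in bbh(table_from_scores(scores))}
            want = {tuple(sorted(p)) for p in reciprocal_oracle(scores)}
            assert got == want

    @pytest.mark.parametrize("seed", range(4))
    def test_rsd_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed + 100)
        for _ in range(25):
            d = rng.integers(1, 50, size=(5, 5)).astype(float)
            scores = np.full_like(d, 100.0)
            got = {
                tuple(sorted(p))
                for p in rsd(table_from_scores(scores, distances=d))
            }
            want = {tuple(sorted(p)) for p in reciprocal_oracle(d, minimize=True)}
            assert got == want

    def test_exact_tie_emits_no_pair(self):
        scores = np.array([[10.0, 10.0], [3.0, 2.0]])
        pairs = bbh(table_from_scores(scores))
        assert ("A|0", "B|0") not in pairs and ("A|0", "B|1") not in pairs

    def test_rsd_equals_bbh_when_orders_agree(self):
        rng = np.random.default_rng(9)
        scores = rng.uniform(50, 150, size=(6, 6))
        distances = 200.0 - scores  # perfectly anti-monotone: same ranking
        t1 = table_from_scores(scores)
        t2 = table_from_scores(scores, distances=distances)
        assert set(map(tuple, bbh(t1))) == set(map(tuple, rsd(t2)))


class TestAllVsAll:
    def test_two_identical_genomes_single_hit(self, model):
        seq = sample_stationary(120, model, np.random.default_rng(0))
        from orthosim.evolver import Gene

        genomes = {
            "A": [Gene("A", "g1", "F0", seq)],
            "B": [Gene("B", "g1", "F0", seq)],
        }
        table = all_vs_all(genomes)
        assert len(table) == 1
        assert table.hits("A", "B")[0].gene_a == "A|g1"
        assert table.hits("B", "A")[0].gene_a == "B|g1"

    def test_infinite_threshold_empty(self, model):
        seq = sample_stationary(100, model, np.random.default_rng(1))
        from orthosim.evolver import Gene

        genomes = {
            "A": [Gene("A", "g1", "F0", seq)],
            "B": [Gene("B", "g1", "F0", seq)],
        }
        assert len(all_vs_all(genomes, threshold=np.inf)) == 0

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            all_vs_all({"A": []})

    def test_top_hit_is_true_ortholog_without_gene_events(self):
        tree = parse_newick("((A:6,B:6):4,C:10):0;")
        cfg = ScenarioConfig(n_root_families=20)
        ds = simulate_dataset(tree, cfg, rng=np.random.default_rng(2))
        table = all_vs_all(ds)  # full all-pairs, no family restriction
        truth = true_ortholog_pairs(ds.gene_trees.values())
        pred = bbh(table)
        assert set(map(tuple, pred)) == set(map(tuple, truth))

    def test_family_restriction_matches_full_search(self):
        tree = parse_newick("(A:8,B:8):0;")
        cfg = ScenarioConfig(n_root_families=15)
        ds = simulate_dataset(tree, cfg, rng=np.random.default_rng(3))
        full = bbh(all_vs_all(ds))
        fast = bbh(all_vs_all(ds, within_families=True))
        assert set(map(tuple, full)) == set(map(tuple, fast))
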