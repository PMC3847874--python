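import itertools

import numpy as np
import pandas as pd
import pytest

from prognet import (
    ConsensusNetwork,
    ExpressionMatrix,
    MIThreshold,
    NetworkEdge,
    ProbeGeneMap,
    PrognetError,
    apply_dpi,
    bootstrap_consensus,
    collapse_probes,
    edge_recovery,
    infer_single_network,
    mi_threshold,
)


def _thr(value):
    return MIThreshold(alpha=0.05, n_tests=1, threshold_mi=value, null_tail_params=(0, 1))


def _pairs(edges):
    return {frozenset((e.regulator, e.target)) for e in edges}


class TestDPI:
    def test_weakest_triangle_edge_removed(self):
        edges = [NetworkEdge("A", "B", 0.5), NetworkEdge("B", "C", 0.4),
                 NetworkEdge("A", "C", 0.2)]
        kept = _pairs(apply_dpi(edges, 0.0))
        assert frozenset(("A", "C")) not in kept
        assert frozenset(("A", "B")) in kept and frozenset(("B", "C")) in kept

    def test_exact_ties_survive(self):
        edges = [NetworkEdge("A", "B", 0.4), NetworkEdge("B", "C", 0.4),
                 NetworkEdge("A", "C", 0.4)]
        assert len(apply_dpi(edges, 0.0)) == 3

    def _brute_force(self, edges, epsilon):
        mi = {frozenset((e.regulator, e.target)): e.mi for e in edges}
        nodes = {n for p in mi for n in p}
        doomed = set()
        for i, j, k in itertools.combinations(sorted(nodes), 3):
            tri = [frozenset((i, j)), frozenset((i, k)), frozenset((j, k))]
            if not all(p in mi for p in tri):
                continue
            for p in tri:
                others = [q for q in tri if q != p]
                if mi[p] < min(mi[q] for q in others) * (1 - epsilon):
                    doomed.add(p)
        return {p for p in mi if p not in doomed}

    @pytest.mark.parametrize("epsilon", [0.0, 0.15])
    def test_matches_exhaustive_triangle_oracle(self, epsilon):
        """100 random 15-node graphs against brute-force triplet enumeration."""
        r = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(15)]
        for _ in range(100):
            edges = [
                NetworkEdge(a, b, float(r.uniform(0.05, 1.0)))
                for a, b in itertools.combinations(nodes, 2)
                if r.random() < 0.35
            ]
            got = _pairs(apply_dpi(edges, epsilon))
            assert got == self._brute_force(edges, epsilon)

    def test_subset_and_idempotent(self, rng):
        nodes = [f"n{i}" for i in range(10)]
        edges = [NetworkEdge(a, b, float(rng.uniform(0.05, 1)))
                 for a, b in itertools.combinations(nodes, 2) if rng.random() < 0.5]
        once = apply_dpi(edges, 0.0)
        assert _pairs(once) <= _pairs(edges)
        assert _pairs(apply_dpi(once, 0.0)) == _pairs(once)


class TestSingleNetwork:
    def _matrix(self, rows, samples=None):
        n = len(next(iter(rows.values())))
        cols = samples or [f"s{i}" for i in range(n)]
        return ExpressionMatrix(pd.DataFrame(rows, index=cols).T.astype(float))

    def test_indirect_chain_edge_pruned_by_dpi(self, rng):
        """TF1 -> TF2 -> gene: the indirect TF1-gene link must vanish."""
        n = 300
        tf1 = rng.normal(size=n)
        tf2 = tf1 + rng.normal(scale=0.1, size=n)
        gene = tf2 + rng.normal(scale=0.1, size=n)
        expr = self._matrix({"TF1": tf1, "TF2": tf2, "G": gene})
        edges = infer_single_network(expr, ["TF1", "TF2"], _thr(0.05), 0.0)
        kept = _pairs(edges)
        assert frozenset(("TF1", "G")) not in kept
        assert frozenset(("TF1", "TF2")) in kept
        assert frozenset(("TF2", "G")) in kept

    def test_infinite_threshold_empty_network(self, rng):
        expr = self._matrix({"TF1": rng.normal(size=50), "G": rng.normal(size=50)})
        assert infer_single_network(expr, ["TF1"], _thr(np.inf)) == []

    def test_empty_tf_list_rejected(self, rng):
        expr = self._matrix({"G": rng.normal(size=50)})
        with pytest.raises(PrognetError):
            infer_single_network(expr, [], _thr(0.1))

    def test_absent_tfs_dropped_with_warning(self, rng, caplog):
        expr = self._matrix({"TF1": rng.normal(size=50), "G": rng.normal(size=50)})
        with caplog.at_level("WARNING"):
            infer_single_network(expr, ["TF1", "TFX"], _thr(np.inf))
        assert "TFX" in caplog.text


class TestBootstrapConsensus:
    def test_recovery_on_planted_structure(self, study):
        cfg, bundle = study
        truth = bundle["truth"]
        expr = bundle["cohorts"]["discovery"]["expression"]
        net = bootstrap_consensus(expr, truth.tf_ids, B=25, seed=cfg.seed)
        precision, recall = edge_recovery(net, truth.edge_pairs)
        assert precision >= 0.8
        assert recall >= 0.6

    def test_support_counts_reproducible(self, study):
        cfg, bundle = study
        truth = bundle["truth"]
        expr = bundle["cohorts"]["discovery"]["expression"]
        a = bootstrap_consensus(expr, truth.tf_ids, B=5, seed=9, n_perm=500)
        b = bootstrap_consensus(expr, truth.tf_ids, B=5, seed=9, n_perm=500)
        assert {(e.pair, e.support, e.mi) for e in a.edges} == \
               {(e.pair, e.support, e.mi) for e in b.edges}

    def test_edge_set_shrinks_as_alpha_decreases(self, study):
        cfg, bundle = study
        truth = bundle["truth"]
        expr = bundle["cohorts"]["discovery"]["expression"]
        loose = bootstrap_consensus(expr, truth.tf_ids, B=10, alpha=0.2, seed=2, n_perm=500)
        strict = bootstrap_consensus(expr, truth.tf_ids, B=10, alpha=0.001, seed=2, n_perm=500)
        assert _pairs(strict.edges) <= _pairs(loose.edges)

    def test_too_few_samples_rejected(self, rng):
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(3, 5)), index=["TF1", "a", "b"],
            columns=[f"s{i}" for i in range(5)]))
        with pytest.raises(PrognetError):
            bootstrap_consensus(expr, ["TF1"], B=5)


class TestConsensusVote:
    """The binomial consensus rule on hand-built support patterns."""

    def _run(self, support, B, n_pairs, occurrences):
        from scipy import stats
        p_hat = occurrences / (B * n_pairs)
        return stats.binom.sf(support - 1, B, p_hat) < 0.05 / n_pairs

    def test_unanimous_vote_retained(self):
        assert self._run(support=100, B=100, n_pairs=50, occurrences=150)

    def test_single_vote_rejected_under_high_rate(self):
        assert not self._run(support=1, B=100, n_pairs=10, occurrences=50)


class TestCollapseProbes:
    def test_max_rule_across_probes(self):
        net = ConsensusNetwork(
            [NetworkEdge("p1", "q1", 0.3, 2), NetworkEdge("p2", "q1", 0.5, 1)],
            B=10, level="probe")
        pmap = ProbeGeneMap([("p1", "G1"), ("p2", "G1"), ("q1", "G2")])
        out = collapse_probes(net, pmap)
        assert len(out.edges) == 1
        edge = out.edges[0]
        assert edge.pair == ("G1", "G2")
        assert edge.mi == pytest.approx(0.5)
        assert edge.support == 2
        assert out.level == "gene"

    def test_same_gene_probe_pair_dropped(self):
        net = ConsensusNetwork([NetworkEdge("p1", "p2", 0.4)], B=1, level="probe")
        pmap = ProbeGeneMap([("p1", "G1"), ("p2", "G1")])
        assert collapse_probes(net, pmap).edges == []

    def test_unmapped_probe_rejected(self):
        net = ConsensusNetwork([NetworkEdge("p1", "q9", 0.4)], B=1, level="probe")
        with pytest.raises(PrognetError, match="q9"):
            collapse_probes(net, ProbeGeneMap([("p1", "G1")]))

    def test_matches_groupby_oracle(self, rng):
        """Random probe multiplicities vs an independent pandas group-by."""
        genes = [f"G{i}" for i in range(8)]
        probes = [(f"p{i}", genes[int(rng.integers(0, 8))]) for i in range(30)]
        pmap = ProbeGeneMap(probes)
        gene_of = pmap.gene_of
        edges = []
        seen = set()
        for _ in range(120):
            a, b = rng.choice(30, size=2, replace=False)
            pa, pb = probes[a][0], probes[b][0]
            if (pa, pb) in seen:
                continue
            seen.add((pa, pb))
            edges.append(NetworkEdge(pa, pb, float(rng.uniform(0.1, 1)), int(rng.integers(1, 9))))
        net = ConsensusNetwork(edges, B=10, level="probe")
        out = collapse_probes(net, pmap)
        frame = pd.DataFrame(
            [(gene_of[e.regulator], gene_of[e.target], e.mi, e.support) for e in edges],
            columns=["r", "t", "mi", "s"])
        frame = frame[frame.r != frame.t]
        oracle = frame.groupby(["r", "t"]).agg(mi=("mi", "max"), s=("s", "max"))
        assert len(out.edges) == len(oracle)
        for e in out.edges:
            row = oracle.loc[(e.regulator, e.target)]
            assert e.mi == pytest.approx(row["mi"])
            assert e.support == row["s"]
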