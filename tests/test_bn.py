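import math

import numpy as np
import pytest
from scipy import stats

from qtlpath.bn import (
    DAG,
    GaussianScorer,
    MCMCConfig,
    consensus_network,
    exhaustive_posterior,
    legal_moves,
    node_score,
    propose_move,
    run_mcmc,
)
from qtlpath.sem import SEMSpec, generate_sem_population


@pytest.fixture(scope="module")
def chain_sem():
    """Q1 -> Y1 -> Y2 with beta = gamma = 1."""
    spec = SEMSpec(
        n=1000, loci=1, mu=[0.0, 0.0], beta=[[1.0, 0.0]],
        gamma=[[0.0, 1.0], [0.0, 0.0]], sigma=[1.0, 1.0], seed=3,
    )
    return generate_sem_population(spec)


@pytest.fixture(scope="module")
def chain_posterior(chain_sem):
    return run_mcmc(chain_sem, MCMCConfig(n_iter=30_000, seed=5))


class TestDAG:
    def test_from_edges_rejects_cycle(self):
        with pytest.raises(ValueError, match="cycle"):
            DAG.from_edges([], ["a", "b"], [("a", "b"), ("b", "a")])

    def test_from_edges_rejects_genotype_child(self):
        with pytest.raises(ValueError, match="genotype"):
            DAG.from_edges(["Q1"], ["a"], [("a", "Q1")])

    def test_key_canonical(self):
        d1 = DAG.from_edges(["Q1"], ["a", "b"], [("Q1", "a"), ("a", "b")])
        d2 = DAG.from_edges(["Q1"], ["a", "b"], [("a", "b"), ("Q1", "a")])
        assert d1.key() == d2.key()


class TestNodeScore:
    def test_empty_parents_closed_form(self, chain_sem):
        # marginal Gaussian MLE log-likelihood minus BIC penalty
        y = chain_sem.frame["Y1"].to_numpy()
        n = len(y)
        sigma2 = y.var()
        expected = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1) - 0.5 * math.log(n) * 2
        assert node_score(chain_sem, "Y1", frozenset()) == pytest.approx(
            expected, abs=1e-8
        )

    def test_true_parent_improves_score(self, chain_sem):
        scorer = GaussianScorer(chain_sem)
        with_y1 = scorer.node_score("Y2", frozenset({"Y1", "Q1"}))
        without = scorer.node_score("Y2", frozenset({"Q1"}))
        assert with_y1 > without

    def test_decomposability_exact(self, chain_sem):
        scorer = GaussianScorer(chain_sem, lambda_=0.7)
        g1 = DAG.from_edges(["Q1"], ["Y1", "Y2"], [("Q1", "Y1")])
        g2 = DAG.from_edges(["Q1"], ["Y1", "Y2"], [("Q1", "Y1"), ("Y1", "Y2")])
        total_diff = scorer.graph_score(g2) - scorer.graph_score(g1)
        node_diff = (
            scorer.node_score("Y2", frozenset({"Y1"}))
            - scorer.node_score("Y2", frozenset())
            - 0.7
        )
        assert total_diff == pytest.approx(node_diff, abs=1e-12)

    def test_genotype_node_constant(self, chain_sem):
        assert node_score(chain_sem, "Q1", frozenset()) == 0.0

    def test_self_parent_rejected(self, chain_sem):
        with pytest.raises(ValueError):
            node_score(chain_sem, "Y1", frozenset({"Y1"}))

    def test_duplicate_collinear_parent_rejected(self, chain_sem):
        ds = chain_sem
        frame = ds.frame.copy()
        frame["Y3"] = frame["Y1"]
        from qtlpath.dataset import MQTLDataset

        dup = MQTLDataset(
            frame, genotype_columns=["Q1"], epistasis_columns=[],
            metabolite_columns=["Y1", "Y2", "Y3"],
        )
        with pytest.raises(ValueError, match="singular"):
            GaussianScorer(dup).node_score("Y2", frozenset({"Y1", "Y3"}))


class TestProposeMove:
    def test_proposals_always_acyclic_and_exogenous(self, chain_sem):
        rng = np.random.default_rng(0)
        dag = DAG.empty(["Q1"], ["Y1", "Y2"])
        for _ in range(10_000):
            new, move, _ = propose_move(dag, rng)
            assert new.is_acyclic()
            for u, v in new.edges():
                assert new.node_types[v] == "metabolite"
            dag = new

    def test_uniform_over_enumerated_moves(self):
        dag = DAG.from_edges(["Q1"], ["Y1", "Y2"], [("Y1", "Y2")])
        moves = legal_moves(dag)
        rng = np.random.default_rng(1)
        counts = dict.fromkeys(moves, 0)
        draws = 50_000
        for _ in range(draws):
            _, move, _ = propose_move(dag, rng)
            counts[move] += 1
        observed = np.array([counts[m] for m in moves])
        chi2 = ((observed - draws / len(moves)) ** 2 / (draws / len(moves))).sum()
        p = stats.chi2.sf(chi2, df=len(moves) - 1)
        assert p > 1e-3

    def test_hastings_ratio_matches_move_counts(self):
        dag = DAG.empty(["Q1"], ["Y1", "Y2"])
        rng = np.random.default_rng(2)
        new, move, log_ratio = propose_move(dag, rng)
        expected = math.log(len(legal_moves(dag))) - math.log(len(legal_moves(new)))
        assert log_ratio == pytest.approx(expected)

    def test_max_parents_respected(self):
        dag = DAG.from_edges(
            ["Q1", "Q2", "Q3"], ["Y1"], [("Q1", "Y1"), ("Q2", "Y1"), ("Q3", "Y1")]
        )
        moves = legal_moves(dag, max_parents=3)
        assert all(kind != "add" for kind, _, _ in moves)


class TestExhaustivePosterior:
    def test_two_node_count(self, chain_sem):
        from qtlpath.dataset import MQTLDataset

        frame = chain_sem.frame[["Y1", "Y2"]].copy()
        ds = MQTLDataset(
            frame, genotype_columns=[], epistasis_columns=[],
            metabolite_columns=["Y1", "Y2"],
        )
        graph_probs, _ = exhaustive_posterior(ds)
        assert len(graph_probs) == 3  # empty, a->b, b->a

    def test_probabilities_normalized(self, chain_sem):
        graph_probs, _ = exhaustive_posterior(chain_sem)
        assert sum(graph_probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_node_limit(self, motif_dataset):
        ds = motif_dataset("linear", seed=0)
        with pytest.raises(ValueError, match="exceed"):
            exhaustive_posterior(ds)


class TestRunMCMC:
    def test_large_lambda_gives_empty_map(self, chain_sem):
        post = run_mcmc(
            chain_sem, MCMCConfig(n_iter=2000, seed=0, lambda_=1e6)
        )
        assert post.map_graph.n_edges == 0

    def test_planted_edge_recovered_in_both_chains(self, chain_posterior):
        for chain in chain_posterior.chains:
            assert chain.edge_frequencies.get(("Y1", "Y2"), 0.0) > 0.8

    def test_convergence_correlation(self, chain_posterior):
        assert chain_posterior.convergence_correlation() > 0.9

    def test_matches_exhaustive_oracle(self, chain_sem, chain_posterior):
        _, exact = exhaustive_posterior(chain_sem)
        freqs = chain_posterior.edge_frequencies()
        for edge, p in exact.items():
            assert abs(freqs.get(edge, 0.0) - p) < 0.05

    def test_acceptance_rates_recorded(self, chain_posterior):
        for chain in chain_posterior.chains:
            assert 0.0 <= chain.acceptance_rate <= 1.0

    def test_deterministic_given_seed(self, chain_sem):
        a = run_mcmc(chain_sem, MCMCConfig(n_iter=3000, seed=9))
        b = run_mcmc(chain_sem, MCMCConfig(n_iter=3000, seed=9))
        assert a.map_graph.key() == b.map_graph.key()
        assert a.edge_frequencies() == b.edge_frequencies()

    def test_uniform_proposal_mode_also_exact(self, chain_sem):
        post = run_mcmc(
            chain_sem,
            MCMCConfig(n_iter=60_000, seed=2, proposal="uniform"),
        )
        _, exact = exhaustive_posterior(chain_sem)
        freqs = post.edge_frequencies()
        for edge, p in exact.items():
            assert abs(freqs.get(edge, 0.0) - p) < 0.05


class TestConsensusNetwork:
    def test_k1_equals_map(self, chain_sem, chain_posterior):
        consensus = consensus_network(chain_posterior, chain_sem, k=1)
        edges = {(e.parent, e.child) for e in consensus.edges}
        assert edges == set(chain_posterior.map_graph.key())
        assert all(e.frequency == 1.0 for e in consensus.edges)

    def test_frequencies_in_unit_interval(self, chain_sem, chain_posterior):
        consensus = consensus_network(chain_posterior, chain_sem, k=10)
        assert all(0.0 < e.frequency <= 1.0 for e in consensus.edges)

    def test_planted_coefficient_recovered(self, chain_sem, chain_posterior):
        consensus = consensus_network(chain_posterior, chain_sem, k=10)
        edge = consensus.edge_dict().get(("Y1", "Y2"))
        assert edge is not None
        assert edge.mean_coefficient == pytest.approx(1.0, abs=0.1)

    def test_warns_when_fewer_graphs(self, chain_sem):
        post = run_mcmc(chain_sem, MCMCConfig(n_iter=500, seed=0, lambda_=1e6))
        with pytest.warns(UserWarning, match="distinct"):
            consensus_network(post, chain_sem, k=10)

    def test_tsv_and_dot_export(self, chain_sem, chain_posterior, tmp_path):
        consensus = consensus_network(chain_posterior, chain_sem, k=10)
        tsv = tmp_path / "c.tsv"
        dot = tmp_path / "c.dot"
        consensus.to_tsv(tsv)
        consensus.to_dot(dot)
        lines = tsv.read_text().strip().splitlines()
        assert lines[0] == "child\tparent\tfrequency\tmean_coefficient"
        assert len(lines) == len(consensus.edges) + 1
        assert dot.read_text().startswith("digraph")


class TestLikelihoodEquivalenceAmbiguity:
    def test_shared_qtl_no_confident_direction(self):
        # two traits driven by one QTL with equal effects and no
        # propagation: the trait-trait edge direction must stay ambiguous
        for seed in range(10):
            spec = SEMSpec(
                n=400, loci=1, mu=[0.0, 0.0], beta=[[1.0, 1.0]],
                gamma=[[0.0, 0.0], [0.0, 0.0]], sigma=[1.0, 1.0], seed=seed,
            )
            ds = generate_sem_population(spec)
            post = run_mcmc(ds, MCMCConfig(n_iter=5000, seed=seed))
            consensus = consensus_network(post, ds, k=10)
            for e in consensus.edges:
                if e.parent.startswith("Y") and e.child.startswith("Y"):
                    assert e.frequency <= 0.7
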