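"""Parsimony networks: distances, connection limit, MSN assembly."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ribopool.network import (
    build_network,
    connection_limit,
    mutational_steps,
    parsimony_probability,
    subnetwork_membership,
    write_graphml,
    write_json,
)
from ribopool.pooling import Ribotype, SamplePool, classify, label_ribotypes
from ribopool.synth import make_ribotype_family


# ---------------------------------------------------------------------------
# oracles

def dijkstra_alignment_steps(a, b):
    """Independent alignment oracle: shortest path over the edit lattice.

    States are (i, j, last_move).  The primary objective is the ordinary
    unit edit cost (substitution 1, every gapped position 1) and the
    secondary objective the mutational step count (substitution 1, gap
    open 1, gap extension 0); both are folded into one scalar weight
    (edit * BIG + steps) so Dijkstra minimises them lexicographically.
    Solved on an explicit graph rather than the DP recurrence used by the
    library.
    """
    BIG = 10_000
    g = nx.DiGraph()
    n, m = len(a), len(b)
    for i in range(n + 1):
        for j in range(m + 1):
            for move in ("M", "X", "Y"):
                if i < n and j < m:
                    cost = 0 if a[i] == b[j] else 1
                    g.add_edge((i, j, move), (i + 1, j + 1, "M"),
                               weight=cost * BIG + cost)
                if i < n:
                    open_cost = 0 if move == "X" else 1
                    g.add_edge((i, j, move), (i + 1, j, "X"),
                               weight=BIG + open_cost)
                if j < m:
                    open_cost = 0 if move == "Y" else 1
                    g.add_edge((i, j, move), (i, j + 1, "Y"),
                               weight=BIG + open_cost)
    ends = [(n, m, mv) for mv in "MXY"]
    best = min(
        nx.dijkstra_path_length(g, (0, 0, "M"), e) for e in ends if g.has_node(e)
    )
    return best % BIG


def brute_force_msn_length(seqs, limit):
    """Total path length of the minimum spanning network, truncated at limit.

    A pair at distance d is included iff its endpoints are not connected
    using pairs of distance < d; all tying pairs at a distance are
    included.  Recomputed from scratch with networkx connectivity checks.
    """
    n = len(seqs)
    dist = {(i, j): mutational_steps(seqs[i], seqs[j])
            for i, j in itertools.combinations(range(n), 2)}
    total = 0
    included = []
    for d in sorted(set(dist.values())):
        if d > limit:
            break
        # connectivity may only use pairs of strictly smaller distance
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(included)
        at_d = [pair for pair, dd in sorted(dist.items()) if dd == d]
        total += sum(d for i, j in at_d if not nx.has_path(g, i, j))
        included.extend(at_d)
    return total


def pool_from_seqs(seqs, sample_id="s", count=100):
    total = count * len(seqs)
    pool = SamplePool(
        sample_id=sample_id,
        total_reads=total,
        ribotypes=[Ribotype(sequence=s, count=count + i) for i, s in enumerate(seqs)],
    )
    return label_ribotypes(classify(pool), sample_id.upper())


# ---------------------------------------------------------------------------
# mutational steps

class TestMutationalSteps:
    def test_identity_and_single_substitution(self):
        assert mutational_steps("ACGT", "ACGT") == 0
        assert mutational_steps("ACGT", "ACGA") == 1

    def test_planted_substitutions_plus_contiguous_insertion(self):
        base = "ACGTACGTACGTACGTACGT"  # 20 nt
        mutated = list(base)
        mutated[2] = "T"
        mutated[9] = "A"
        mutated[15] = "C"
        with_insert = "".join(mutated[:12]) + "GG" + "".join(mutated[12:])
        assert mutational_steps(base, with_insert) == 4  # 3 subs + 1 gap event

    def test_symmetry_and_zero_iff_identical(self):
        a, b = "ACGTAAC", "ACGTTTAAC"
        assert mutational_steps(a, b) == mutational_steps(b, a)
        assert mutational_steps(a, a) == 0
        assert mutational_steps(a, b) > 0

    @pytest.mark.parametrize("seed", range(8))
    def test_alignment_matches_dijkstra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 14)))
        b = "".join(rng.choice(list("ACGT"), size=rng.integers(6, 14)))
        if len(a) == len(b):
            b += "A"
        assert mutational_steps(a, b) == dijkstra_alignment_steps(a, b)

    def test_gap_exclude_mode_counts_substitutions_only(self):
        base = "ACGTACGTACGTACGTACGT"
        with_insert = base[:10] + "GGG" + base[10:]
        assert mutational_steps(base, with_insert, gap_mode="step") == 1
        assert mutational_steps(base, with_insert, gap_mode="exclude") == 0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            mutational_steps("", "ACGT")


# ---------------------------------------------------------------------------
# connection limit

class TestConnectionLimit:
    def test_extreme_confidence_forces_single_steps(self):
        assert connection_limit(450, confidence=1 - 1e-12) == 1

    def test_monotone_in_sequence_length(self):
        limits = [connection_limit(L) for L in range(100, 1100, 100)]
        assert limits == sorted(limits)
        assert connection_limit(600) >= connection_limit(300)

    def test_deterministic(self):
        assert connection_limit(450) == connection_limit(450)

    def test_probability_monotone_decreasing_in_steps(self):
        probs = [parsimony_probability(j, 450) for j in range(1, 15)]
        assert probs == sorted(probs, reverse=True)
        assert parsimony_probability(0, 450) == 1.0

    def test_probability_matches_monte_carlo_of_generative_model(self):
        # simulate the substitution model directly: per-site Poisson hit
        # counts with Jukes-Cantor base changes; the closed form for
        # P(site differs) and P(exactly one hit | differs) must agree
        rng = np.random.default_rng(2024)
        for lam in (0.01, 0.03, 0.08):
            n = 400_000
            hits = rng.poisson(lam, size=n)
            state = np.zeros(n, dtype=np.int64)
            active = hits.copy()
            while active.max(initial=0) > 0:
                mask = active > 0
                state[mask] = (state[mask] + rng.integers(1, 4, size=mask.sum())) % 4
                active[mask] -= 1
            differs = state != 0
            p_mc = differs.mean()
            p_closed = 0.75 * (1 - np.exp(-4 * lam / 3))
            assert abs(p_mc - p_closed) < 3 * np.sqrt(p_closed * (1 - p_closed) / n)
            cond_mc = (differs & (hits == 1)).sum() / differs.sum()
            cond_closed = lam * np.exp(-lam) / p_closed
            assert abs(cond_mc - cond_closed) < 4 * np.sqrt(cond_closed / differs.sum())

    def test_limit_agrees_with_independent_high_precision_recomputation(self):
        import sympy

        m = 450
        j = 1
        while True:
            p = sympy.Rational(j + 1, m)
            lam = -sympy.Rational(3, 4) * sympy.log(1 - sympy.Rational(4, 3) * p)
            P = (lam * sympy.exp(-lam) / p) ** (j + 1)
            if float(P.evalf(30)) >= 0.95:
                j += 1
            else:
                break
        assert connection_limit(450, 0.95) == j

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            connection_limit(450, confidence=0.4)
        with pytest.raises(ValueError):
            connection_limit(450, confidence=1.0)
        with pytest.raises(ValueError):
            connection_limit(30)


# ---------------------------------------------------------------------------
# network assembly

class TestBuildNetwork:
    def test_single_ribotype(self):
        fam = make_ribotype_family(100, 1, [], seed=1)
        net = build_network([pool_from_seqs([fam[0].sequence])])
        assert len(net.nodes) == 1
        assert net.edges == ()
        assert len(net.subnetworks) == 1

    def test_two_step_join_inserts_one_inferred_node(self):
        fam = make_ribotype_family(100, 3, [1, 2], seed=3)
        seqs = [m.sequence for m in fam]  # chain: d(0,1)=1, d(1,2)=2, d(0,2)=3
        net = build_network([pool_from_seqs(seqs)])
        kinds = [n.kind for n in net.nodes.values()]
        assert kinds.count("observed") == 3
        assert kinds.count("inferred") == 1  # one intermediate on the 2-step join
        assert net.total_steps == 3  # 1-step edge + a 2-step path
        assert len(net.subnetworks) == 1
        inferred = [n for n in net.nodes.values() if n.kind == "inferred"]
        g = net.graph
        assert all(g.degree(n.node_id) >= 2 for n in inferred)

    def test_multi_step_join_has_d_minus_1_intermediates(self):
        fam = make_ribotype_family(200, 2, [4], seed=4)
        net = build_network([pool_from_seqs([m.sequence for m in fam])])
        kinds = [n.kind for n in net.nodes.values()]
        assert kinds.count("inferred") == 3
        assert net.total_steps == 4

    def test_pairs_beyond_limit_stay_disconnected(self):
        fam = make_ribotype_family(450, 2, [30], seed=5)
        net = build_network([pool_from_seqs([m.sequence for m in fam])])
        assert net.connection_limit < 30
        assert len(net.subnetworks) == 2
        assert net.edges == ()

    def test_observed_edges_span_exactly_one_step(self):
        fam = make_ribotype_family(120, 5, [1, 1, 2, 3], seed=6)
        net = build_network([pool_from_seqs([m.sequence for m in fam])])
        for u, v in net.edges:
            nu, nv = net.nodes[u], net.nodes[v]
            if nu.kind == "observed" and nv.kind == "observed":
                assert mutational_steps(nu.sequence, nv.sequence) == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_total_path_length_equals_brute_force_msn(self, seed):
        rng = np.random.default_rng(seed)
        n_haps = int(rng.integers(3, 9))
        steps = [int(rng.integers(1, 4)) for _ in range(n_haps - 1)]
        fam = make_ribotype_family(90, n_haps, steps, seed=seed + 50)
        seqs = [m.sequence for m in fam]
        net = build_network([pool_from_seqs(seqs)])
        assert net.total_steps == brute_force_msn_length(seqs, net.connection_limit)

    def test_no_truncation_makes_length_at_least_mst(self):
        fam = make_ribotype_family(300, 6, [1, 2, 1, 3, 2], seed=9)
        seqs = [m.sequence for m in fam]
        net = build_network([pool_from_seqs(seqs)])
        assert len(net.subnetworks) == 1  # nothing truncated
        g = nx.Graph()
        for i, j in itertools.combinations(range(len(seqs)), 2):
            g.add_edge(i, j, weight=mutational_steps(seqs[i], seqs[j]))
        mst = sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(g, data=True))
        assert net.total_steps >= mst

    def test_planted_three_cluster_design_recovers_three_subnetworks(self):
        pools = []
        for k in range(3):
            fam = make_ribotype_family(450, 3, [1, 2], seed=100 + k,
                                       id_prefix=f"c{k}")
            pools.append(pool_from_seqs([m.sequence for m in fam],
                                        sample_id=f"sample{k}"))
        net = build_network(pools)
        assert len(net.subnetworks) == 3
        membership = subnetwork_membership(net)
        assert len(set(membership.assignments.values())) == 3
        # each sample's ribotypes stay together in one subnetwork
        for k in range(3):
            subs = {v for (s, _), v in membership.assignments.items()
                    if s == f"sample{k}"}
            assert len(subs) == 1

    def test_pool_order_invariance(self):
        pools = []
        for k in range(3):
            fam = make_ribotype_family(450, 2, [2], seed=200 + k)
            pools.append(pool_from_seqs([m.sequence for m in fam],
                                        sample_id=f"p{k}", count=100 * (k + 1)))
        net_fwd = build_network(pools)
        net_rev = build_network(pools[::-1])
        assert set(net_fwd.nodes) == set(net_rev.nodes)
        assert net_fwd.edges == net_rev.edges
        assert subnetwork_membership(net_fwd).assignments == \
            subnetwork_membership(net_rev).assignments

    def test_empty_input_gives_empty_network(self):
        net = build_network([])
        assert net.nodes == {} and net.edges == ()

    def test_shared_sequence_across_pools_is_one_node(self):
        fam = make_ribotype_family(100, 2, [1], seed=8)
        seqs = [m.sequence for m in fam]
        p1 = pool_from_seqs(seqs, "a")
        p2 = pool_from_seqs(seqs[:1], "b")
        net = build_network([p1, p2])
        obs = [n for n in net.nodes.values() if n.kind == "observed"]
        assert len(obs) == 2
        shared = [n for n in obs if len(n.occurrences) == 2]
        assert len(shared) == 1

    def test_exports(self, tmp_path):
        fam = make_ribotype_family(100, 3, [1, 2], seed=10)
        net = build_network([pool_from_seqs([m.sequence for m in fam])])
        write_graphml(net, tmp_path / "net.graphml")
        write_json(net, tmp_path / "net.json")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_nodes() == len(net.nodes)
        assert g.number_of_edges() == len(net.edges)
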