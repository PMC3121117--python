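import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycolink import (
    ExpressionSignature,
    GeneSetCollection,
    NetworkScreenRecord,
    PipelineConfig,
    RegulatoryNetwork,
    ValidationError,
)
from glycolink.network import (
    build_reference_networks,
    enrichment_test,
    gcp,
    network_log_likelihood,
    random_network,
    screen_networks,
)

from conftest import make_matrix


def sig_of(genes):
    return ExpressionSignature(table=pd.DataFrame(
        {"gene_id": sorted(genes), "direction": "up",
         "min_abs_fold_change": 2.0, "max_q_value": 0.01}))


# --------------------------------------------------- reference construction

def test_build_reference_direct_example():
    bound = GeneSetCollection(sets={
        "OCT4": ("bound", frozenset({"A", "B"})),
        "SOX2": ("bound", frozenset({"B"})),
    })
    functional = GeneSetCollection(sets={"F": ("funct", frozenset({"B", "C"}))})
    nets = build_reference_networks(bound, functional, sig_of({"B"}),
                                    {"A", "B", "C", "OCT4", "SOX2"})
    assert len(nets) == 1
    assert nets[0].nodes == {"OCT4", "SOX2", "B"}
    assert nets[0].edges == {("OCT4", "B"), ("SOX2", "B")}


def test_build_reference_excludes_nonsignature_sets():
    bound = GeneSetCollection(sets={"OCT4": ("b", frozenset({"A"}))})
    functional = GeneSetCollection(sets={"F": ("f", frozenset({"A"}))})
    nets = build_reference_networks(bound, functional, sig_of({"Z"}),
                                    {"A", "OCT4", "Z"})
    assert nets == []


def test_build_reference_matches_set_algebra_oracle(rng):
    genes = [f"g{i}" for i in range(80)]
    tfs = ["TF1", "TF2", "TF3", "TF4"]
    bound = GeneSetCollection(sets={
        tf: ("b", frozenset(rng.choice(genes, size=30, replace=False)))
        for tf in tfs})
    functional = GeneSetCollection(sets={
        f"F{k}": ("f", frozenset(rng.choice(genes, size=12, replace=False)))
        for k in range(40)})
    sig = sig_of(rng.choice(genes, size=15, replace=False))
    measured = set(genes) | set(tfs)
    nets = {n.network_id: n
            for n in build_reference_networks(bound, functional, sig,
                                              measured)}
    for fid in functional.ids():
        edges = {(tf, g) for tf in tfs
                 for g in bound.members(tf) & functional.members(fid)}
        targets = {v for _, v in edges}
        expect_kept = bool(targets) and bool(targets & sig.genes)
        assert (fid in nets) == expect_kept
        if expect_kept:
            assert nets[fid].edges == edges


# ----------------------------------------------------------------- enrichment

def test_enrichment_direct_example():
    net = RegulatoryNetwork("N", frozenset({"TF", "a", "b"}),
                            frozenset([("TF", "a"), ("TF", "b")]))
    p = enrichment_test(net, sig_of({"a", "b", "c", "d", "e"}), 10)
    assert abs(p - 10 / 45) < 1e-12


def test_enrichment_k_zero_is_one():
    net = RegulatoryNetwork("N", frozenset({"TF", "a"}),
                            frozenset([("TF", "a")]))
    assert enrichment_test(net, sig_of({"z1", "z2"}), 10) == 1.0


def test_enrichment_matches_exhaustive_enumeration(rng):
    for trial in range(30):
        N = int(rng.integers(4, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = [f"u{i}" for i in range(N)]
        sig_genes = set(universe[:K])
        targets = list(rng.choice(universe, size=n, replace=False))
        k = len(set(targets) & sig_genes)
        edges = frozenset(("TF", t) for t in targets)
        net = RegulatoryNetwork("N", frozenset(targets) | {"TF"}, edges)
        p = enrichment_test(net, sig_of(sig_genes), N)
        count = sum(1 for draw in itertools.combinations(universe, n)
                    if len(set(draw) & sig_genes) >= k)
        assert abs(p - count / math.comb(N, n)) < 1e-12


# ------------------------------------------------------------- log-likelihood

def oracle_ll(net, data, node_order):
    """Independent per-node OLS summation (lstsq on raw design matrices)."""
    idx = {g: i for i, g in enumerate(node_order)}
    n = data.shape[1]
    parents = net.parents()
    total = 0.0
    for g in node_order:
        y = data[idx[g]]
        pa = parents[g]
        if pa:
            X = np.column_stack([np.ones(n)] + [data[idx[p]] for p in pa])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:
            resid = y - y.mean()
        s2 = max((resid @ resid) / n, 1e-12)
        total += -0.5 * n * (math.log(2 * math.pi * s2) + 1)
    return total


def random_dag(nodes, n_edges, rng):
    order = list(rng.permutation(nodes))
    pairs = list(itertools.combinations(range(len(order)), 2))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = frozenset((order[pairs[c][0]], order[pairs[c][1]])
                      for c in chosen)
    return RegulatoryNetwork("R", frozenset(nodes), edges)


def test_loglik_matches_oracle_on_random_dags(rng):
    for trial in range(100):
        k = int(rng.integers(2, 7))
        nodes = [f"n{i}" for i in range(k)]
        n_edges = int(rng.integers(1, k * (k - 1) // 2 + 1))
        net = random_dag(nodes, n_edges, rng)
        data = rng.normal(size=(k, 30))
        matrix = make_matrix(data, gene_ids=nodes)
        got = network_log_likelihood(net, matrix, "all")
        want = oracle_ll(net, data, nodes)
        assert abs(got - want) < 1e-8 * max(1, abs(want))


def test_single_edge_vs_edgeless_closed_form(rng):
    n = 30
    data = rng.normal(size=(2, n))
    data[1] += 0.7 * data[0]
    nodes = ["A", "B"]
    matrix = make_matrix(data, gene_ids=nodes)
    edgeless = RegulatoryNetwork("e", frozenset(nodes), frozenset())
    edge = RegulatoryNetwork("f", frozenset(nodes),
                             frozenset([("A", "B")]))
    r = np.corrcoef(data)[0, 1]
    diff = (network_log_likelihood(edge, matrix, "all")
            - network_log_likelihood(edgeless, matrix, "all"))
    assert abs(diff - (-(n / 2) * math.log(1 - r**2))) < 1e-8


def test_adding_edge_never_decreases_ll(rng):
    for trial in range(20):
        nodes = [f"n{i}" for i in range(4)]
        data = rng.normal(size=(4, 25))
        matrix = make_matrix(data, gene_ids=nodes)
        net = random_dag(nodes, 2, rng)
        base = network_log_likelihood(net, matrix, "all")
        # add one order-respecting edge if possible
        order = list(nodes)
        for u, v in itertools.permutations(nodes, 2):
            if (u, v) in net.edges or (v, u) in net.edges:
                continue
            try:
                bigger = RegulatoryNetwork("b", net.nodes,
                                           net.edges | {(u, v)})
            except ValidationError:
                continue
            assert (network_log_likelihood(bigger, matrix, "all")
                    >= base - 1e-9)
            break


def test_ll_invariant_to_relabeling_and_sample_order(rng):
    nodes = ["a", "b", "c", "d"]
    data = rng.normal(size=(4, 20))
    net = random_dag(nodes, 3, rng)
    m1 = make_matrix(data, gene_ids=nodes)
    perm = rng.permutation(20)
    m2 = make_matrix(data[:, perm], gene_ids=nodes)
    assert abs(network_log_likelihood(net, m1, "all")
               - network_log_likelihood(net, m2, "all")) < 1e-9


# ----------------------------------------------------------------- null model

def test_random_network_preserves_counts_and_acyclic(rng, default_bundle):
    for template in default_bundle.networks[:5]:
        null = random_network(template, rng)
        assert null.nodes == template.nodes
        assert null.n_edges == template.n_edges  # acyclicity checked in ctor


def test_random_network_two_node_frequencies(rng):
    template = RegulatoryNetwork("t", frozenset({"A", "B"}),
                                 frozenset([("A", "B")]))
    n = 10_000
    forward = sum(("A", "B") in random_network(template, rng).edges
                  for _ in range(n))
    se = math.sqrt(0.25 / n)
    assert abs(forward / n - 0.5) < 3 * se


def test_random_network_matches_sampler_distribution(rng):
    # enumerate the sampler's exact outcome distribution for 4 nodes/3 edges
    nodes = ["a", "b", "c", "d"]
    template = RegulatoryNetwork("t", frozenset(nodes),
                                 frozenset([("a", "b"), ("b", "c"),
                                            ("c", "d")]))
    all_pairs = list(itertools.combinations(range(4), 2))
    pair_sets = list(itertools.combinations(all_pairs, 3))
    expected = {}
    orders = list(itertools.permutations(range(4)))
    for order in orders:
        for pairs in pair_sets:
            edges = frozenset((nodes[order[i]], nodes[order[j]])
                              for i, j in pairs)
            expected[edges] = expected.get(edges, 0) + 1
    total = len(orders) * len(pair_sets)
    draws = 20_000
    counts = {}
    for _ in range(draws):
        e = random_network(template, rng).edges
        counts[e] = counts.get(e, 0) + 1
    assert set(counts) <= set(expected)
    obs = np.array([counts.get(e, 0) for e in expected])
    exp = np.array([v / total for v in expected.values()]) * draws
    keep = exp >= 5
    chi2 = float(np.sum((obs[keep] - exp[keep]) ** 2 / exp[keep]))
    p = stats.chi2.sf(chi2, keep.sum() - 1)
    assert p > 0.01


# ----------------------------------------------------------------------- GCP

def test_gcp_plus_one_arithmetic(rng):
    nodes = ["A", "B"]
    data = rng.normal(size=(2, 30))
    data[1] += 2.0 * data[0]  # strong dependence: null below observed
    matrix = make_matrix(data, gene_ids=nodes, classes=["iPSC"] * 30)
    net = RegulatoryNetwork("n", frozenset(nodes), frozenset([("A", "B")]))
    res = gcp(net, matrix, PipelineConfig(n_random_networks=1), seed=0)
    assert res.gcp in (0.5, 1.0)
    assert len(res.null_lls) == 1


def test_gcp_detects_planted_structure(rng):
    n = 20
    nodes = [f"n{i}" for i in range(10)]
    net = random_dag(nodes, 9, rng)
    data = np.zeros((10, n))
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(net.edges)
    idx = {x: i for i, x in enumerate(nodes)}
    parents = net.parents()
    for node in nx.topological_sort(g):
        pa = parents[node]
        if pa:
            data[idx[node]] = (0.8 * sum(data[idx[p]] for p in pa)
                               + rng.normal(0, 0.5, n))
        else:
            data[idx[node]] = rng.normal(0, 1, n)
    matrix = make_matrix(data, gene_ids=nodes, classes=["iPSC"] * n)
    res = gcp(net, matrix, PipelineConfig(n_random_networks=200), seed=1)
    assert res.gcp < 0.05


# ------------------------------------------------------------------ screening

def test_screen_records_and_truth_recovery(default_bundle, default_config):
    from glycolink.expression import de_test, intersect_signature

    b = default_bundle
    de = {l: de_test(b.matrix, l, default_config)
          for l in b.matrix.lineages()}
    signature = intersect_signature(de)
    cfg = PipelineConfig(n_random_networks=300)
    records, genes = screen_networks(b.networks, signature, b.matrix, cfg)
    by_id = {r.network_id: r for r in records}
    cons = b.truth.consistent_network_ids
    sens = np.mean([by_id[i].in_signature for i in cons])
    specificity = 1 - np.mean([by_id[i].in_signature
                               for i in b.truth.inconsistent_network_ids])
    assert sens >= 0.9
    assert specificity >= 0.9
    # records survive a JSON round trip
    blob = json.dumps([r.to_dict() for r in records])
    back = [NetworkScreenRecord.from_dict(d) for d in json.loads(blob)]
    assert back == records


def test_screen_no_enrichment_leaves_gcp_unset(default_bundle):
    sig = sig_of({"not-a-gene"})
    records, genes = screen_networks(default_bundle.networks[:4], sig,
                                     default_bundle.matrix,
                                     PipelineConfig(n_random_networks=10))
    assert genes == set()
    assert all(r.gcp is None and not r.in_signature for r in records)
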