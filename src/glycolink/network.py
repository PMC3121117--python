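"""Network screening: enrichment plus graph-consistency probability (GCP).

A reference network is a directed acyclic TF->target graph. Screening is a
two-stage filter: (1) hypergeometric enrichment of expression-signature
genes among the network's target genes, and (2) consistency of the network
structure with the expression data, summarized as the GCP — the empirical
upper-tail probability of the network's Gaussian log-likelihood within the
distribution of log-likelihoods of random networks having the same node and
edge counts, scored on the same data.

The joint density of a DAG factorizes into per-node conditionals; under the
linear-Gaussian model each node contributes the maximized log-likelihood of
an ordinary least-squares regression (with intercept) of the node on its
parents, so the network score is a sum of per-node Gaussian terms with
MLE residual variances. Because every random network reuses the same data,
all regressions are solved from one centered cross-product (Gram) matrix.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import hypergeom

from .io import logger
from .types import (
    ExpressionMatrix,
    ExpressionSignature,
    GcpResult,
    GeneSetCollection,
    NetworkScreenRecord,
    PipelineConfig,
    RegulatoryNetwork,
    ValidationError,
)

_VAR_FLOOR = 1e-12
_LN_2PI = math.log(2.0 * math.pi)


# ------------------------------------------------------- reference networks

def build_reference_networks(bound_sets: GeneSetCollection,
                             functional_sets: GeneSetCollection,
                             signature: ExpressionSignature,
                             measured_genes: set[str]
                             ) -> list[RegulatoryNetwork]:
    """Partition TF-bound gene sets by functional sets into reference DAGs.

    For each functional set F the candidate targets are the measured genes
    bound by at least one TF and contained in F; edges run TF -> target for
    every binding TF. TFs themselves are never targets, so every graph is
    bipartite and acyclic. Networks whose targets miss the expression
    signature entirely are dropped (step 4 of the screening scheme).
    """
    tf_ids = set(bound_sets.ids())
    missing_tfs = tf_ids - measured_genes
    if missing_tfs:
        raise ValidationError(
            f"TF genes absent from measured genes: {sorted(missing_tfs)}"
        )
    sig_genes = signature.genes
    networks = []
    for fid in functional_sets.ids():
        fset = functional_sets.members(fid)
        edges = set()
        for tf in bound_sets.ids():
            for g in bound_sets.members(tf) & fset & measured_genes:
                if g != tf and g not in tf_ids:
                    edges.add((tf, g))
        targets = {v for _, v in edges}
        if not targets:
            logger.info("functional set %s: empty candidate set, skipped", fid)
            continue
        if not (targets & sig_genes):
            logger.info("functional set %s: no signature gene, excluded", fid)
            continue
        nodes = targets | {u for u, _ in edges}
        networks.append(RegulatoryNetwork(network_id=fid,
                                          nodes=frozenset(nodes),
                                          edges=frozenset(edges)))
    logger.info("built %d reference networks from %d functional sets",
                len(networks), len(functional_sets))
    return networks


def enrichment_test(network: RegulatoryNetwork,
                    signature: ExpressionSignature,
                    universe_size: int) -> float:
    """Hypergeometric upper-tail enrichment of signature genes in a network.

    Draws are the network's target (non-regulator) genes; regulator nodes
    are excluded from the draw count. Returns P[X >= k] for X hypergeometric
    with population ``universe_size``, ``K`` signature genes, ``n`` targets.
    """
    regulators = network.regulators()
    targets = sorted(network.nodes - regulators)
    n = len(targets)
    K = len(signature.genes)
    k = len(set(targets) & signature.genes)
    if K > universe_size or n > universe_size:
        raise ValidationError("signature or network larger than the universe")
    if k > min(n, K):
        raise ValidationError("impossible enrichment configuration")
    return float(hypergeom.sf(k - 1, universe_size, K, n))


# ------------------------------------------------------------ log-likelihood

def _gram(data: np.ndarray) -> np.ndarray:
    """Centered cross-product matrix of node rows (nodes x nodes)."""
    centered = data - data.mean(axis=1, keepdims=True)
    return centered @ centered.T


def _node_ll(n: int, rss: float) -> float:
    sigma2 = max(rss / n, _VAR_FLOOR)
    return -0.5 * n * (_LN_2PI + math.log(sigma2) + 1.0)


def _network_ll_from_gram(gram: np.ndarray, parents: list[list[int]],
                          n: int) -> float:
    """Sum of per-node Gaussian OLS log-likelihoods from the Gram matrix.

    With centered data, OLS-with-intercept of node v on parent set P has
    RSS = G[v,v] - G[v,P] @ G[P,P]^{-1} @ G[P,v]; root nodes use the
    marginal RSS = G[v,v].
    """
    ll = 0.0
    for v, pa in enumerate(parents):
        gvv = gram[v, v]
        if not pa:
            ll += _node_ll(n, gvv)
            continue
        gpp = gram[np.ix_(pa, pa)]
        gpv = gram[pa, v]
        try:
            beta = np.linalg.solve(gpp, gpv)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(gpp, gpv, rcond=None)[0]
        rss = gvv - float(gpv @ beta)
        ll += _node_ll(n, max(rss, 0.0))
    return ll


def _scope_columns(matrix: ExpressionMatrix, sample_scope: str) -> list[int]:
    if sample_scope == "all":
        return list(range(matrix.n_samples))
    if sample_scope == "iPSC_only":
        return [j for j, s in enumerate(matrix.sample_ids)
                if matrix.annotations[s].cell_class == "iPSC"]
    raise ValidationError(f"unknown sample scope {sample_scope!r}")


def _node_data(network_nodes: list[str], matrix: ExpressionMatrix,
               cols: list[int]) -> np.ndarray:
    gidx = matrix.gene_index()
    missing = [g for g in network_nodes if g not in gidx]
    if missing:
        raise ValidationError(f"network nodes not measured: {missing}")
    rows = [gidx[g] for g in network_nodes]
    return matrix.values[np.ix_(rows, cols)]


def network_log_likelihood(network: RegulatoryNetwork,
                           matrix: ExpressionMatrix,
                           sample_scope: str = "all") -> float:
    """Gaussian-network maximum log-likelihood of a DAG on expression data.

    Each root node contributes -(n/2)(ln(2 pi sigma^2) + 1) with sigma^2 its
    MLE marginal variance; each child node contributes the same with
    sigma^2 the MLE residual variance of OLS (with intercept) of the child
    on its parents. Residual variances are floored at 1e-12.
    """
    cols = _scope_columns(matrix, sample_scope)
    n = len(cols)
    nodes = sorted(network.nodes)
    parent_names = network.parents()
    max_indeg = max((len(parent_names[v]) for v in nodes), default=0)
    if max_indeg >= n - 1:
        raise ValidationError(
            f"in-degree {max_indeg} too large for {n} samples"
        )
    data = _node_data(nodes, matrix, cols)
    node_pos = {g: i for i, g in enumerate(nodes)}
    parents = [[node_pos[p] for p in parent_names[v]] for v in nodes]
    return _network_ll_from_gram(_gram(data), parents, n)


# -------------------------------------------------------------- random DAGs

def random_network(template: RegulatoryNetwork,
                   rng: np.random.Generator) -> RegulatoryNetwork:
    """Random DAG with the template's node set and edge count.

    A uniform random permutation of the nodes is drawn as topological order
    and the edges are sampled uniformly without replacement from all
    order-respecting pairs, so the result is acyclic by construction.
    """
    nodes = sorted(template.nodes)
    n = len(nodes)
    if n < 2 or template.n_edges < 1:
        raise ValidationError("template needs >= 2 nodes and >= 1 edge")
    m_all = n * (n - 1) // 2
    if template.n_edges > m_all:
        raise ValidationError("edge count exceeds C(n, 2)")
    order = rng.permutation(n)
    pair_idx = rng.choice(m_all, size=template.n_edges, replace=False)
    iu, ju = np.triu_indices(n, k=1)
    edges = frozenset(
        (nodes[order[iu[p]]], nodes[order[ju[p]]]) for p in pair_idx
    )
    return RegulatoryNetwork(network_id=template.network_id + ":null",
                             nodes=frozenset(nodes), edges=edges)


def _random_parent_lists(n_nodes: int, n_edges: int,
                         rng: np.random.Generator,
                         iu: np.ndarray, ju: np.ndarray) -> list[list[int]]:
    """Parent index lists of one random order-respecting DAG (fast path)."""
    order = rng.permutation(n_nodes)
    pair_idx = rng.choice(iu.size, size=n_edges, replace=False)
    parents: list[list[int]] = [[] for _ in range(n_nodes)]
    for p in pair_idx:
        parents[order[ju[p]]].append(order[iu[p]])
    return parents


# ---------------------------------------------------------------------- GCP

def gcp(network: RegulatoryNetwork, matrix: ExpressionMatrix,
        config: PipelineConfig | None = None,
        seed: int | None = None) -> GcpResult:
    """Graph-consistency probability of a network on expression data.

    The observed log-likelihood is compared with the null distribution from
    ``n_random_networks`` random DAGs with the same node set and edge count,
    scored on the same (scope-restricted) data. The plus-one estimator
    gcp = (1 + #{null >= observed}) / (1 + n_random) never returns zero; a
    small GCP means the given structure fits the data better than almost all
    random structures, i.e. the network is data-consistent.
    """
    config = config or PipelineConfig()
    seed = config.rng_seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cols = _scope_columns(matrix, config.sample_scope_for_gcp)
    n = len(cols)
    nodes = sorted(network.nodes)
    k = len(nodes)
    parent_names = network.parents()
    max_indeg = max((len(parent_names[v]) for v in nodes), default=0)
    if max_indeg >= n - 1:
        raise ValidationError(f"in-degree {max_indeg} too large for {n} samples")
    data = _node_data(nodes, matrix, cols)
    gram = _gram(data)
    node_pos = {g: i for i, g in enumerate(nodes)}
    parents = [[node_pos[p] for p in parent_names[v]] for v in nodes]
    observed = _network_ll_from_gram(gram, parents, n)
    iu, ju = np.triu_indices(k, k=1)
    null_lls = np.empty(config.n_random_networks)
    for r in range(config.n_random_networks):
        null_parents = _random_parent_lists(k, network.n_edges, rng, iu, ju)
        null_lls[r] = _network_ll_from_gram(gram, null_parents, n)
    n_ge = int(np.sum(null_lls >= observed))
    value = (1.0 + n_ge) / (1.0 + config.n_random_networks)
    return GcpResult(observed_ll=observed, null_lls=null_lls, gcp=value,
                     rng_seed=seed)


# ----------------------------------------------------------------- screening

def screen_networks(references: list[RegulatoryNetwork],
                    signature: ExpressionSignature,
                    matrix: ExpressionMatrix,
                    config: PipelineConfig | None = None,
                    seed: int | None = None
                    ) -> tuple[list[NetworkScreenRecord], set[str]]:
    """Two-stage screen of reference networks; returns records and the union
    of in-signature networks' genes (the network signature).

    Enrichment is tested first; the (costlier) GCP is computed only for
    networks passing enrichment, matching the step order of the screening
    scheme. Per-network null RNG streams are spawned from the base seed, so
    the full screen is reproducible for a given seed and reference order.
    """
    if not references:
        raise ValidationError("no reference networks to screen")
    config = config or PipelineConfig()
    base_seed = config.rng_seed if seed is None else seed
    universe = config.background_universe_size or matrix.n_genes
    records = []
    signature_genes: set[str] = set()
    ss = np.random.SeedSequence(base_seed)
    children = ss.spawn(len(references))
    for net, child in zip(references, children):
        p_enrich = enrichment_test(net, signature, universe)
        passes_enrich = p_enrich < config.enrichment_alpha
        observed_ll = None
        gcp_value = None
        passes_gcp = False
        if passes_enrich:
            net_seed = int(child.generate_state(1)[0] % (2**31))
            result = gcp(net, matrix, config, seed=net_seed)
            observed_ll = result.observed_ll
            gcp_value = result.gcp
            passes_gcp = result.gcp < config.gcp_alpha
        in_sig = passes_enrich and passes_gcp
        targets = net.nodes - net.regulators()
        records.append(NetworkScreenRecord(
            network_id=net.network_id,
            n_nodes=net.n_nodes,
            n_edges=net.n_edges,
            n_signature_genes=len(targets & signature.genes),
            enrichment_p=p_enrich,
            observed_log_likelihood=observed_ll,
            gcp=gcp_value,
            passes_enrichment=passes_enrich,
            passes_gcp=passes_gcp,
            in_signature=in_sig,
        ))
        if in_sig:
            signature_genes |= net.nodes
    n_pass = sum(r.in_signature for r in records)
    logger.info("network screen: %d/%d networks in signature, %d genes",
                n_pass, len(records), len(signature_genes))
    return records, signature_genes
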