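import numpy as np
import pytest
from scipy import integrate, stats

from glycolink import PipelineConfig, RawIntensityTable, ValidationError
from glycolink.expression import (
    NormexpParams,
    bh_fdr,
    correlation_matrix,
    cut_tree_k,
    de_test,
    fit_normexp_moments,
    hierarchical_cluster,
    intersect_signature,
    loocv_nn_classify,
    normexp_correct,
    normexp_posterior_mean,
)

from conftest import make_matrix


# ---------------------------------------------------------------- normexp

def quad_posterior_mean(x, mu, sigma, alpha):
    """Numerical-integration oracle for E[S | X = x] under N+Exp."""
    def num(s):
        return s * np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma)

    def den(s):
        return np.exp(-s / alpha) * stats.norm.pdf(x - s, mu, sigma)

    hi = max(x + 10 * sigma, 20 * alpha)
    a, _ = integrate.quad(num, 0, hi, limit=200)
    b, _ = integrate.quad(den, 0, hi, limit=200)
    return a / b


def test_posterior_mean_matches_quadrature_oracle():
    rng = np.random.default_rng(0)
    net = rng.normal(100, 15, 10_000) + rng.exponential(200, 10_000)
    params = fit_normexp_moments(net)
    assert not params.fallback
    probes = np.linspace(np.quantile(net, 0.02), np.quantile(net, 0.98), 20)
    ours = normexp_posterior_mean(probes, params)
    for x, got in zip(probes, ours):
        want = quad_posterior_mean(x, params.mu, params.sigma, params.alpha)
        assert abs(got - want) / abs(want) < 1e-4


def test_posterior_mean_tail_identity_sigma_to_zero():
    params = NormexpParams(mu=5.0, sigma=1e-4, alpha=200.0)
    x = 1000.0
    got = normexp_posterior_mean(np.array([x]), params)[0]
    assert abs(got - (x - 5.0)) < 0.01  # E[S|X] -> x - mu for x >> mu


def test_normexp_offset_floor_and_monotonicity():
    rng = np.random.default_rng(1)
    fg = rng.normal(500, 50, size=(500, 2)) + rng.exponential(300, (500, 2))
    bg = np.full((500, 2), 100.0)
    raw = RawIntensityTable(gene_ids=[f"g{i}" for i in range(500)],
                            sample_ids=["a", "b"],
                            foreground=np.abs(fg) + 1, background=bg)
    out = normexp_correct(raw, offset=16.0)
    assert np.all(np.isfinite(out.values))
    # monotone in net intensity within an array
    order = np.argsort(raw.foreground[:, 0])
    assert np.all(np.diff(out.values[order, 0]) >= -1e-9)


def test_normexp_fallback_on_degenerate_array():
    fg = np.full((300, 1), 250.0)  # constant array: moment fit degenerates
    raw = RawIntensityTable(gene_ids=[f"g{i}" for i in range(300)],
                            sample_ids=["a"], foreground=fg,
                            background=np.zeros((300, 1)))
    out = normexp_correct(raw, offset=16.0)
    assert np.all(np.isfinite(out.values))
    np.testing.assert_allclose(out.values, np.log2(250.0 + 16.0))


# ------------------------------------------------------------- clustering

def test_complete_linkage_hand_example():
    m = make_matrix([[0.0, 1.0, 10.0]]).values  # one gene, 3 samples
    matrix = make_matrix(m)
    merges = hierarchical_cluster(matrix, "complete", axis="samples")
    heights = merges[:, 2]
    np.testing.assert_allclose(heights, [1.0, 10.0])


def test_duplicated_sample_merges_at_zero():
    matrix = make_matrix([[1.0, 1.0, 5.0], [2.0, 2.0, 9.0]])
    merges = hierarchical_cluster(matrix, "ward", axis="samples")
    assert merges[0, 2] == 0.0


def test_cluster_heights_nondecreasing_and_k2_separates_classes(
        default_bundle):
    matrix = default_bundle.matrix
    for linkage in ("complete", "ward"):
        merges = hierarchical_cluster(matrix, linkage, axis="samples")
        assert np.all(np.diff(merges[:, 2]) >= -1e-9)
    labels = cut_tree_k(hierarchical_cluster(matrix, "complete"), 2)
    classes = [matrix.annotations[s].cell_class for s in matrix.sample_ids]
    split = {c: {labels[j] for j, cl in enumerate(classes) if cl == c}
             for c in ("iPSC", "SC")}
    assert split["iPSC"].isdisjoint(split["SC"])


# ------------------------------------------------------------ correlation

def test_correlation_matrix_identities():
    matrix = make_matrix(np.array([[1.0, -1.0], [2.0, -2.0], [3.0, -3.0]]))
    corr = correlation_matrix(matrix)
    assert corr.iloc[0, 0] == 1.0
    assert abs(corr.iloc[0, 1] + 1.0) < 1e-12


def test_correlation_matches_two_pass_formula(rng):
    vals = rng.normal(size=(5, 4))
    matrix = make_matrix(vals)
    corr = correlation_matrix(matrix).to_numpy()
    for i in range(4):
        for j in range(4):
            x, y = vals[:, i], vals[:, j]
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2)
                          * np.sum((y - y.mean()) ** 2))
            assert abs(corr[i, j] - num / den) < 1e-12


def test_zero_variance_sample_named():
    matrix = make_matrix([[1.0, 2.0], [1.0, 3.0]])
    with pytest.raises(ValidationError, match="s0"):
        correlation_matrix(matrix)


# ------------------------------------------------------------------ LOOCV

def test_loocv_duplicated_samples_perfect():
    vals = np.array([[1.0, 1.0, 5.0, 5.0], [2.0, 2.0, 3.0, 3.0],
                     [0.0, 0.0, 9.0, 9.0]])
    matrix = make_matrix(vals, classes=["SC", "SC", "iPSC", "iPSC"])
    labels = {s: matrix.annotations[s].cell_class for s in matrix.sample_ids}
    accuracy, _ = loocv_nn_classify(matrix, labels)
    assert accuracy == 1.0


def test_loocv_equals_brute_force(rng):
    vals = rng.normal(size=(40, 6))
    classes = ["SC", "iPSC", "SC", "iPSC", "SC", "iPSC"]
    matrix = make_matrix(vals, classes=classes)
    labels = {s: c for s, c in zip(matrix.sample_ids, classes)}
    _, preds = loocv_nn_classify(matrix, labels)
    corr = np.corrcoef(vals, rowvar=False)
    for i, sid in enumerate(matrix.sample_ids):
        dists = [(1 - corr[i, j], j) for j in range(6) if j != i]
        best = min(dists)[1]
        assert preds[sid] == classes[best]


# --------------------------------------------------------------- de tests

def test_de_hand_example():
    # A=(1,2,3) vs B=(4,5,6): pooled SD 1, SE 0.8165, t=-3.674, p=0.0214
    vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]])
    matrix = make_matrix(vals,
                         classes=["iPSC"] * 3 + ["SC"] * 3,
                         lineages=["X"] * 6)
    res = de_test(matrix, "X")
    row = res.table.iloc[0]
    assert abs(row.t_statistic + 3.674) < 1e-3
    assert abs(row.p_value - 0.0214) < 1e-3
    assert abs(row.log2_fold_change + 3.0) < 1e-12


def test_de_identical_groups_degenerate():
    vals = np.array([[1.0, 1.0, 1.0, 1.0]])
    matrix = make_matrix(vals, classes=["iPSC", "iPSC", "SC", "SC"])
    res = de_test(matrix, "X")
    assert res.table.p_value.iloc[0] == 1.0
    assert res.table.t_statistic.iloc[0] == 0.0


def test_bh_examples_and_properties(rng):
    np.testing.assert_allclose(bh_fdr(np.array([0.03])), [0.03])
    np.testing.assert_allclose(bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])),
                               [0.04, 0.04, 0.04, 0.04])
    p = rng.uniform(size=500)
    q = bh_fdr(p)
    assert np.all(q >= p - 1e-15)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)
    with pytest.raises(ValidationError):
        bh_fdr(np.array([0.1, 1.2]))


def test_signature_selection_boundaries(rng):
    # FC boundary is inclusive (|log2FC| >= log2(fc)); FDR boundary strict.
    from glycolink.expression import _fc_passes

    cfg = PipelineConfig()
    a = np.array([[2.0, 2.0]])
    b = np.array([[1.0, 1.0]])
    assert _fc_passes(a, b, np.array([1.0]), cfg)[0]
    assert not _fc_passes(a, b, np.array([0.999]), cfg)[0]
    # strict '<' on the FDR threshold: a gene with q exactly at the
    # threshold never passes
    vals = np.vstack([rng.normal(size=6) for _ in range(20)])
    vals[0, :3] += 5.0
    matrix = make_matrix(vals, classes=["iPSC"] * 3 + ["SC"] * 3)
    res = de_test(matrix, "X",
                  PipelineConfig(fdr_threshold=float(
                      de_test(matrix, "X").table.q_value.iloc[0])))
    assert not bool(res.table.passes.iloc[0])


def test_intersection_discordant_direction_excluded(default_config):
    import pandas as pd

    from glycolink.types import DEResult

    def mk(rows):
        return DEResult(contrast="L", table=pd.DataFrame(rows),
                        fdr_threshold=0.05, fc_threshold=2.0)

    r1 = mk([{"gene_id": "A", "log2_fold_change": 2.0, "q_value": 0.01,
              "passes": True},
             {"gene_id": "B", "log2_fold_change": -2.0, "q_value": 0.01,
              "passes": True}])
    r2 = mk([{"gene_id": "A", "log2_fold_change": 1.5, "q_value": 0.02,
              "passes": True},
             {"gene_id": "B", "log2_fold_change": 2.0, "q_value": 0.02,
              "passes": True}])
    sig = intersect_signature({"L1": r1, "L2": r2})
    assert sig.genes == {"A"}
    assert sig.direction("A") == "up"
    row = sig.table.iloc[0]
    assert abs(row.min_abs_fold_change - 2.0**1.5) < 1e-12
    assert row.max_q_value == 0.02


def test_intersection_idempotent_and_order_invariant(default_bundle,
                                                     default_config):
    m = default_bundle.matrix
    de = {l: de_test(m, l, default_config) for l in m.lineages()}
    sig1 = intersect_signature(de)
    sig2 = intersect_signature(dict(reversed(list(de.items()))))
    assert sig1.genes == sig2.genes
    one = {"A": de["AM"], "B": de["AM"]}
    assert intersect_signature(one).genes == de["AM"].passing_genes()
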