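"""Expression preprocessing and the iPSC-vs-SC expression signature.

The stage mirrors a standard one-color microarray workflow: normal+
exponential convolution background correction with an offset, hierarchical
clustering (complete or Ward linkage, Euclidean distance), Pearson sample
correlation, leave-one-out nearest-neighbor classification on correlation
distance, per-lineage Student t-tests with Benjamini-Hochberg FDR and a
fold-change cut, and the intersection of the per-lineage gene lists into a
direction-concordant signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as _scipy_linkage
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import logger
from .types import (
    DEResult,
    ExpressionMatrix,
    ExpressionSignature,
    GlycolinkError,
    PipelineConfig,
    RawIntensityTable,
    ValidationError,
)


# ------------------------------------------------------- background correction

@dataclass
class NormexpParams:
    """Per-array parameters of the normal+exponential convolution fit."""

    mu: float
    sigma: float
    alpha: float
    fallback: bool = False


def fit_normexp_moments(net: np.ndarray) -> NormexpParams:
    """Tail-moment fit of X = N(mu, sigma^2) + Exp(alpha) to net intensities.

    mu is the mode of the net-intensity density (kernel estimate); sigma is
    the root-mean-square spread of the lower tail below the mode (the lower
    tail is dominated by the normal noise component); alpha is the mean
    excess above the mode (dominated by the exponential signal). These
    tail moments are far more stable than raw skewness-based moments when
    the signal scale exceeds the noise scale. Degenerate arrays (empty
    tails, non-positive alpha or sigma estimates) are flagged for the
    truncation fallback.
    """
    net = np.asarray(net, dtype=float)
    if net.size < 10 or np.ptp(net) == 0:
        return NormexpParams(mu=float(net.mean()), sigma=0.0, alpha=0.0,
                             fallback=True)
    lo, hi = np.quantile(net, [0.001, 0.999])
    grid = np.linspace(lo, hi, 512)
    density = stats.gaussian_kde(net)(grid)
    mu = float(grid[np.argmax(density)])
    below = net[net < mu] - mu
    above = net[net > mu] - mu
    if below.size == 0 or above.size == 0:
        return NormexpParams(mu=mu, sigma=0.0, alpha=0.0, fallback=True)
    sigma2 = float(np.mean(below**2))
    alpha = float(np.mean(above))
    if sigma2 <= 0 or alpha <= 0:
        return NormexpParams(mu=mu, sigma=0.0, alpha=0.0, fallback=True)
    return NormexpParams(mu=mu, sigma=np.sqrt(sigma2), alpha=alpha)


def normexp_posterior_mean(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """E[signal | observed] under the normal+exponential convolution.

    With mu_sx = x - mu - sigma^2/alpha, the conditional mean of the true
    (exponential) signal is mu_sx + sigma * phi(mu_sx/sigma)/Phi(mu_sx/sigma).
    The Mills-ratio term is evaluated in log space to stay finite deep in the
    lower tail.
    """
    mu_sx = x - params.mu - params.sigma**2 / params.alpha
    z = mu_sx / params.sigma
    mills = np.exp(norm.logpdf(z) - norm.logcdf(z))
    return mu_sx + params.sigma * mills


def normexp_correct(raw: RawIntensityTable,
                    offset: float = 16.0) -> ExpressionMatrix:
    """Background-correct raw intensities and return log2 values.

    Per array: net = foreground - background; the convolution model is fit by
    method of moments and each probe is replaced by the posterior mean of its
    true signal; output is log2(corrected + offset). Arrays for which the
    moment fit degenerates (non-positive alpha or sigma^2 estimate) fall back
    to max(net, offset/2) with a logged warning.
    """
    fg, bg = raw.foreground, raw.background
    if np.any(fg <= 0):
        raise ValidationError("foreground intensities must be positive")
    corrected = np.empty_like(fg)
    for j, sid in enumerate(raw.sample_ids):
        net = fg[:, j] - bg[:, j]
        params = fit_normexp_moments(net)
        if params.fallback:
            logger.warning(
                "normexp moment fit degenerate for array %s; "
                "falling back to truncation", sid)
            corrected[:, j] = np.maximum(net, 0.5 * offset)
        else:
            corrected[:, j] = normexp_posterior_mean(net, params)
    values = np.log2(corrected + offset)
    if not np.all(np.isfinite(values)):
        raise GlycolinkError("non-finite values after background correction")
    from .types import SampleAnnotation

    annotations = {
        s: SampleAnnotation(sample_id=s, lineage="NA", cell_class="SC",
                            line_id="NA", passage=0)
        for s in raw.sample_ids
    }
    return ExpressionMatrix(gene_ids=list(raw.gene_ids),
                            sample_ids=list(raw.sample_ids),
                            values=values, annotations=annotations)


# ------------------------------------------------------------------ clustering

def hierarchical_cluster(matrix: ExpressionMatrix, linkage: str = "complete",
                         axis: str = "samples") -> np.ndarray:
    """Agglomerative clustering with Euclidean distance.

    Returns the (n-1) x 4 merge table (scipy linkage format: merged indices,
    merge height, cluster size). ``linkage`` is 'complete' or 'ward'.
    """
    if linkage not in ("complete", "ward"):
        raise ValidationError(f"unsupported linkage {linkage!r}")
    if axis not in ("samples", "genes"):
        raise ValidationError(f"axis must be 'samples' or 'genes'")
    data = matrix.values.T if axis == "samples" else matrix.values
    if data.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 items")
    if not np.all(np.isfinite(data)):
        raise ValidationError("matrix contains NaN/inf")
    return _scipy_linkage(data, method=linkage, metric="euclidean")


def dendrogram_to_text(merges: np.ndarray, labels: list[str]) -> str:
    """Newick-like nested-text rendering of a merge table."""
    n = len(labels)
    reps: dict[int, str] = {i: labels[i] for i in range(n)}
    for k, (a, b, height, _) in enumerate(merges):
        reps[n + k] = f"({reps[int(a)]},{reps[int(b)]}):{height:.6g}"
    return reps[n + len(merges) - 1] + ";"


def cut_tree_k(merges: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels (0..k-1) from a merge table."""
    from scipy.cluster.hierarchy import fcluster

    return fcluster(merges, t=k, criterion="maxclust") - 1


def correlation_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation of expression profiles."""
    vals = matrix.values
    sds = vals.std(axis=0)
    zero = [s for s, sd in zip(matrix.sample_ids, sds) if sd == 0]
    if zero:
        raise ValidationError(f"zero-variance sample(s): {zero}")
    corr = np.corrcoef(vals, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.sample_ids,
                        columns=matrix.sample_ids)


# ------------------------------------------------------------------- LOOCV NN

def loocv_nn_classify(matrix: ExpressionMatrix,
                      labels: dict[str, str]) -> tuple[float, dict[str, str]]:
    """Leave-one-out nearest-neighbor classification on correlation distance.

    Distance between samples is 1 - Pearson r; each held-out sample receives
    the label of its nearest remaining sample; ties resolve to the lowest
    sample index for determinism. Returns (accuracy, predictions).
    """
    ids = matrix.sample_ids
    y = [labels[s] for s in ids]
    if len(set(y)) < 2:
        raise ValidationError("need at least 2 label classes")
    from collections import Counter

    singletons = [c for c, n in Counter(y).items() if n < 2]
    if singletons:
        logger.warning("classes with a single member can never be predicted "
                       "correctly: %s", singletons)
    dist = 1.0 - correlation_matrix(matrix).to_numpy()
    n = len(ids)
    preds: dict[str, str] = {}
    correct = 0
    for i in range(n):
        best_j, best_d = -1, np.inf
        for j in range(n):
            if j == i:
                continue
            if dist[i, j] < best_d:  # strict < keeps the lowest tied index
                best_d, best_j = dist[i, j], j
        preds[ids[i]] = y[best_j]
        correct += preds[ids[i]] == y[i]
    return correct / n, preds


# --------------------------------------------------------- differential tests

def student_t_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray,
                                                          np.ndarray]:
    """Row-wise two-sided pooled-variance (Student) t-test.

    Degenerate rows with zero pooled variance get p = 1 when the group means
    agree and p = 0 otherwise (an exact-constant difference), with a warning.
    """
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValidationError("each group needs >= 2 samples")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    p = 2.0 * t_dist.sf(np.abs(t), df)
    degenerate = se == 0
    if np.any(degenerate):
        logger.warning("%d rows with zero pooled variance", degenerate.sum())
        equal = degenerate & (ma == mb)
        p[equal] = 1.0
        t[equal] = 0.0
        unequal = degenerate & (ma != mb)
        p[unequal] = 0.0
        t[unequal] = np.sign(ma[unequal] - mb[unequal]) * np.inf
    return t, p


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_test(matrix: ExpressionMatrix, lineage: str,
            config: PipelineConfig | None = None) -> DEResult:
    """iPSC-vs-SC differential test for one lineage.

    Student's t per gene on log2 intensities; log2 fold change is
    mean(iPSC) - mean(SC); q-values are BH-adjusted within the lineage; a
    gene passes iff q < fdr_threshold and the fold change reaches
    fc_threshold (on the configured scale, default |delta log2| >= log2(fc)).
    """
    config = config or PipelineConfig()
    ipsc = matrix.samples_where(lineage=lineage, cell_class="iPSC")
    sc = matrix.samples_where(lineage=lineage, cell_class="SC")
    if len(ipsc) < 2 or len(sc) < 2:
        raise ValidationError(
            f"lineage {lineage!r} needs >= 2 iPSC and >= 2 SC samples "
            f"(got {len(ipsc)}, {len(sc)})"
        )
    col = {s: j for j, s in enumerate(matrix.sample_ids)}
    a = matrix.values[:, [col[s] for s in ipsc]]
    b = matrix.values[:, [col[s] for s in sc]]
    t, p = student_t_rows(a, b)
    q = bh_fdr(p)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    passes = (q < config.fdr_threshold) & _fc_passes(a, b, lfc, config)
    table = pd.DataFrame({
        "gene_id": matrix.gene_ids,
        "mean_a": a.mean(axis=1),
        "mean_b": b.mean(axis=1),
        "t_statistic": t,
        "p_value": p,
        "q_value": q,
        "log2_fold_change": lfc,
        "passes": passes,
    })
    logger.info("DE %s: %d iPSC vs %d SC samples, %d/%d genes pass",
                lineage, len(ipsc), len(sc), int(passes.sum()), len(table))
    return DEResult(contrast=lineage, table=table,
                    fdr_threshold=config.fdr_threshold,
                    fc_threshold=config.fc_threshold)


def _fc_passes(a: np.ndarray, b: np.ndarray, lfc: np.ndarray,
               config: PipelineConfig) -> np.ndarray:
    if config.fc_scale == "log2":
        return np.abs(lfc) >= np.log2(config.fc_threshold)
    # linear scale: ratio of linear-scale group means
    ra = np.power(2.0, a).mean(axis=1)
    rb = np.power(2.0, b).mean(axis=1)
    ratio = np.maximum(ra / rb, rb / ra)
    return ratio >= config.fc_threshold


def select_signature(de_results: dict[str, DEResult]) -> dict[str, set[str]]:
    """Per-lineage passing gene sets (gene ids only)."""
    return {lineage: res.passing_genes() for lineage, res in de_results.items()}


def intersect_signature(de_results: dict[str, DEResult]) -> ExpressionSignature:
    """Intersect per-lineage passing sets into the expression signature.

    A gene is a member iff it passes in every lineage with the same sign of
    fold change; discordant-direction genes are dropped and logged. Per
    member the minimum linear fold-change magnitude and the maximum q-value
    across lineages are reported.
    """
    if len(de_results) < 2:
        raise ValidationError("need >= 2 lineages to intersect")
    lineages = list(de_results)
    passing = [de_results[l].passing_genes() for l in lineages]
    common = set.intersection(*passing)
    rows = []
    discordant = []
    for gene in sorted(common):
        lfcs = [_gene_value(de_results[l], gene, "log2_fold_change")
                for l in lineages]
        qs = [_gene_value(de_results[l], gene, "q_value") for l in lineages]
        signs = {np.sign(v) for v in lfcs}
        if len(signs) != 1:
            discordant.append(gene)
            continue
        direction = "up" if lfcs[0] > 0 else "down"
        rows.append({
            "gene_id": gene,
            "direction": direction,
            "min_abs_fold_change": float(2.0 ** min(abs(v) for v in lfcs)),
            "max_q_value": float(max(qs)),
        })
    if discordant:
        logger.info("excluded %d discordant-direction genes: %s",
                    len(discordant), discordant[:10])
    table = pd.DataFrame(rows, columns=["gene_id", "direction",
                                        "min_abs_fold_change", "max_q_value"])
    return ExpressionSignature(table=table)


def _gene_value(res: DEResult, gene: str, column: str) -> float:
    idx = res._gene_index if hasattr(res, "_gene_index") else None
    if idx is None:
        idx = {g: i for i, g in enumerate(res.table["gene_id"])}
        res._gene_index = idx  # cached; table is treated as immutable
    return float(res.table[column].iloc[idx[gene]])


def expression_signature(matrix: ExpressionMatrix,
                         config: PipelineConfig | None = None
                         ) -> tuple[dict[str, DEResult], ExpressionSignature]:
    """Run per-lineage DE tests and intersect them into the signature."""
    config = config or PipelineConfig()
    de_results = {l: de_test(matrix, l, config) for l in matrix.lineages()}
    return de_results, intersect_signature(de_results)
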