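"""Lectin-array quantification and the iPSC-vs-SC glycan signature.

Spots are averaged over replicates and background-subtracted; lectin
differences between iPSC and SC samples are tested with Student's t on log2
signals with BH-FDR across lectins; lectin signals are correlated with the
expression of their mapped glycosyltransferases; and the glycan signature
keeps the lectins that are both differential and backed by a mapped enzyme
inside the expression signature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .expression import bh_fdr, student_t_rows
from .io import logger
from .types import (
    ExpressionMatrix,
    ExpressionSignature,
    LGGMap,
    LectinArrayData,
    LectinSignalMatrix,
    PipelineConfig,
    SampleAnnotation,
    ValidationError,
)


def quantify_lectin(raw: LectinArrayData,
                    floor_value: float = 1.0) -> LectinSignalMatrix:
    """Average replicate spots and subtract background, flooring the result.

    signal(lectin, sample) = mean(replicates) - background, floored at
    ``floor_value`` (> 0) so downstream log transforms stay defined;
    flooring events are counted and logged.
    """
    if floor_value <= 0:
        raise ValidationError("floor_value must be positive")
    values = np.empty((len(raw.lectin_ids), len(raw.sample_ids)))
    n_floored = 0
    for i, lid in enumerate(raw.lectin_ids):
        for j, sid in enumerate(raw.sample_ids):
            key = (lid, sid)
            reps = raw.spots.get(key)
            if not reps:
                raise ValidationError(f"no replicates for {key}")
            signal = float(np.mean(reps)) - raw.backgrounds[key]
            if signal < floor_value:
                signal = floor_value
                n_floored += 1
            values[i, j] = signal
    if n_floored:
        logger.info("floored %d lectin signals at %g", n_floored, floor_value)
    return LectinSignalMatrix(lectin_ids=list(raw.lectin_ids),
                              sample_ids=list(raw.sample_ids),
                              values=values, floor_value=floor_value,
                              n_floored=n_floored)


def lectin_de_test(signals: LectinSignalMatrix,
                   annotations: dict[str, SampleAnnotation],
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-lectin Student t-test, iPSC vs SC pooled across lineages.

    Tests run on log2 signals by default (``config.lectin_scale``); BH-FDR
    is applied across lectins. Returns a frame with columns lectin_id,
    t_statistic, p_value, q_value, passes.
    """
    config = config or PipelineConfig()
    ipsc = [j for j, s in enumerate(signals.sample_ids)
            if annotations[s].cell_class == "iPSC"]
    sc = [j for j, s in enumerate(signals.sample_ids)
          if annotations[s].cell_class == "SC"]
    if len(ipsc) < 2 or len(sc) < 2:
        raise ValidationError("need >= 2 samples per cell class")
    vals = signals.values
    if config.lectin_scale == "log2":
        vals = np.log2(vals)
    t, p = student_t_rows(vals[:, ipsc], vals[:, sc])
    q = bh_fdr(p)
    passes = q < config.fdr_threshold
    logger.info("lectin DE: %d/%d lectins significant at FDR<%g",
                int(passes.sum()), len(signals.lectin_ids),
                config.fdr_threshold)
    return pd.DataFrame({
        "lectin_id": signals.lectin_ids,
        "t_statistic": t,
        "p_value": p,
        "q_value": q,
        "passes": passes,
    })


def lectin_gt_correlation(signals: LectinSignalMatrix,
                          expression: ExpressionMatrix,
                          lgg_map: LGGMap,
                          config: PipelineConfig | None = None
                          ) -> pd.DataFrame:
    """Pearson correlation of each mapped (lectin, enzyme) pair.

    Correlations run across the samples shared by the two tables, on log2
    signal vs log2 expression (expression values are already log2). The
    two-sided p-value uses the t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom. Pairs with fewer than 4 shared samples are
    skipped with a warning.
    """
    config = config or PipelineConfig()
    shared = [s for s in signals.sample_ids if s in set(expression.sample_ids)]
    lec_col = {s: j for j, s in enumerate(signals.sample_ids)}
    exp_col = {s: j for j, s in enumerate(expression.sample_ids)}
    gidx = expression.gene_index()
    lidx = {l: i for i, l in enumerate(signals.lectin_ids)}
    rows = []
    for lectin, gt in lgg_map.pairs():
        if lectin not in lidx or gt not in gidx:
            logger.warning("pair (%s, %s) not measured; skipped", lectin, gt)
            continue
        n = len(shared)
        if n < 4:
            logger.warning("pair (%s, %s): only %d shared samples; skipped",
                           lectin, gt, n)
            continue
        sig = signals.values[lidx[lectin], [lec_col[s] for s in shared]]
        if config.lectin_scale == "log2":
            sig = np.log2(sig)
        expr = expression.values[gidx[gt], [exp_col[s] for s in shared]]
        r = _pearson(sig, expr)
        p = _corr_p(r, n)
        rows.append({"lectin_id": lectin, "glycosyltransferase": gt,
                     "r": r, "p_value": p, "n": n})
    return pd.DataFrame(rows, columns=["lectin_id", "glycosyltransferase",
                                       "r", "p_value", "n"])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValidationError("zero-variance series in correlation")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _corr_p(r: float, n: int) -> float:
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * t_dist.sf(abs(t), n - 2))


def assemble_glycan_signature(lectin_de: pd.DataFrame,
                              lgg_map: LGGMap,
                              expression_signature: ExpressionSignature
                              ) -> pd.DataFrame:
    """Glycan signature: differential lectins whose mapped enzymes sit in
    the expression signature.

    A lectin qualifies iff it passes the lectin DE test AND at least one of
    its mapped glycosyltransferases is an expression-signature member; only
    the in-signature enzymes are emitted. Returns rows (lectin_id,
    glycosyltransferase, epitope, reaction).
    """
    passing = set(lectin_de.loc[lectin_de["passes"], "lectin_id"])
    sig_genes = expression_signature.genes
    rows = []
    for record in lgg_map.records:
        if record.lectin_id not in passing:
            continue
        for gt in sorted(record.glycosyltransferase_ids & sig_genes):
            rows.append({
                "lectin_id": record.lectin_id,
                "glycosyltransferase": gt,
                "epitope": record.epitope,
                "reaction": record.reaction_note,
            })
    table = pd.DataFrame(rows, columns=["lectin_id", "glycosyltransferase",
                                        "epitope", "reaction"])
    n_lec = table["lectin_id"].nunique() if len(table) else 0
    n_gt = table["glycosyltransferase"].nunique() if len(table) else 0
    logger.info("glycan signature: %d lectins over %d glycosyltransferases",
                n_lec, n_gt)
    return table


def glycan_signature_gts(signature_table: pd.DataFrame) -> set[str]:
    """Distinct enzymes backing the glycan signature."""
    if signature_table.empty:
        return set()
    return set(signature_table["glycosyltransferase"])
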