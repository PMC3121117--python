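"""Synthetic study-shaped data with known ground truth.

The generator emulates the shape of the real study: four somatic lineages,
each with one parental somatic-cell (SC) line and several iPSC lines over a
few passages; a genome-scale log2 expression matrix with a shared
iPSC-vs-SC differential component plus lineage-specific effects; regulatory
sub-networks that are either data-consistent (targets generated as linear-
Gaussian functions of their parents) or inconsistent (same topology, targets
independent); and a 43-lectin array whose coupled lectins are noisy monotone
functions of designated glycosyltransferase transcripts.

Every generator is a pure function of (design, seed); sub-stage RNG streams
are derived from the top-level seed and the stage name, so stages can be
re-run independently and still reproduce the full-bundle results.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (
    logger,
    write_edge_list,
    write_expression_table,
    write_lectin_table,
    write_lgg_map,
    write_metadata_table,
)
from .types import (
    ExpressionMatrix,
    LGGMap,
    LGGRecord,
    LectinArrayData,
    RegulatoryNetwork,
    SampleAnnotation,
    ValidationError,
)

DEFAULT_LINEAGES = ("AM", "PAE", "UtE", "MRC")


@dataclass
class SimulationDesign:
    """Knobs of the synthetic study; defaults emulate the real study shape."""

    n_genes: int = 2000
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    ipsc_lines_per_lineage: int = 3
    passages_per_line: int = 3
    sc_replicates: int = 3
    common_de_fraction: float = 0.10
    lineage_de_fraction: float = 0.05
    effect_size_log2: float = 2.0
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 8.0
    baseline_sd_log2: float = 1.5
    n_networks: int = 40
    nodes_per_network: tuple[int, int] = (8, 15)
    edge_coefficient: float = 0.8
    network_noise_sd: float = 0.5
    max_regulators: int = 4
    n_lectins: int = 43
    coupled_lectin_fraction: float = 0.5
    coupling_slope: float = 1.0
    replicate_cv: float = 0.05
    background_mean: float = 100.0
    n_replicate_spots: int = 3

    def __post_init__(self) -> None:
        for name in ("common_de_fraction", "lineage_de_fraction",
                     "coupled_lectin_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0,1], got {v}")
        if self.effect_size_log2 < 0:
            raise ValidationError("effect_size_log2 must be >= 0")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be >= 0")
        if not (1 <= self.ipsc_lines_per_lineage <= 3):
            raise ValidationError("ipsc_lines_per_lineage must be 1..3")


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every downstream stage."""

    rng_seed: int
    planted_common_de: dict[str, str] = field(default_factory=dict)
    planted_lineage_de: dict[str, dict[str, str]] = field(default_factory=dict)
    consistent_network_ids: set[str] = field(default_factory=set)
    inconsistent_network_ids: set[str] = field(default_factory=set)
    network_coefficients: dict[str, dict[str, float]] = field(
        default_factory=dict)
    lectin_couplings: dict[str, tuple[str, float]] = field(
        default_factory=dict)
    network_enzymes: set[str] = field(default_factory=set)
    decoy_network_enzymes: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["consistent_network_ids"] = sorted(self.consistent_network_ids)
        d["inconsistent_network_ids"] = sorted(self.inconsistent_network_ids)
        d["network_enzymes"] = sorted(self.network_enzymes)
        d["decoy_network_enzymes"] = sorted(self.decoy_network_enzymes)
        d["lectin_couplings"] = {k: list(v)
                                 for k, v in self.lectin_couplings.items()}
        return d

    def expected_candidates(self) -> set[str]:
        """Glycosyltransferases the full pipeline should nominate."""
        glycan_side = {gt for gt, slope in self.lectin_couplings.values()
                       if slope != 0 and gt in self.planted_common_de}
        return glycan_side | self.network_enzymes

    def lectin_couplings_gene_set(self) -> set[str]:
        return {gt for gt, _ in self.lectin_couplings.values()}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stage.encode())])


# ------------------------------------------------------------- expression

def simulate_expression(design: SimulationDesign,
                        seed: int) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Planted-differential log2 expression matrix plus its ground truth.

    Per-gene baselines are Normal(8, 1.5) log2 units; iPSC samples of every
    lineage are shifted by +/- effect_size_log2 on the planted common genes
    (sign = planted direction); lineage-specific genes are shifted only in
    that lineage's iPSC samples; i.i.d. Normal(0, noise_sd_log2) noise is
    added everywhere.
    """
    rng = _stage_rng(seed, "expression")
    n_ipsc = design.ipsc_lines_per_lineage * design.passages_per_line
    if design.sc_replicates < 2 or n_ipsc < 2:
        raise ValidationError("need >= 2 samples per group in every lineage")
    width = max(5, len(str(design.n_genes)))
    gene_ids = [f"G{i:0{width}d}" for i in range(design.n_genes)]

    annotations: dict[str, SampleAnnotation] = {}
    sample_ids: list[str] = []
    for lineage in design.lineages:
        for p in range(design.sc_replicates):
            sid = f"{lineage}_SC_p{p + 1}"
            sample_ids.append(sid)
            annotations[sid] = SampleAnnotation(
                sample_id=sid, lineage=lineage, cell_class="SC",
                line_id=f"{lineage}-SC", passage=p + 1)
        for li in range(design.ipsc_lines_per_lineage):
            for p in range(design.passages_per_line):
                sid = f"{lineage}_iPSC{li + 1}_p{p + 1}"
                sample_ids.append(sid)
                annotations[sid] = SampleAnnotation(
                    sample_id=sid, lineage=lineage, cell_class="iPSC",
                    line_id=f"{lineage}-iPSC{li + 1}", passage=p + 1)

    n_common = int(round(design.common_de_fraction * design.n_genes))
    n_per_lineage = int(round(design.lineage_de_fraction * design.n_genes))
    needed = n_common + n_per_lineage * len(design.lineages)
    if needed > design.n_genes:
        raise ValidationError("DE fractions exceed the gene universe")
    planted = rng.choice(design.n_genes, size=needed, replace=False)
    common_idx = planted[:n_common]
    truth = SyntheticTruth(rng_seed=seed)
    directions = rng.choice([1.0, -1.0], size=needed)
    for pos, gi in enumerate(common_idx):
        truth.planted_common_de[gene_ids[gi]] = (
            "up" if directions[pos] > 0 else "down")
    lineage_idx: dict[str, np.ndarray] = {}
    for k, lineage in enumerate(design.lineages):
        lo = n_common + k * n_per_lineage
        idx = planted[lo:lo + n_per_lineage]
        lineage_idx[lineage] = idx
        truth.planted_lineage_de[lineage] = {
            gene_ids[gi]: ("up" if directions[lo + off] > 0 else "down")
            for off, gi in enumerate(idx)
        }

    baseline = rng.normal(design.baseline_mean_log2, design.baseline_sd_log2,
                          size=design.n_genes)
    values = np.tile(baseline[:, None], (1, len(sample_ids)))
    sign = np.zeros(design.n_genes)
    sign[common_idx] = directions[:n_common]
    for j, sid in enumerate(sample_ids):
        a = annotations[sid]
        if a.cell_class != "iPSC":
            continue
        values[:, j] += sign * design.effect_size_log2
        idx = lineage_idx[a.lineage]
        lo = n_common + list(design.lineages).index(a.lineage) * n_per_lineage
        values[idx, j] += (directions[lo:lo + len(idx)]
                           * design.effect_size_log2)
    values += rng.normal(0.0, design.noise_sd_log2, size=values.shape)
    matrix = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                              values=values, annotations=annotations)
    logger.info("simulated expression: %d genes x %d samples, %d common and "
                "%d per-lineage planted genes", design.n_genes,
                len(sample_ids), n_common, n_per_lineage)
    return matrix, truth


# --------------------------------------------------------------- networks

def simulate_networks(design: SimulationDesign, matrix: ExpressionMatrix,
                      truth: SyntheticTruth, seed: int,
                      sample_scope: str = "iPSC_only"
                      ) -> tuple[list[RegulatoryNetwork], ExpressionMatrix]:
    """Plant consistent and inconsistent regulatory networks.

    Networks alternate consistent/inconsistent. Each has 1-4 regulator genes
    and a star/bipartite regulator->target topology. For consistent networks
    the target rows are regenerated within the scoring sample scope as
    sum(edge_coefficient x parent) + Normal(0, network_noise_sd), recentred
    so the target keeps its original scope mean (the differential structure
    planted by simulate_expression is preserved). Inconsistent networks get
    the same kind of topology but their targets stay independent of the
    parents. Consistent networks draw most targets from the planted common
    differential genes, so they are also signature-enriched; inconsistent
    networks draw from undifferential genes. Node sets are disjoint across
    networks.
    """
    rng = _stage_rng(seed, "networks")
    gidx = matrix.gene_index()
    lineage_genes = {g for per in truth.planted_lineage_de.values()
                     for g in per}
    common_pool = [g for g in matrix.gene_ids
                   if g in truth.planted_common_de
                   and g not in truth.lectin_couplings_gene_set()]
    null_pool = [g for g in matrix.gene_ids
                 if g not in truth.planted_common_de
                 and g not in lineage_genes]
    rng.shuffle(common_pool)
    rng.shuffle(null_pool)

    scope_cols = [j for j, s in enumerate(matrix.sample_ids)
                  if sample_scope == "all"
                  or matrix.annotations[s].cell_class == "iPSC"]
    values = matrix.values.copy()
    networks: list[RegulatoryNetwork] = []

    def draw(pool_a: list[str], pool_b: list[str], p_a: float) -> str:
        use_a = (rng.random() < p_a and pool_a) or not pool_b
        pool = pool_a if use_a else pool_b
        if not pool:
            raise ValidationError("gene pools exhausted for network nodes")
        return pool.pop()

    lo, hi = design.nodes_per_network
    for k in range(design.n_networks):
        nid = f"NET{k:03d}"
        consistent = k % 2 == 0
        n_nodes = int(rng.integers(lo, hi + 1))
        n_reg = int(min(rng.integers(1, design.max_regulators + 1),
                        n_nodes - 1))
        n_tgt = n_nodes - n_reg
        if consistent:
            # Regulators sit outside the planted differential pool (they are
            # excluded from the enrichment draw anyway); targets are mostly
            # planted common genes, making the network signature-enriched.
            regulators = [draw(null_pool, common_pool, 1.0)
                          for _ in range(n_reg)]
            targets = [draw(common_pool, null_pool, 0.9)
                       for _ in range(n_tgt)]
        else:
            regulators = [draw(null_pool, common_pool, 1.0)
                          for _ in range(n_reg)]
            targets = [draw(null_pool, common_pool, 1.0)
                       for _ in range(n_tgt)]
        # Star/bipartite topology: each target is bound by one regulator, so
        # regenerated targets keep the per-lineage variance of the planted
        # expression model and the two planted structures stay orthogonal.
        edges: set[tuple[str, str]] = set()
        for tgt in targets:
            reg = regulators[int(rng.integers(0, n_reg))]
            edges.add((reg, tgt))
        net = RegulatoryNetwork(network_id=nid,
                                nodes=frozenset(regulators + targets),
                                edges=frozenset(edges))
        networks.append(net)
        if consistent:
            truth.consistent_network_ids.add(nid)
            coeffs: dict[str, float] = {}
            parent_map = net.parents()
            for tgt in targets:
                row = gidx[tgt]
                parents = parent_map[tgt]
                contrib = np.zeros(len(scope_cols))
                for reg in parents:
                    contrib += (design.edge_coefficient
                                * values[gidx[reg], scope_cols])
                    coeffs[f"{reg}->{tgt}"] = design.edge_coefficient
                noise = rng.normal(0.0, design.network_noise_sd,
                                   size=len(scope_cols))
                orig_mean = values[row, scope_cols].mean()
                new = contrib + noise
                values[row, scope_cols] = new - new.mean() + orig_mean
            truth.network_coefficients[nid] = coeffs
        else:
            truth.inconsistent_network_ids.add(nid)
    out = ExpressionMatrix(gene_ids=list(matrix.gene_ids),
                           sample_ids=list(matrix.sample_ids),
                           values=values, annotations=dict(matrix.annotations))
    logger.info("simulated %d networks (%d consistent)", len(networks),
                len(truth.consistent_network_ids))
    return networks, out


# ----------------------------------------------------------------- lectins

def simulate_lectin(design: SimulationDesign, matrix: ExpressionMatrix,
                    gt_gene_ids: list[str], truth: SyntheticTruth,
                    seed: int) -> LectinArrayData:
    """Lectin-array spot table coupled to glycosyltransferase transcripts.

    Coupled lectins have a per-sample true signal of
    2^(slope x log2-expression of the coupled enzyme + intercept); uncoupled
    lectins are log-normal noise. Replicate spots multiply the true signal
    by (1 + Normal(0, replicate_cv)); backgrounds are
    Normal(background_mean, background_mean/10) truncated at 0.
    """
    rng = _stage_rng(seed, "lectin")
    if design.replicate_cv < 0:
        raise ValidationError("replicate_cv must be >= 0")
    n_coupled = int(round(design.coupled_lectin_fraction * design.n_lectins))
    if len(gt_gene_ids) < n_coupled:
        raise ValidationError(
            f"need >= {n_coupled} enzyme genes, got {len(gt_gene_ids)}")
    missing = [g for g in gt_gene_ids if g not in set(matrix.gene_ids)]
    if missing:
        raise ValidationError(f"enzyme genes not in expression: {missing}")
    lectin_ids = [f"LEC{i:02d}" for i in range(design.n_lectins)]
    coupled = list(rng.choice(design.n_lectins, size=n_coupled,
                              replace=False))
    gidx = matrix.gene_index()
    gt_for = {}
    for pos, li in enumerate(sorted(coupled)):
        gt_for[lectin_ids[li]] = gt_gene_ids[pos]

    spots: dict[tuple[str, str], list[float]] = {}
    backgrounds: dict[tuple[str, str], float] = {}
    for lid in lectin_ids:
        if lid in gt_for:
            gt = gt_for[lid]
            expr = matrix.values[gidx[gt]]
            intercept = 11.0 - design.coupling_slope * expr.mean()
            log2_true = design.coupling_slope * expr + intercept
            truth.lectin_couplings[lid] = (gt, design.coupling_slope)
        else:
            log2_true = rng.normal(11.0, 1.0, size=matrix.n_samples)
        true_signal = np.power(2.0, log2_true)
        for j, sid in enumerate(matrix.sample_ids):
            reps = true_signal[j] * (
                1.0 + rng.normal(0.0, design.replicate_cv,
                                 size=design.n_replicate_spots))
            reps = np.maximum(reps, 0.0)
            bg = max(rng.normal(design.background_mean,
                                design.background_mean / 10.0), 0.0)
            spots[(lid, sid)] = [float(r) for r in reps]
            backgrounds[(lid, sid)] = float(bg)
    logger.info("simulated lectin array: %d lectins (%d coupled) x %d "
                "samples", design.n_lectins, n_coupled, matrix.n_samples)
    return LectinArrayData(lectin_ids=lectin_ids,
                           sample_ids=list(matrix.sample_ids),
                           spots=spots, backgrounds=backgrounds)


def build_lgg_map(truth: SyntheticTruth, lectin_ids: list[str],
                  decoy_genes: list[str]) -> LGGMap:
    """LGG relation table for the synthetic study.

    Coupled lectins map to their driving enzyme; uncoupled lectins map to
    decoy (undifferential) genes so they can never contribute a signature
    enzyme even if a test is marginally significant.
    """
    records = []
    di = 0
    for lid in lectin_ids:
        if lid in truth.lectin_couplings:
            gt, _ = truth.lectin_couplings[lid]
            records.append(LGGRecord(
                lectin_id=lid, epitope=f"epitope-{gt}",
                glycosyltransferase_ids=frozenset({gt}),
                reaction_note=f"{gt} builds the {lid} ligand"))
        else:
            decoy = decoy_genes[di % len(decoy_genes)]
            di += 1
            records.append(LGGRecord(
                lectin_id=lid, epitope="uncharacterized",
                glycosyltransferase_ids=frozenset({decoy}),
                reaction_note="no known coupling"))
    return LGGMap(records=records)


# ------------------------------------------------------ glycan stage fixture

@dataclass
class GlycanFixture:
    """Synthetic glycan-stage fixture with an unambiguous expected outcome."""

    matrix: ExpressionMatrix
    lectin_data: LectinArrayData
    lgg_map: LGGMap
    expected_lectins: set[str]
    expected_gts: set[str]


def simulate_glycan_fixture(seed: int = 20750) -> GlycanFixture:
    """Construct a glycan-signature fixture: exactly 16 qualifying lectins
    over 12 glycosyltransferases.

    The fixture (synthetic, clearly separated: effect size 4 log2 units so
    every planted enzyme survives the four-way signature) contains:
    16 lectins coupled to 12 planted differential enzymes (four enzymes feed
    two lectins each, exercising the redundant many-to-one relations);
    4 decoy lectins that are differential but map only to undifferential
    genes; and 23 uncoupled noise lectins mapped to undifferential genes.
    Only the 16 coupled lectins may enter the glycan signature.
    """
    design = SimulationDesign(effect_size_log2=4.0)
    matrix, truth = simulate_expression(design, seed)
    rng = _stage_rng(seed, "glycan-fixture")
    common = sorted(truth.planted_common_de)
    picks = [str(g) for g in rng.choice(common, size=16, replace=False)]
    gts, drivers = picks[:12], picks[12:]
    non_de = sorted(set(matrix.gene_ids) - set(common)
                    - {g for per in truth.planted_lineage_de.values()
                       for g in per})
    decoys = [str(g) for g in rng.choice(non_de, size=30, replace=False)]

    lectin_ids = [f"LEC{i:02d}" for i in range(design.n_lectins)]
    couple_gt = {lectin_ids[i]: gts[i] for i in range(12)}
    couple_gt.update({lectin_ids[12 + i]: gts[i] for i in range(4)})
    couple_driver = {lectin_ids[16 + i]: drivers[i] for i in range(4)}

    gidx = matrix.gene_index()
    spots: dict[tuple[str, str], list[float]] = {}
    backgrounds: dict[tuple[str, str], float] = {}
    records = []
    for pos, lid in enumerate(lectin_ids):
        if lid in couple_gt:
            driver = couple_gt[lid]
            mapped = couple_gt[lid]
            epitope = f"epitope-{mapped}"
        elif lid in couple_driver:
            driver = couple_driver[lid]
            mapped = decoys[pos % len(decoys)]
            epitope = "off-target"
        else:
            driver = None
            mapped = decoys[pos % len(decoys)]
            epitope = "uncharacterized"
        if driver is not None:
            expr = matrix.values[gidx[driver]]
            log2_true = expr + (11.0 - expr.mean())
        else:
            log2_true = rng.normal(11.0, 1.0, size=matrix.n_samples)
        true_signal = np.power(2.0, log2_true)
        for j, sid in enumerate(matrix.sample_ids):
            reps = np.maximum(true_signal[j] * (
                1.0 + rng.normal(0.0, design.replicate_cv,
                                 size=design.n_replicate_spots)), 0.0)
            spots[(lid, sid)] = [float(r) for r in reps]
            backgrounds[(lid, sid)] = float(max(
                rng.normal(design.background_mean,
                           design.background_mean / 10.0), 0.0))
        records.append(LGGRecord(lectin_id=lid, epitope=epitope,
                                 glycosyltransferase_ids=frozenset({mapped}),
                                 reaction_note=""))
    data = LectinArrayData(lectin_ids=lectin_ids,
                           sample_ids=list(matrix.sample_ids),
                           spots=spots, backgrounds=backgrounds)
    return GlycanFixture(matrix=matrix, lectin_data=data,
                         lgg_map=LGGMap(records=records),
                         expected_lectins=set(couple_gt),
                         expected_gts=set(gts))


# ------------------------------------------------------------- full bundle

@dataclass
class SyntheticBundle:
    """All inputs of one synthetic study plus its ground truth."""

    design: SimulationDesign
    matrix: ExpressionMatrix
    networks: list[RegulatoryNetwork]
    lectin_data: LectinArrayData
    lgg_map: LGGMap
    truth: SyntheticTruth


def simulate_all(design: SimulationDesign | None = None,
                 seed: int = 20750) -> SyntheticBundle:
    """Generate a complete synthetic study (expression, networks, lectins,
    LGG map, truth) from one seed."""
    design = design or SimulationDesign()
    matrix, truth = simulate_expression(design, seed)
    rng = _stage_rng(seed, "assignment")

    # Reserve planted-common genes as lectin-coupled enzymes before the
    # networks consume the pool; reserve undifferential decoys as well.
    n_coupled = int(round(design.coupled_lectin_fraction * design.n_lectins))
    common_genes = sorted(truth.planted_common_de)
    lineage_genes = {g for per in truth.planted_lineage_de.values()
                     for g in per}
    if n_coupled > len(common_genes):
        raise ValidationError("not enough planted genes for lectin coupling")
    gt_gene_ids = [str(g) for g in rng.choice(common_genes, size=n_coupled,
                                              replace=False)]
    for g in gt_gene_ids:  # mark as reserved for simulate_networks
        truth.lectin_couplings[f"_reserved_{g}"] = (g, design.coupling_slope)

    networks, matrix = simulate_networks(design, matrix, truth, seed)
    for g in list(truth.lectin_couplings):
        if g.startswith("_reserved_"):
            del truth.lectin_couplings[g]

    lectin_data = simulate_lectin(design, matrix, gt_gene_ids, truth, seed)

    # Designate a few consistent-network targets as enzymes on the network
    # side of the integration, plus decoys from inconsistent networks that a
    # correct screen must not nominate.
    cons = [n for n in networks
            if n.network_id in truth.consistent_network_ids]
    incons = [n for n in networks
              if n.network_id in truth.inconsistent_network_ids]
    for net in cons[:4]:
        tgt = sorted(net.nodes - net.regulators())[0]
        truth.network_enzymes.add(tgt)
    for net in incons[:2]:
        tgt = sorted(net.nodes - net.regulators())[0]
        truth.decoy_network_enzymes.add(tgt)

    decoys = sorted(set(matrix.gene_ids) - set(common_genes)
                    - lineage_genes
                    - {g for net in networks for g in net.nodes})
    lgg = build_lgg_map(truth, lectin_data.lectin_ids, decoys[:30])
    return SyntheticBundle(design=design, matrix=matrix, networks=networks,
                           lectin_data=lectin_data, lgg_map=lgg, truth=truth)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict:
    """Write all bundle inputs as TSV/JSON files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "networks": outdir / "networks.tsv",
        "lectin": outdir / "lectin.tsv",
        "lgg": outdir / "lgg_map.tsv",
        "truth": outdir / "truth.json",
        "planted_sets": outdir / "planted_sets.gmt",
        "network_enzymes": outdir / "network_enzymes.txt",
    }
    write_expression_table(bundle.matrix, paths["expression"])
    write_metadata_table(bundle.matrix.annotations, paths["metadata"])
    write_edge_list(bundle.networks, paths["networks"])
    write_lectin_table(bundle.lectin_data, paths["lectin"])
    write_lgg_map(bundle.lgg_map, paths["lgg"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(bundle.truth.to_dict(), fh, indent=1, sort_keys=True)
    with open(paths["planted_sets"], "w", encoding="utf-8") as fh:
        common = sorted(bundle.truth.planted_common_de)
        fh.write("\t".join(["planted_common", "shared iPSC-vs-SC genes",
                            *common]) + "\n")
        for lineage, per in bundle.truth.planted_lineage_de.items():
            fh.write("\t".join([f"planted_{lineage}",
                                f"{lineage}-specific genes",
                                *sorted(per)]) + "\n")
    with open(paths["network_enzymes"], "w", encoding="utf-8") as fh:
        for g in sorted(bundle.truth.network_enzymes
                        | bundle.truth.decoy_network_enzymes):
            fh.write(g + "\n")
    return {k: str(v) for k, v in paths.items()}
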