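"""Domain types shared by every pipeline stage.

All containers are plain dataclasses around numpy/pandas objects; gene and
sample identifiers are opaque, case-sensitive strings (no symbol aliasing —
callers must pre-harmonize OCT3/4-vs-POU5F1 style aliases before loading).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
import pandas as pd


class GlycolinkError(Exception):
    """Base class for pipeline errors."""


class ParseError(GlycolinkError):
    """Raised when an input file violates its format contract."""


class ValidationError(GlycolinkError):
    """Raised when an in-memory object violates a domain invariant."""


CELL_CLASSES = ("iPSC", "SC")


@dataclass(frozen=True)
class SampleAnnotation:
    """Metadata for one array sample.

    ``cell_class`` separates induced pluripotent stem cells (iPSC) from their
    parental somatic cells (SC); ``lineage`` names the somatic source (e.g.
    AM, PAE, UtE, MRC); ``passage`` is the culture passage number.
    """

    sample_id: str
    lineage: str
    cell_class: str
    line_id: str
    passage: int

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValidationError(
                f"cell_class must be one of {CELL_CLASSES}, got {self.cell_class!r}"
            )
        if self.passage < 0:
            raise ValidationError(f"passage must be non-negative, got {self.passage}")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of background-corrected log2 intensities."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    annotations: dict[str, SampleAnnotation]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g, s = len(self.gene_ids), len(self.sample_ids)
        if self.values.shape != (g, s):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{g} genes x {s} samples"
            )
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        missing = [s_ for s_ in self.sample_ids if s_ not in self.annotations]
        if missing:
            raise ValidationError(f"samples missing annotation: {missing}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def samples_where(self, lineage: str | None = None,
                      cell_class: str | None = None) -> list[str]:
        """Sample ids matching the given lineage and/or cell class."""
        out = []
        for s in self.sample_ids:
            a = self.annotations[s]
            if lineage is not None and a.lineage != lineage:
                continue
            if cell_class is not None and a.cell_class != cell_class:
                continue
            out.append(s)
        return out

    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.annotations[s].lineage, None)
        return list(seen)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        col = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [col[s] for s in ids]
        return ExpressionMatrix(
            gene_ids=list(self.gene_ids),
            sample_ids=ids,
            values=self.values[:, idx],
            annotations={s: self.annotations[s] for s in ids},
        )


@dataclass
class RawIntensityTable:
    """Raw one-color array intensities before background correction."""

    gene_ids: list[str]
    sample_ids: list[str]
    foreground: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        self.foreground = np.asarray(self.foreground, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        shape = (len(self.gene_ids), len(self.sample_ids))
        if self.foreground.shape != shape or self.background.shape != shape:
            raise ValidationError("foreground/background shape mismatch")
        if not np.all(np.isfinite(self.foreground)):
            raise ValidationError("foreground intensities must be finite")
        if np.any(self.background < 0):
            raise ValidationError("background intensities must be non-negative")


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): set_id -> (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {sid!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def description(self, set_id: str) -> str:
        return self.sets[set_id][0]

    def ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class RegulatoryNetwork:
    """Directed acyclic regulator->target graph over measured genes."""

    network_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValidationError(
                    f"network {self.network_id}: self-edge {u}->{v}"
                )
            if u not in self.nodes or v not in self.nodes:
                raise ValidationError(
                    f"network {self.network_id}: edge endpoint outside node set"
                )
        if self._has_cycle():
            raise ValidationError(f"network {self.network_id} contains a cycle")

    def _has_cycle(self) -> bool:
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return not nx.is_directed_acyclic_graph(g)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def parents(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {n: [] for n in sorted(self.nodes)}
        for u, v in sorted(self.edges):
            out[v].append(u)
        return out

    def regulators(self) -> frozenset[str]:
        """Nodes with out-edges (TF-like sources)."""
        return frozenset(u for u, _ in self.edges)

    def targets(self) -> frozenset[str]:
        return frozenset(v for _, v in self.edges)


@dataclass
class DEResult:
    """Per-gene two-group differential expression results for one contrast.

    ``table`` columns: gene_id, mean_a, mean_b, t_statistic, p_value, q_value,
    log2_fold_change (A - B), passes.
    """

    contrast: str
    table: pd.DataFrame
    fdr_threshold: float
    fc_threshold: float

    def passing_genes(self) -> set[str]:
        return set(self.table.loc[self.table["passes"], "gene_id"])

    def directions(self) -> dict[str, str]:
        sub = self.table[self.table["passes"]]
        return {
            g: ("up" if fc > 0 else "down")
            for g, fc in zip(sub["gene_id"], sub["log2_fold_change"])
        }


@dataclass
class ExpressionSignature:
    """Genes differential in every lineage with concordant direction.

    ``table`` columns: gene_id, direction (up/down in iPSC),
    min_abs_fold_change (linear scale, minimum magnitude across lineages),
    max_q_value (maximum FDR across lineages).
    """

    table: pd.DataFrame

    @property
    def genes(self) -> set[str]:
        return set(self.table["gene_id"])

    def direction(self, gene: str) -> str:
        row = self.table[self.table["gene_id"] == gene]
        return str(row["direction"].iloc[0])

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.table["gene_id"])


@dataclass
class GcpResult:
    """Graph-consistency probability of one network.

    ``gcp`` is the plus-one empirical upper-tail probability of the observed
    Gaussian-network log-likelihood within the null distribution from random
    networks with identical node and edge counts.
    """

    observed_ll: float
    null_lls: np.ndarray
    gcp: float
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.null_lls = np.asarray(self.null_lls, dtype=float)
        if not (0.0 < self.gcp <= 1.0):
            raise ValidationError(f"gcp must lie in (0, 1], got {self.gcp}")


@dataclass
class NetworkScreenRecord:
    """Screening outcome for one reference network."""

    network_id: str
    n_nodes: int
    n_edges: int
    n_signature_genes: int
    enrichment_p: float
    observed_log_likelihood: float | None
    gcp: float | None
    passes_enrichment: bool
    passes_gcp: bool
    in_signature: bool

    def __post_init__(self) -> None:
        if self.in_signature != (self.passes_enrichment and self.passes_gcp):
            raise ValidationError(
                "in_signature must equal passes_enrichment AND passes_gcp"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkScreenRecord":
        return cls(**d)


@dataclass
class LectinArrayData:
    """Raw lectin-array spots: replicate foregrounds plus one background
    per (lectin, sample)."""

    lectin_ids: list[str]
    sample_ids: list[str]
    spots: dict[tuple[str, str], list[float]]
    backgrounds: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        _check_unique(self.lectin_ids, "lectin id")
        _check_unique(self.sample_ids, "sample id")
        for key, reps in self.spots.items():
            if any(r < 0 for r in reps):
                raise ValidationError(f"negative intensity for {key}")

    def replicate_counts(self) -> set[int]:
        return {len(v) for v in self.spots.values()}


@dataclass
class LectinSignalMatrix:
    """Averaged, background-subtracted lectin signals (lectins x samples)."""

    lectin_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    floor_value: float
    n_floored: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < self.floor_value):
            raise ValidationError("signals below configured floor")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.lectin_ids,
                            columns=self.sample_ids)


@dataclass(frozen=True)
class LGGRecord:
    """One curated lectin - glycan epitope - glycosyltransferase relation."""

    lectin_id: str
    epitope: str
    glycosyltransferase_ids: frozenset[str]
    reaction_note: str = ""


@dataclass
class LGGMap:
    """Curated lectin/glycan/glycosyltransferase relation table.

    Relations are many-to-many ("redundant"): a lectin may report epitopes
    built by several enzymes, and one enzyme may feed several lectins.
    """

    records: list[LGGRecord] = field(default_factory=list)

    def glycosyltransferases(self) -> set[str]:
        out: set[str] = set()
        for r in self.records:
            out |= r.glycosyltransferase_ids
        return out

    def lectins(self) -> set[str]:
        return {r.lectin_id for r in self.records}

    def for_lectin(self, lectin_id: str) -> list[LGGRecord]:
        return [r for r in self.records if r.lectin_id == lectin_id]

    def pairs(self) -> list[tuple[str, str]]:
        """Distinct (lectin, glycosyltransferase) pairs in record order."""
        seen: dict[tuple[str, str], None] = {}
        for r in self.records:
            for gt in sorted(r.glycosyltransferase_ids):
                seen.setdefault((r.lectin_id, gt), None)
        return list(seen)


@dataclass
class PipelineConfig:
    """Thresholds and sizes shared across the pipeline stages."""

    fdr_threshold: float = 0.05
    fc_threshold: float = 2.0
    enrichment_alpha: float = 0.05
    gcp_alpha: float = 0.05
    n_random_networks: int = 2000
    normexp_offset: float = 16.0
    lectin_floor: float = 1.0
    background_universe_size: int | None = None
    rng_seed: int = 20750
    sample_scope_for_gcp: str = "iPSC_only"
    fc_scale: str = "log2"
    lectin_scale: str = "log2"

    def __post_init__(self) -> None:
        for name in ("fdr_threshold", "enrichment_alpha", "gcp_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0,1), got {v}")
        if self.fc_threshold <= 0:
            raise ValidationError("fc_threshold must be positive")
        if self.n_random_networks < 1:
            raise ValidationError("n_random_networks must be >= 1")
        if self.sample_scope_for_gcp not in ("iPSC_only", "all"):
            raise ValidationError(
                "sample_scope_for_gcp must be 'iPSC_only' or 'all'"
            )
        if self.fc_scale not in ("log2", "linear"):
            raise ValidationError("fc_scale must be 'log2' or 'linear'")
        if self.lectin_scale not in ("log2", "linear"):
            raise ValidationError("lectin_scale must be 'log2' or 'linear'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


def _check_unique(ids: Iterable[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind}: {i!r}")
        seen.add(i)
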