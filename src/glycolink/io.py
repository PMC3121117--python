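"""Readers and writers for the pipeline's tab-separated interchange formats.

Dialect: UTF-8 TSV, lines starting with ``#`` are comments, floats are
written with 9 significant digits so that write -> parse round-trips are
identity up to float formatting. All parsers preserve file order.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ExpressionMatrix,
    GeneSetCollection,
    LGGMap,
    LGGRecord,
    LectinArrayData,
    ParseError,
    PipelineConfig,
    RegulatoryNetwork,
    SampleAnnotation,
    ValidationError,
)

logger = logging.getLogger("glycolink")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

FLOAT_FMT = "%.9g"


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    """Non-comment, non-blank lines with their 1-based line numbers."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line))
    return out


# ---------------------------------------------------------------- expression

def parse_metadata_table(path: str | Path) -> dict[str, SampleAnnotation]:
    """Sample metadata TSV: sample_id, lineage, cell_class, line_id, passage."""
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty metadata file")
    header = lines[0][1].split("\t")
    required = ["sample_id", "lineage", "cell_class", "line_id", "passage"]
    if header[: len(required)] != required:
        raise ParseError(f"{path}: metadata header must start with {required}")
    out: dict[str, SampleAnnotation] = {}
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields")
        sid = fields[0]
        if sid in out:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        out[sid] = SampleAnnotation(
            sample_id=sid,
            lineage=fields[1],
            cell_class=fields[2],
            line_id=fields[3],
            passage=int(fields[4]),
        )
    return out


def parse_expression_table(path: str | Path,
                           metadata_path: str | Path) -> ExpressionMatrix:
    """Load a genes x samples log2-intensity TSV with joined annotations.

    First column holds gene ids, header row holds sample ids; row and column
    order is preserved from the file.
    """
    annotations = parse_metadata_table(metadata_path)
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    header = lines[0][1].split("\t")
    sample_ids = header[1:]
    seen_s: set[str] = set()
    for s in sample_ids:
        if s in seen_s:
            raise ParseError(f"{path}: duplicate sample id {s!r}")
        seen_s.add(s)
    missing = [s for s in sample_ids if s not in annotations]
    if missing:
        raise ParseError(
            f"{path}: samples absent from metadata: {missing}"
        )
    gene_ids: list[str] = []
    seen_g: set[str] = set()
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, "
                f"got {len(fields)}"
            )
        gid = fields[0]
        if gid in seen_g:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        seen_g.add(gid)
        gene_ids.append(gid)
        rows.append([float(x) for x in fields[1:]])
    mat = ExpressionMatrix(
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        values=np.asarray(rows, dtype=float),
        annotations={s: annotations[s] for s in sample_ids},
    )
    logger.info("loaded expression matrix %d genes x %d samples from %s",
                mat.n_genes, mat.n_samples, path)
    return mat


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gid in enumerate(matrix.gene_ids):
            vals = "\t".join(FLOAT_FMT % v for v in matrix.values[i])
            fh.write(f"{gid}\t{vals}\n")


def write_metadata_table(annotations: dict[str, SampleAnnotation],
                         path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tlineage\tcell_class\tline_id\tpassage\n")
        for a in annotations.values():
            fh.write(f"{a.sample_id}\t{a.lineage}\t{a.cell_class}\t"
                     f"{a.line_id}\t{a.passage}\n")


# ----------------------------------------------------------------- gene sets

def parse_gmt(path: str | Path) -> GeneSetCollection:
    """GMT gene sets: set_id TAB description TAB member TAB member ...

    Members are deduplicated (first occurrence kept implicitly by set
    semantics); empty member fields are dropped.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"{path}:{lineno}: GMT line needs >= 3 fields, got {len(fields)}"
            )
        sid, desc = fields[0], fields[1]
        members = frozenset(m for m in fields[2:] if m)
        if sid in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set id {sid!r}")
        sets[sid] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in collection.ids():
            desc = collection.description(sid)
            members = sorted(collection.members(sid))
            fh.write("\t".join([sid, desc, *members]) + "\n")


# ------------------------------------------------------------------ networks

def parse_edge_list(path: str | Path) -> list[RegulatoryNetwork]:
    """Edge-list TSV (network_id, regulator, target) -> one DAG per id.

    Acyclicity and the no-self-edge rule are verified on load; violations
    raise naming the offending network.
    """
    lines = _data_lines(path)
    if not lines:
        return []
    header = lines[0][1].split("\t")
    if header[:3] != ["network_id", "regulator", "target"]:
        raise ParseError(
            f"{path}: header must be network_id/regulator/target"
        )
    edges_by_net: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 fields")
        nid, reg, tgt = fields[0], fields[1], fields[2]
        if reg == tgt:
            raise ParseError(
                f"{path}:{lineno}: self-edge {reg}->{tgt} in network {nid}"
            )
        edges_by_net.setdefault(nid, []).append((reg, tgt))
    networks = []
    for nid, edges in edges_by_net.items():
        nodes = frozenset(u for e in edges for u in e)
        try:
            net = RegulatoryNetwork(network_id=nid, nodes=nodes,
                                    edges=frozenset(edges))
        except ValidationError as exc:
            raise ParseError(f"{path}: network {nid}: {exc}") from exc
        networks.append(net)
    logger.info("loaded %d regulatory networks from %s", len(networks), path)
    return networks


def write_edge_list(networks: list[RegulatoryNetwork],
                    path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("network_id\tregulator\ttarget\n")
        for net in networks:
            for reg, tgt in sorted(net.edges):
                fh.write(f"{net.network_id}\t{reg}\t{tgt}\n")


# -------------------------------------------------------------- lectin array

def parse_lectin_table(path: str | Path) -> LectinArrayData:
    """Lectin spot TSV: lectin_id, sample_id, replicate_index, intensity,
    background.

    Replicate lists are assembled per (lectin, sample) in replicate-index
    order; gaps in the index are kept as shorter lists with a logged warning.
    """
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty lectin file")
    header = lines[0][1].split("\t")
    required = ["lectin_id", "sample_id", "replicate_index", "intensity",
                "background"]
    if header[:5] != required:
        raise ParseError(f"{path}: lectin header must be {required}")
    lectin_ids: list[str] = []
    sample_ids: list[str] = []
    reps: dict[tuple[str, str], dict[int, float]] = {}
    backgrounds: dict[tuple[str, str], float] = {}
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields")
        lid, sid = fields[0], fields[1]
        ridx = int(fields[2])
        intensity = float(fields[3])
        if intensity < 0:
            raise ParseError(
                f"{path}:{lineno}: negative intensity {intensity} for "
                f"({lid}, {sid})"
            )
        if lid not in lectin_ids:
            lectin_ids.append(lid)
        if sid not in sample_ids:
            sample_ids.append(sid)
        key = (lid, sid)
        reps.setdefault(key, {})[ridx] = intensity
        backgrounds[key] = float(fields[4])
    spots: dict[tuple[str, str], list[float]] = {}
    for key, by_idx in reps.items():
        idxs = sorted(by_idx)
        if idxs != list(range(idxs[0], idxs[0] + len(idxs))):
            logger.warning("replicate index gap for %s; keeping %d replicates",
                           key, len(idxs))
        spots[key] = [by_idx[i] for i in idxs]
    return LectinArrayData(lectin_ids=lectin_ids, sample_ids=sample_ids,
                           spots=spots, backgrounds=backgrounds)


def write_lectin_table(data: LectinArrayData, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lectin_id\tsample_id\treplicate_index\tintensity\t"
                 "background\n")
        for lid in data.lectin_ids:
            for sid in data.sample_ids:
                key = (lid, sid)
                if key not in data.spots:
                    continue
                bg = data.backgrounds[key]
                for ridx, val in enumerate(data.spots[key], start=1):
                    fh.write(f"{lid}\t{sid}\t{ridx}\t" + FLOAT_FMT % val +
                             "\t" + FLOAT_FMT % bg + "\n")


# ------------------------------------------------------------------- LGG map

def parse_lgg_map(path: str | Path) -> LGGMap:
    """Lectin-glycan-glycosyltransferase map TSV: lectin_id, epitope,
    glycosyltransferases (semicolon-joined), note."""
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty LGG map file")
    header = lines[0][1].split("\t")
    if header[:3] != ["lectin_id", "epitope", "glycosyltransferases"]:
        raise ParseError(
            f"{path}: LGG header must start with lectin_id/epitope/"
            "glycosyltransferases"
        )
    records = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 fields")
        gts = frozenset(g.strip() for g in fields[2].split(";") if g.strip())
        note = fields[3] if len(fields) > 3 else ""
        records.append(LGGRecord(lectin_id=fields[0], epitope=fields[1],
                                 glycosyltransferase_ids=gts,
                                 reaction_note=note))
    return LGGMap(records=records)


def write_lgg_map(lgg: LGGMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("lectin_id\tepitope\tglycosyltransferases\tnote\n")
        for r in lgg.records:
            gts = ";".join(sorted(r.glycosyltransferase_ids))
            fh.write(f"{r.lectin_id}\t{r.epitope}\t{gts}\t{r.reaction_note}\n")


# --------------------------------------------------------------------- misc

def load_config(path: str | Path) -> PipelineConfig:
    """Pipeline configuration from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        d = json.loads(text)
    else:
        d = yaml.safe_load(text) or {}
    return PipelineConfig.from_dict(d)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path,
                     index_name: str = "id") -> None:
    """Generic labelled-matrix writer using the package float format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(index_name + "\t" + "\t".join(map(str, frame.columns)) + "\n")
        for idx, row in zip(frame.index, frame.to_numpy()):
            fh.write(str(idx) + "\t" +
                     "\t".join(FLOAT_FMT % v for v in row) + "\n")
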