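"""Integration of the network and glycan signatures into candidate
glycosyltransferases bridging the transcriptional and cell-surface states.

The candidate list is the union of (a) glycan-related enzymes among the
genes of the screened network signature and (b) the enzymes backing the
glycan signature; genes on both sides are tagged "both". A curated pathway
table annotates each candidate with its function class and the glycan
structure it builds.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .types import LGGMap, ValidationError

_EVIDENCE_ORDER = {"both": 0, "network": 1, "glycan": 2}


def candidate_glycosyltransferases(network_signature_gts: set[str],
                                   glycan_signature_gts: set[str]
                                   ) -> pd.DataFrame:
    """Union of the two enzyme sets with per-gene evidence tags.

    Returns a frame with columns (gene, evidence), evidence in
    {network, glycan, both}, sorted by evidence class then gene for a
    stable output.
    """
    rows = []
    for gene in sorted(network_signature_gts | glycan_signature_gts):
        in_net = gene in network_signature_gts
        in_gly = gene in glycan_signature_gts
        evidence = "both" if (in_net and in_gly) else (
            "network" if in_net else "glycan")
        rows.append({"gene": gene, "evidence": evidence})
    table = pd.DataFrame(rows, columns=["gene", "evidence"])
    if len(table):
        table = table.sort_values(
            by=["evidence", "gene"],
            key=lambda s: s.map(_EVIDENCE_ORDER) if s.name == "evidence"
            else s,
        ).reset_index(drop=True)
    return table


def select_enzymes(genes: set[str], lgg_map: LGGMap,
                   extra_enzymes: set[str] | None = None) -> set[str]:
    """Restrict a gene set to the known enzyme universe.

    The universe is the set of glycosyltransferases named in the LGG map
    plus an optional user-supplied list (the explicit stand-in for the
    narrative hand-picking of glycan-related genes from pathway diagrams).
    """
    universe = lgg_map.glycosyltransferases() | (extra_enzymes or set())
    return genes & universe


def pathway_annotation(candidates: pd.DataFrame,
                       pathway_table: pd.DataFrame) -> pd.DataFrame:
    """Annotate candidates with function class and glycan structure.

    Left join on ``gene``; candidates absent from the curated table are
    flagged "Unknown" with an empty structure.
    """
    for col in ("gene", "function"):
        if col not in pathway_table.columns:
            raise ValidationError(f"pathway table lacks column {col!r}")
    merged = candidates.merge(pathway_table, on="gene", how="left")
    merged["function"] = merged["function"].fillna("Unknown")
    if "glycan_structure" in merged.columns:
        merged["glycan_structure"] = merged["glycan_structure"].fillna("")
    else:
        merged["glycan_structure"] = ""
    return merged


# ---------------------------------------------------- shipped curated tables

def _read_data_tsv(name: str) -> pd.DataFrame:
    ref = resources.files("glycolink.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#",
                           dtype=str, keep_default_na=False)


def load_pathway_annotation() -> pd.DataFrame:
    """Curated enzyme -> (function, glycan structure) table."""
    table = _read_data_tsv("glycan_pathway_annotation.tsv")
    if "glycan_structure" not in table.columns:
        table["glycan_structure"] = ""
    return table


def load_reported_glycogene_signatures() -> tuple[set[str], set[str]]:
    """Published (network-side, glycan-side) glycan-enzyme gene sets.

    The network side holds the glycan-transfer genes found in the screened
    network signature; the glycan side holds the enzymes backing the
    lectin-derived glycan signature. These printed lists are the worked
    example for the integration step.
    """
    table = _read_data_tsv("reported_glycogene_signatures.tsv")
    network = set(table.loc[table["side"] == "network", "gene"])
    glycan = set(table.loc[table["side"] == "glycan", "gene"])
    return network, glycan
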