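"""Multi-source miRNA→target consensus voting and network export.

Target assertions come from several independent databases (typically
eleven: three experimentally validated, eight prediction-based), supplied
as plain TSV tables so the analysis is reproducible offline against a
pinned snapshot.  An interaction is kept when it is asserted by at least
``min_votes`` distinct sources (every source counts equally; an optional
override keeps any experimentally validated interaction regardless of
vote count).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .io import read_target_table

DEFAULT_MIN_VOTES = 4


@dataclass(frozen=True)
class ConsensusEdge:
    """A miRNA→gene interaction with its supporting sources."""

    mirna: str
    gene: str
    votes: int
    sources: frozenset[str]
    any_validated: bool

    def __post_init__(self) -> None:
        if self.votes != len(self.sources):
            raise ValueError("votes must equal the number of supporting sources")


def load_sources(tables: Sequence[str | Path | pd.DataFrame]) -> pd.DataFrame:
    """Load and de-duplicate target-assertion tables.

    miRNA identifiers keep their case (miR-x naming is case-sensitive by
    convention) but are stripped; gene symbols are upper-cased.  Duplicate
    (source, mirna, gene) rows collapse to one assertion.
    """
    frames = []
    for t in tables:
        df = t.copy() if isinstance(t, pd.DataFrame) else read_target_table(t)
        frames.append(df)
    if not frames:
        raise ValueError("no source tables supplied")
    out = pd.concat(frames, ignore_index=True)
    out["mirna"] = out["mirna"].str.strip()
    out["gene"] = out["gene"].str.strip().str.upper()
    out["source"] = out["source"].str.strip()
    out = out.drop_duplicates(subset=["source", "mirna", "gene"]).reset_index(drop=True)
    return out


def consensus_vote(
    assertions: pd.DataFrame,
    mirnas: Iterable[str],
    min_votes: int = DEFAULT_MIN_VOTES,
    validated_override: bool = False,
) -> list[ConsensusEdge]:
    """Keep miRNA→gene pairs asserted by at least ``min_votes`` sources.

    With ``validated_override`` any pair carrying a validated-evidence
    assertion is kept regardless of votes.
    """
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")
    query = set(mirnas)
    if not query:
        raise ValueError("query miRNA set is empty")
    sub = assertions[assertions["mirna"].isin(query)]
    edges = []
    grouped = sub.groupby(["mirna", "gene"], sort=True)
    for (mirna, gene), grp in grouped:
        sources = frozenset(grp["source"])
        validated = bool((grp["evidence"] == "validated").any())
        if len(sources) >= min_votes or (validated_override and validated):
            edges.append(ConsensusEdge(mirna, gene, len(sources), sources, validated))
    return edges


def union_targets(
    edges: Iterable[ConsensusEdge], mirnas: Iterable[str] | None = None
) -> pd.Series:
    """Union of target genes with per-gene cross-regulation degree.

    Returns a Series mapping each gene to the number of distinct query
    miRNAs that target it, sorted by decreasing degree then gene name.
    """
    query = set(mirnas) if mirnas is not None else None
    counts: dict[str, set[str]] = {}
    for e in edges:
        if query is not None and e.mirna not in query:
            continue
        counts.setdefault(e.gene, set()).add(e.mirna)
    ser = pd.Series({g: len(ms) for g, ms in counts.items()}, dtype=int, name="n_mirnas")
    return ser.sort_index().sort_values(ascending=False, kind="stable")


def edges_frame(edges: Iterable[ConsensusEdge]) -> pd.DataFrame:
    rows = [
        {
            "mirna": e.mirna,
            "gene": e.gene,
            "votes": e.votes,
            "any_validated": e.any_validated,
            "sources": ",".join(sorted(e.sources)),
        }
        for e in edges
    ]
    return pd.DataFrame(rows, columns=["mirna", "gene", "votes", "any_validated", "sources"])


def export_network(edges: Iterable[ConsensusEdge], path: str | Path) -> pd.DataFrame:
    """Write a bipartite edge list plus node-type table for network tools.

    ``<path>`` gets the edge list (mirna, gene, votes, any_validated);
    ``<path stem>_nodes.tsv`` gets node ids with a type column
    distinguishing miRNA from gene nodes.
    """
    path = Path(path)
    df = edges_frame(edges)[["mirna", "gene", "votes", "any_validated"]]
    df.to_csv(path, sep="\t", index=False)
    mirna_nodes = sorted(df["mirna"].unique())
    gene_nodes = sorted(df["gene"].unique())
    nodes = pd.DataFrame(
        {
            "node": mirna_nodes + gene_nodes,
            "type": ["mirna"] * len(mirna_nodes) + ["gene"] * len(gene_nodes),
        }
    )
    nodes.to_csv(path.with_name(path.stem + "_nodes.tsv"), sep="\t", index=False)
    return df


def import_network(path: str | Path) -> list[ConsensusEdge]:
    """Parse an exported edge list back into consensus edges (sources are
    not stored in the export; each edge gets a placeholder source set of
    matching size)."""
    df = pd.read_csv(path, sep="\t")
    return [
        ConsensusEdge(
            r.mirna,
            r.gene,
            int(r.votes),
            frozenset(f"source_{i}" for i in range(int(r.votes))),
            bool(r.any_validated),
        )
        for r in df.itertuples()
    ]
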