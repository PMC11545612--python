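"""Pathway over-representation with phenotype-module rollup.

A query gene set (e.g. the consensus targets of a miRNA cluster) is tested
for overlap with each pathway of a GMT collection using the upper-tail
hypergeometric probability; Benjamini-Hochberg adjustment is reported per
analysis.  Enriched pathways roll up into phenotype modules (cell
motility, cell survival, or both) via a packaged pathway→module map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

#: rollup of the ten enriched oncogenic pathways into phenotype modules
DEFAULT_MODULE_MAP: dict[str, str] = {
    "Adherens junction": "motility",
    "Focal adhesion": "motility",
    "EGFR tyrosine kinase inhibitor resistance": "survival",
    "p53 signaling pathway": "survival",
    "Cellular senescence": "survival",
    "Cell cycle": "survival",
    "PI3K-Akt signaling pathway": "both",
    "Rap1 signaling pathway": "both",
    "MAPK signaling pathway": "both",
    "Ras signaling pathway": "both",
}

MODULES = ("motility", "survival", "both", "unassigned")


@dataclass(frozen=True)
class EnrichmentRecord:
    """One pathway's over-representation result."""

    pathway: str
    overlap_genes: frozenset[str]
    k: int  # overlap size
    K: int  # pathway size in universe
    n: int  # query size in universe
    N: int  # universe size
    p_value: float
    fdr: float
    module: str = "unassigned"


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts query genes falling in a pathway of size ``K`` when ``n``
    genes are drawn without replacement from a universe of ``N``.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """Conservative over-representation variant: the overlap is decremented
    by one before taking the hypergeometric tail, penalising single-gene
    overlaps.  Always at least the plain p-value."""
    if k == 0:
        return 1.0
    return hypergeom_overrep(k - 1, K, n, N)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def assign_module(pathway: str, module_map: Mapping[str, str] | None = None) -> str:
    module_map = DEFAULT_MODULE_MAP if module_map is None else module_map
    return module_map.get(pathway, "unassigned")


def run_ora(
    query_genes: Iterable[str],
    gmt: Mapping[str, Sequence[str]],
    universe: Iterable[str] | None = None,
    top_m: int | None = None,
    statistic: str = "hypergeometric",
    module_map: Mapping[str, str] | None = None,
) -> list[EnrichmentRecord]:
    """Over-representation analysis of a query set against a GMT collection.

    The universe defaults to the union of all GMT genes (background choice
    is analysis-dependent; override when a platform universe is known).
    Query genes outside the universe are dropped.  Pathways with zero
    overlap are omitted.  Records are ranked by p-value (ties broken by
    larger overlap then name) and truncated to ``top_m`` when given.
    """
    if statistic not in ("hypergeometric", "ease"):
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = hypergeom_overrep if statistic == "hypergeometric" else ease_score
    gmt_sets = {name: set(genes) for name, genes in gmt.items()}
    if universe is None:
        universe_set = set().union(*gmt_sets.values()) if gmt_sets else set()
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ValueError("gene universe is empty")
    query = set(query_genes) & universe_set
    N, n = len(universe_set), len(query)

    hits = []
    for name, genes in gmt_sets.items():
        members = genes & universe_set
        overlap = members & query
        if not overlap:
            continue
        k, K = len(overlap), len(members)
        hits.append((name, overlap, k, K, stat(k, K, n, N)))
    if not hits:
        return []
    fdrs = bh_adjust([h[4] for h in hits])
    records = [
        EnrichmentRecord(
            name, frozenset(overlap), k, K, n, N, p, float(fdr),
            assign_module(name, module_map),
        )
        for (name, overlap, k, K, p), fdr in zip(hits, fdrs)
    ]
    records.sort(key=lambda r: (r.p_value, -r.k, r.pathway))
    return records[:top_m] if top_m is not None else records


def module_rollup(
    records: Iterable[EnrichmentRecord] | Iterable[str],
    module_map: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Count enriched pathways per phenotype module."""
    counts = dict.fromkeys(MODULES, 0)
    for rec in records:
        name = rec if isinstance(rec, str) else rec.pathway
        counts[assign_module(name, module_map)] += 1
    return counts


def records_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "pathway": r.pathway,
            "k": r.k,
            "K": r.K,
            "n": r.n,
            "N": r.N,
            "p": r.p_value,
            "fdr": r.fdr,
            "module": r.module,
            "overlap_genes": ",".join(sorted(r.overlap_genes)),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["pathway", "k", "K", "n", "N", "p", "fdr", "module", "overlap_genes"]
    )
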