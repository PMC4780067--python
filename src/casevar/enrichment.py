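"""Gene-set overlap statistics with FDR control.

Given a query gene list (e.g. upregulated genes), a collection of gene
sets (GMT format), and a gene universe, each set is scored with the exact
hypergeometric upper-tail probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the set size within the universe, n the
query size and k the observed overlap.  P-values across sets are adjusted
with the Benjamini-Hochberg step-up procedure.  Up- and down-regulated
lists are intended to be tested separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OverlapResult",
    "overlap_test",
    "adjust_fdr",
    "enrich",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of one query list with one gene set."""

    set_name: str
    universe_size: int  # N
    set_size: int       # K (within the universe)
    query_size: int     # n (within the universe)
    overlap: int        # k
    p_value: float
    q_value: float | None = None


def _normalize(genes: Iterable[str]) -> Set[str]:
    return {g.strip().upper() for g in genes if g and g.strip()}


def overlap_test(
    query_genes: Iterable[str],
    gene_set: Iterable[str],
    universe: Iterable[str],
    set_name: str = "",
) -> OverlapResult:
    """Exact hypergeometric upper-tail test of query/set overlap.

    Symbols are upper-cased and deduplicated; query or set genes outside
    the universe are dropped with a warning.  An empty universe is an
    error.
    """
    uni = _normalize(universe)
    if not uni:
        raise ValueError("gene universe is empty")
    query = _normalize(query_genes)
    gset = _normalize(gene_set)
    outside = query - uni
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe dropped (e.g. %s)",
            len(outside),
            sorted(outside)[0],
        )
    query &= uni
    gset &= uni
    N, K, n = len(uni), len(gset), len(query)
    k = len(query & gset)
    # P(X >= k); survival function is P(X > k-1)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 0.0), 1.0)
    return OverlapResult(
        set_name=set_name,
        universe_size=N,
        set_size=K,
        query_size=n,
        overlap=k,
        p_value=p,
    )


def adjust_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted q-values (monotone in ranked p)."""
    if len(p_values) == 0:
        return []
    _, q, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(v) for v in q]


def enrich(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Test a query list against every gene set; rows sorted by p-value.

    Returns a DataFrame with columns set_name, universe_size, set_size,
    query_size, overlap, p_value, q_value.
    """
    results = [
        overlap_test(query_genes, members, universe, set_name=name)
        for name, members in gene_sets.items()
    ]
    qs = adjust_fdr([r.p_value for r in results])
    rows = [
        {
            "set_name": r.set_name,
            "universe_size": r.universe_size,
            "set_size": r.set_size,
            "query_size": r.query_size,
            "overlap": r.overlap,
            "p_value": r.p_value,
            "q_value": q,
        }
        for r, q in zip(results, qs)
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "universe_size",
            "set_size",
            "query_size",
            "overlap",
            "p_value",
            "q_value",
        ],
    )
    return df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(
        drop=True
    )


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Parse a GMT file: one set per line, tab-separated
    name<TAB>description<TAB>gene1<TAB>gene2..."""
    sets: Dict[str, List[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *members]) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path: str | Path) -> List[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        s = line.strip()
        if s and not s.startswith("#"):
            out.append(s)
    return out
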