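"""Fold enrichment and one-sided hypergeometric tests for gene-set terms.

For a query of n genes from a background of N, a term with K background
members and k query hits scores fold enrichment (k/n)/(K/N) and a
one-sided (over-representation) hypergeometric tail p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from scipy import stats

from coexscreen.cohort_io import GeneSetCollection
from coexscreen.stratified_stats import bh_adjust

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Raised for invalid enrichment input."""


@dataclass
class EnrichmentRow:
    """One term's enrichment of the query against the background."""

    term_id: str
    description: str
    k: int  # query genes in term
    n: int  # query genes in background
    K: int  # term genes in background
    N: int  # background size
    fold_enrichment: float
    p: float
    q: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.n, self.K):
            raise EnrichmentError(
                f"term {self.term_id!r}: k={self.k} outside [0, min(n, K)]"
            )
        if self.fold_enrichment < 0 or not 0 < self.p <= 1:
            raise EnrichmentError(f"term {self.term_id!r}: invalid statistics")


def fold_enrichment(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    bh: bool = False,
) -> list[EnrichmentRow]:
    """Score every term of ``collection`` against ``query``.

    Query genes outside the background are dropped with a logged count.
    Terms with no background member are skipped.  p is the upper
    hypergeometric tail P(X >= k); k = 0 gives fold enrichment 0 and
    p = 1.  With ``bh=True`` the q field holds BH-adjusted p across the
    scored terms.

    Raises
    ------
    EnrichmentError
        If the background has fewer than 2 genes or the query is empty
        after restriction to the background.
    """
    background_set = frozenset(background)
    if len(background_set) < 2:
        raise EnrichmentError("background must contain at least 2 genes")
    query_set = frozenset(query)
    dropped = query_set - background_set
    if dropped:
        logger.info("dropping %d query gene(s) outside the background", len(dropped))
    query_set = query_set & background_set
    if not query_set:
        raise EnrichmentError("query is empty after restriction to the background")

    N = len(background_set)
    n = len(query_set)
    rows: list[EnrichmentRow] = []
    for term_id, (desc, members) in collection:
        term_bg = members & background_set
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & query_set)
        fe = (k / n) / (K / N)
        if k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, 5e-324), 1.0)  # tail including k is never exactly 0
        rows.append(EnrichmentRow(term_id, desc, k, n, K, N, fe, p))

    if bh and rows:
        qvals = bh_adjust([row.p for row in rows])
        for row, q in zip(rows, qvals):
            row.q = q
    return rows


def write_enrichment_tsv(rows: list[EnrichmentRow], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        handle.write(
            "term_id\tdescription\tk\tn\tK\tN\tfold_enrichment\tp\tq\n"
        )
        for row in sorted(rows, key=lambda r: (r.p, r.term_id)):
            q = "NA" if row.q is None else f"{row.q:.10g}"
            handle.write(
                f"{row.term_id}\t{row.description}\t{row.k}\t{row.n}\t{row.K}\t"
                f"{row.N}\t{row.fold_enrichment:.10g}\t{row.p:.10g}\t{q}\n"
            )
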