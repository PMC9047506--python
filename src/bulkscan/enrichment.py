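"""One-sided hypergeometric over-representation analysis on flat term maps.

Stands in for ontology-based enrichment: term -> gene-set maps are taken
as given (no DAG propagation, no length-bias weighting), and each term is
scored with the upper-tail hypergeometric probability of observing at
least k list members out of a term of size K, a list of size n and a
universe of size N, followed by BH adjustment across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .de_analysis import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class TermMap:
    """Flat term -> member-gene-set annotation over a gene universe."""

    terms: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: g & self.universe for t, g in self.terms.items() if g}
        self.terms = {t: g for t, g in self.terms.items() if g}
        if not self.universe:
            raise ValueError("empty gene universe")

    @classmethod
    def from_tsv(
        cls,
        term_gene_path: str,
        universe: set[str] | None = None,
        description_path: str | None = None,
    ) -> "TermMap":
        """Two-column (term, gene) TSV; optional (term, description) TSV."""
        table = pd.read_csv(
            term_gene_path, sep="\t", header=None, names=["term", "gene"], comment="#"
        )
        terms: dict[str, set[str]] = {}
        for term, genes in table.groupby("term")["gene"]:
            terms[str(term)] = set(map(str, genes))
        if universe is None:
            universe = set().union(*terms.values())
        descriptions = {}
        if description_path:
            desc = pd.read_csv(
                description_path, sep="\t", header=None, names=["term", "description"]
            )
            descriptions = dict(zip(desc["term"].astype(str), desc["description"]))
        return cls(terms, universe, descriptions)


def hypergeometric_enrichment(
    gene_list: set[str] | list[str],
    term_map: TermMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Score every term; returns a p-sorted table with BH-adjusted p.

    p = P(X >= k) for X ~ Hypergeom(N=len(universe), K=len(term),
    n=len(list)). Genes outside the universe are dropped with a logged
    count. The ``significant`` column thresholds the raw p at ``alpha``,
    matching an enrichment cutoff of p < 0.05.
    """
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    outside = genes - term_map.universe
    if outside:
        logger.warning(
            "%d query genes outside the universe dropped, e.g. %s",
            len(outside),
            sorted(outside)[:3],
        )
        genes -= outside
    if not genes:
        raise ValueError("no query genes remain inside the universe")
    big_n = len(term_map.universe)
    n = len(genes)
    rows = []
    for term, members in term_map.terms.items():
        big_k = len(members)
        k = len(genes & members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            {
                "term": term,
                "description": term_map.descriptions.get(term, ""),
                "k": k,
                "K": big_k,
                "n": n,
                "N": big_n,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p"])
    table["significant"] = table["p"] < alpha
    return table.sort_values(["p", "term"], ignore_index=True)


def write_enrichment_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)
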