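"""Dual-evidence protein-interaction join.

An interaction involving an AS-disrupted domain is reported only when it
has BOTH experimental support (an edge in the merged experimentally
validated PPI network) and structural support (the disrupted domain and a
domain of the partner form a known domain–domain interaction pair).
Gene-symbol joins are case-insensitive; edges are undirected and stored in
canonical order; self-loops (homodimers) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd


@dataclass(frozen=True)
class PPIEdge:
    gene_a: str
    gene_b: str
    source_count: int


@dataclass(frozen=True)
class EvidencedInteraction:
    as_gene: str
    as_domain: str
    partner_gene: str
    partner_domain: str
    has_experimental: bool = True
    has_structural: bool = True


def _key(g: str) -> str:
    return g.strip().casefold()


def _canon(a: str, b: str) -> tuple[str, str]:
    return (a, b) if _key(a) <= _key(b) else (b, a)


def merge_ppi(edge_lists: Iterable[pd.DataFrame]) -> dict[tuple[str, str], PPIEdge]:
    """Union experimental edge lists with canonical ordering.

    Duplicate edges (including reversed orientation) collapse into one,
    accumulating ``source_count``. Malformed rows (missing gene) are
    skipped and counted in the returned edges' log attribute-free way:
    callers needing the skip count can compare row totals.
    """
    edges: dict[tuple[str, str], int] = {}
    names: dict[tuple[str, str], tuple[str, str]] = {}
    for df in edge_lists:
        for row in df.itertuples(index=False):
            a, b = str(row.gene_a).strip(), str(row.gene_b).strip()
            if not a or not b or a.lower() == "nan" or b.lower() == "nan":
                continue
            ca, cb = _canon(a, b)
            k = (_key(ca), _key(cb))
            edges[k] = edges.get(k, 0) + 1
            names.setdefault(k, (ca, cb))
    return {k: PPIEdge(names[k][0], names[k][1], n) for k, n in edges.items()}


def structural_partners(
    as_domain: str,
    ddi: pd.DataFrame,
    gene_domains: pd.DataFrame,
) -> dict[str, set[str]]:
    """Genes carrying any domain that pairs with *as_domain* in the DDI table.

    Returns partner gene → set of its pairing domains. A self-pair
    (as_domain, as_domain) makes every gene carrying the domain — including
    the AS gene itself — its own candidate partner (homodimerization).
    """
    partners_domains: set[str] = set()
    for row in ddi.itertuples(index=False):
        da, db = str(row.dom_a), str(row.dom_b)
        if da == as_domain:
            partners_domains.add(db)
        if db == as_domain:
            partners_domains.add(da)
    out: dict[str, set[str]] = {}
    for row in gene_domains.itertuples(index=False):
        if str(row.accession) in partners_domains:
            out.setdefault(str(row.gene), set()).add(str(row.accession))
    return out


def dual_evidence_join(
    as_gene_domains: Iterable[tuple[str, str]],
    ddi: pd.DataFrame,
    gene_domains: pd.DataFrame,
    merged_ppi: Mapping[tuple[str, str], PPIEdge],
    expressed_genes: set[str] | None = None,
) -> list[EvidencedInteraction]:
    """The two-criteria join: structural candidates ∩ experimental edges.

    *as_gene_domains* lists (gene, disrupted domain accession) pairs. When
    *expressed_genes* is given, partners absent from it are dropped
    (case-insensitive membership).
    """
    expressed_keys = {_key(g) for g in expressed_genes} if expressed_genes is not None else None
    out: list[EvidencedInteraction] = []
    seen = set()
    for as_gene, as_dom in as_gene_domains:
        candidates = structural_partners(as_dom, ddi, gene_domains)
        for partner, pdoms in sorted(candidates.items()):
            if expressed_keys is not None and _key(partner) not in expressed_keys:
                continue
            k = tuple(sorted((_key(as_gene), _key(partner))))
            if k not in merged_ppi:
                continue
            sig = (_key(as_gene), as_dom, _key(partner))
            if sig in seen:
                continue
            seen.add(sig)
            out.append(
                EvidencedInteraction(as_gene, as_dom, partner, ",".join(sorted(pdoms)))
            )
    return out


def to_dot(interactions: Iterable[EvidencedInteraction]) -> str:
    """Bipartite graph text export (AS genes boxed, partners oval)."""
    lines = ["graph dual_evidence {"]
    as_genes = sorted({i.as_gene for i in interactions})
    for g in as_genes:
        lines.append(f'  "{g}" [shape=box];')
    for i in sorted(interactions, key=lambda x: (x.as_gene, x.partner_gene)):
        lines.append(f'  "{i.as_gene}" -- "{i.partner_gene}" [label="{i.as_domain}"];')
    lines.append("}")
    return "\n".join(lines)
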