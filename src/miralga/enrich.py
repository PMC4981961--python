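"""Hypergeometric GO/KEGG enrichment of target genes.

Each term is tested with the upper-tail hypergeometric probability
P(X >= k) of drawing k annotated genes in a selection of size n from a
background of N genes of which K carry the term.  Benjamini-Hochberg
controls the FDR across all tested terms; the q-value reported is the
BH FDR (no separate estimator).  GO significance uses corrected p <
0.05; KEGG uses p < 0.05 and q < 0.05.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .targets import TargetSite

__all__ = ["EnrichmentResult", "hypergeom_enrich", "top_terms_by_category",
           "export_network"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # selected genes with the term
    K: int  # background genes with the term
    n: int  # selection size
    N: int  # background size
    p: float
    p_adj: float = 1.0
    q: float = 1.0
    significant_go: bool = False
    significant_kegg: bool = False


def hypergeom_enrich(
    selected: set[str] | list[str],
    term_map: list[tuple[str, str, str]],
    background: set[str] | list[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every term of `term_map` for enrichment in `selected`.

    term_map rows are (term_id, gene_id, term_name); rows whose gene is
    outside the background are ignored.  Results come back sorted by p
    (ties by term id).
    """
    selected = set(selected)
    background = set(background)
    stray = selected - background
    if stray:
        raise ValueError(f"selected genes outside background: {sorted(stray)[:5]}")
    genes_of: dict[str, set[str]] = defaultdict(set)
    names: dict[str, str] = {}
    for term, gene, name in term_map:
        if gene in background:
            genes_of[term].add(gene)
            names[term] = name
    if not genes_of:
        raise ValueError("term map is empty over the background")
    N, n = len(background), len(selected)
    results = []
    for term in sorted(genes_of):
        K = len(genes_of[term])
        k = len(genes_of[term] & selected)
        # upper tail including k: survival function at k-1
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append(EnrichmentResult(term, names[term], k, K, n, N, min(p, 1.0)))
    pvals = [r.p for r in results]
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, pa in zip(results, p_adj):
        r.p_adj = float(pa)
        r.q = float(pa)  # BH FDR doubles as the q-value
        r.significant_go = r.p_adj < alpha
        r.significant_kegg = r.p < alpha and r.q < alpha
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def top_terms_by_category(
    results: list[EnrichmentResult],
    category_map: dict[str, str],
    top_n: int = 10,
) -> dict[str, list[EnrichmentResult]]:
    """Up to `top_n` most-enriched terms per GO category (BP/CC/MF)."""
    out: dict[str, list[EnrichmentResult]] = defaultdict(list)
    for r in sorted(results, key=lambda r: (r.p, r.term_id)):
        cat = category_map.get(r.term_id)
        if cat and len(out[cat]) < top_n:
            out[cat].append(r)
    return dict(out)


def export_network(union: list[TargetSite]) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """SIF-style edge list and per-miRNA degree table.

    Edges are unique (miRNA, "targets", gene) triples from a
    deduplicated target-site union; degrees support "most connected
    node" queries.
    """
    pairs = sorted({(s.mirna_id, s.transcript_id) for s in union})
    edges = [(m, "targets", g) for m, g in pairs]
    deg: dict[str, int] = defaultdict(int)
    for m, _g in pairs:
        deg[m] += 1
    return edges, dict(deg)
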