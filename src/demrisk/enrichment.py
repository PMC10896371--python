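"""Hypergeometric gene-set enrichment with Benjamini-Hochberg correction.

For a mapped gene list of size n drawn from a background of N genes, and a
gene set with K background members, the enrichment p-value is the one-sided
upper tail P[X >= k] of the hypergeometric distribution at the observed
overlap k.  Gene sets are intersected with the background before testing.
Reported results keep adjusted p <= 0.05 (inclusive) and more than one
overlapping gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    gene_set: str
    overlap_genes: list[str]
    k: int      # overlap
    K: int      # set size within background
    n: int      # mapped-list size
    N: int      # background size
    p: float
    adj_p: float | None = None


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> gene1 <tab> ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def hypergeom_enrich(mapped_genes, gene_sets: dict[str, list[str]],
                     background_genes) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test of each gene set against the mapped
    list; BH-adjusted p-values are filled in across all tested sets."""
    background = set(background_genes)
    if not background:
        raise ValueError("empty background gene universe")
    mapped = set(mapped_genes) & background
    if set(mapped_genes) - background:
        raise ValueError("mapped genes outside the background universe: "
                         f"{sorted(set(mapped_genes) - background)[:10]}")
    N, n = len(background), len(mapped)
    results = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & background
        overlap = sorted(members & mapped)
        k, K = len(overlap), len(members)
        # P[X >= k] for X ~ Hypergeom(N, K, n); k = 0 gives p = 1
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        results.append(EnrichmentResult(name, overlap, k, K, n, N,
                                        min(p, 1.0)))
    if results:
        adj = bh_adjust([r.p for r in results])
        for r, q in zip(results, adj):
            r.adj_p = q
    return results


def bh_adjust(pvalues) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    ps = list(pvalues)
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("p-values must lie in (0, 1]")
    if not ps:
        return []
    _, adj, _, _ = multipletests(ps, method="fdr_bh")
    return [float(q) for q in adj]


def filter_enriched(results: list[EnrichmentResult],
                    max_adj_p: float = 0.05,
                    min_overlap_exclusive: int = 1) -> list[EnrichmentResult]:
    """The reporting filter: adjusted p <= threshold (inclusive) and
    overlap strictly greater than ``min_overlap_exclusive``."""
    return [r for r in results
            if r.adj_p is not None and r.adj_p <= max_adj_p
            and r.k > min_overlap_exclusive]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_set, ";".join(r.overlap_genes), r.k, r.K, r.n, r.N,
          r.p, r.adj_p) for r in results],
        columns=["gene_set", "overlap_genes", "k", "K", "n", "N",
                 "p", "adj_p"])
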