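"""Term enrichment of gene sets by the hypergeometric upper tail.

Gene sets (module members, regulated genes, drought-specific genes) are
tested against a gene -> term annotation table: for each term with at least
one annotated gene in the universe, the p-value is the probability that a
uniform draw of the study-set size from the universe contains at least as
many term members as observed — the one-sided Fisher exact test.  P-values
are adjusted across tested terms with the Benjamini-Hochberg step-up rule.

An optional term DAG (child -> parent edges) can be closed first so that
every gene annotated to a term is also counted for all its ancestors
(true-path propagation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationTable:
    """gene -> set of terms, optional term names and parent DAG edges."""

    gene_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    parents: dict[str, set[str]] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


def read_annotation_tsv(path) -> AnnotationTable:
    """Two-column TSV (gene_id, term_id); extra columns ignored."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="!")
    cols = list(df.columns)
    if "gene_id" in cols and "term_id" in cols:
        pairs = df[["gene_id", "term_id"]]
    else:
        pairs = df.iloc[:, :2]
        pairs.columns = ["gene_id", "term_id"]
    gene_terms: dict[str, set[str]] = {}
    for g, t in zip(pairs["gene_id"], pairs["term_id"]):
        gene_terms.setdefault(g, set()).add(t)
    return AnnotationTable(gene_terms)


def read_gaf(path) -> AnnotationTable:
    """Thin GAF 2.x column extractor: DB object id (col 2) and GO id (col 5)."""
    gene_terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("!") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            gene_terms.setdefault(fields[1], set()).add(fields[4])
    return AnnotationTable(gene_terms)


def propagate_annotations(table: AnnotationTable) -> AnnotationTable:
    """True-path closure: annotate each gene to every ancestor of its direct
    terms.  Requires an acyclic parent graph; idempotent."""
    if not table.parents:
        return AnnotationTable(
            {g: set(ts) for g, ts in table.gene_terms.items()},
            dict(table.term_names), {},
        )
    dag = nx.DiGraph()
    for child, ps in table.parents.items():
        for p in ps:
            dag.add_edge(child, p)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        raise ValueError(f"term graph contains a cycle: {cycle}")
    ancestors = {t: nx.descendants(dag, t) for t in dag.nodes}
    closed = {}
    for g, ts in table.gene_terms.items():
        full = set(ts)
        for t in ts:
            full |= ancestors.get(t, set())
        closed[g] = full
    return AnnotationTable(closed, dict(table.term_names), dict(table.parents))


@dataclass
class EnrichmentResult:
    term_id: str
    k: int  # term hits in the study set
    n: int  # study-set size
    K: int  # term hits in the universe
    N: int  # universe size
    p: float
    fdr: float = np.nan


def fisher_enrichment(
    study: set[str], universe: set[str], table: AnnotationTable
) -> list[EnrichmentResult]:
    """One-sided Fisher (hypergeometric upper tail) per term.

    p = P(X >= k) with X ~ Hypergeom(N, K, n).  Terms with no annotated
    gene in the universe are skipped so the BH family contains only
    testable terms.  Results sorted by p, ties by term id.
    """
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    N = len(universe)
    n = len(study)
    term_members: dict[str, set[str]] = {}
    for g in universe:
        for t in table.gene_terms.get(g, ()):
            term_members.setdefault(t, set()).add(g)
    results = []
    for term in sorted(term_members):
        members = term_members[term]
        K = len(members)
        k = len(members & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        results.append(EnrichmentResult(term, k, n, K, N, p))
    pvals = np.array([r.p for r in results])
    if len(pvals):
        fdrs = bh_fdr(pvals)
        for r, q in zip(results, fdrs):
            r.fdr = float(q)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.k, r.n, r.K, r.N, r.p, r.fdr) for r in results],
        columns=["term_id", "k", "n", "K", "N", "p", "fdr"],
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
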