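"""Ontology-aware enrichment and cross-set summarization of enriched terms.

This module works on a single-rooted (per namespace) directed acyclic graph of
ontology terms connected by ``is_a`` edges — the structure of the Gene
Ontology — together with gene→term annotation maps.  It provides

* over-representation testing of a study gene set against a population with
  one-sided Fisher's exact tests and Benjamini–Hochberg FDR control, and
* the *common most-specific term* summarization: given several enriched-term
  sets (e.g. per starvation time point), find for each most-specific term the
  nearest ancestor (by shortest ``is_a`` distance, the term itself counting as
  distance 0) that is present in **all** sets, thereby separating processes
  that are commonly enriched from time-dependent ones.

Flat annotation schemes without a hierarchy (Pfam domains, KEGG pathways) are
handled by the same :func:`enrich` code path — simply skip propagation and
never consult the DAG.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd
from scipy import stats
from statsmodels.stats import multitest

__all__ = [
    "GoDag",
    "AnnotationMap",
    "CommonSpecificResult",
    "parse_obo",
    "write_obo",
    "most_specific",
    "common_most_specific",
    "propagate_annotations",
    "enrich",
    "bh_adjust",
    "read_annotations",
    "write_annotations",
]


class GoDag:
    """Acyclic ``is_a`` hierarchy of ontology terms.

    Parameters
    ----------
    terms
        Mapping term id → human-readable name.
    parents
        Mapping term id → set of direct ``is_a`` parents.  Every parent must
        itself be a term; the induced directed graph (child → parent) must be
        acyclic and have at least one root (a term without parents).
    """

    def __init__(self, terms: Mapping[str, str], parents: Mapping[str, Iterable[str]]):
        self.terms: dict[str, str] = dict(terms)
        self.parents: dict[str, frozenset[str]] = {
            t: frozenset(parents.get(t, ())) for t in self.terms
        }
        for term, ps in self.parents.items():
            missing = ps - self.terms.keys()
            if missing:
                raise ValueError(
                    f"term {term!r} has is_a parent(s) not defined in the "
                    f"ontology: {sorted(missing)}"
                )
        graph = nx.DiGraph()
        graph.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            graph.add_edges_from((child, p) for p in ps)
        if not nx.is_directed_acyclic_graph(graph):
            edge = nx.find_cycle(graph)[0]
            raise ValueError(f"is_a cycle detected (e.g. {edge[0]} -> {edge[1]})")
        self._graph = graph
        self.roots: frozenset[str] = frozenset(
            t for t, ps in self.parents.items() if not ps
        )
        if not self.roots:
            raise ValueError("ontology has no root term")

    # -- basic container protocol -------------------------------------------------
    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GoDag({len(self)} terms, {len(self.roots)} root(s))"

    def _require(self, term: str) -> None:
        if term not in self.terms:
            raise KeyError(f"unknown term id: {term!r}")

    # -- graph queries ------------------------------------------------------------
    def ancestors(self, term: str) -> set[str]:
        """All proper ancestors of *term* under the ``is_a`` closure."""
        self._require(term)
        return set(nx.descendants(self._graph, term))

    def distance(self, child: str, ancestor: str) -> int:
        """Length of the shortest directed ``is_a`` path from child to ancestor.

        ``distance(t, t)`` is 0.  Raises ``ValueError`` if *ancestor* is not
        reachable from *child*.
        """
        self._require(child)
        self._require(ancestor)
        try:
            return nx.shortest_path_length(self._graph, child, ancestor)
        except nx.NetworkXNoPath:
            raise ValueError(f"{ancestor!r} is not an ancestor of {child!r}")

    def ancestors_by_distance(self, term: str) -> dict[int, set[str]]:
        """Group ``{term} ∪ ancestors(term)`` by shortest-path distance."""
        self._require(term)
        by_dist: dict[int, set[str]] = collections.defaultdict(set)
        for node, d in nx.shortest_path_length(self._graph, source=term).items():
            by_dist[d].add(node)
        return dict(by_dist)


@dataclass
class AnnotationMap:
    """Gene → set-of-term-ids map.

    ``propagated`` records whether the map is closed under ancestors (the
    true-path rule).  Flat Pfam/KEGG-style annotations stay unpropagated and
    never reference a DAG.
    """

    gene_to_terms: dict[str, set[str]]
    propagated: bool = False

    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_to_terms.values():
            out |= ts
        return out


@dataclass
class CommonSpecificResult:
    """Outcome of the common most-specific summarization.

    ``provenance`` maps each common term to the list of ``(child, distance)``
    pairs that selected it — the most-specific input terms from which the
    common term was reached and the shortest ``is_a`` distance walked.
    """

    common: set[str]
    non_common: set[str]
    provenance: dict[str, list[tuple[str, int]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# OBO I/O
# ---------------------------------------------------------------------------

def parse_obo(source: str | Path | IO[str]) -> GoDag:
    """Read an OBO file (``id``, ``name``, ``is_a``; other tags ignored).

    Obsolete stanzas are dropped; relationship types other than ``is_a`` are
    ignored; acyclicity and dangling ``is_a`` targets are validated.
    """
    graph = obonet.read_obo(source, ignore_obsolete=True)
    terms: dict[str, str] = {}
    parents: dict[str, set[str]] = {}
    for node, data in graph.nodes(data=True):
        if "name" not in data:
            # node created only because something points at it via is_a
            raise ValueError(f"dangling is_a target: {node!r} has no [Term] stanza")
        terms[node] = data["name"]
        parents[node] = set()
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            parents[child].add(parent)
    return GoDag(terms, parents)


def write_obo(dag: GoDag, path: str | Path, header: bool = True) -> None:
    """Write a minimal OBO subset ([Term] stanzas with id, name, is_a)."""
    with open(path, "w") as fh:
        if header:
            fh.write("format-version: 1.2\nontology: synthetic\n\n")
        for term in sorted(dag.terms):
            fh.write(f"[Term]\nid: {term}\nname: {dag.terms[term]}\n")
            for parent in sorted(dag.parents[term]):
                fh.write(f"is_a: {parent} ! {dag.terms[parent]}\n")
            fh.write("\n")


def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a two-column gene<TAB>term TSV into an (unpropagated) map."""
    gene_to_terms: dict[str, set[str]] = collections.defaultdict(set)
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            gene_to_terms[gene].add(term)
    return AnnotationMap(dict(gene_to_terms), propagated=False)


def write_annotations(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(ann.gene_to_terms):
            for term in sorted(ann.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# DAG set operations
# ---------------------------------------------------------------------------

def most_specific(dag: GoDag, terms: Iterable[str]) -> set[str]:
    """Drop every term that is a proper ancestor of another term in the set."""
    terms = set(terms)
    for t in terms:
        dag._require(t)
    redundant: set[str] = set()
    for t in terms:
        redundant |= dag.ancestors(t) & terms
    return terms - redundant


def common_most_specific(
    dag: GoDag,
    input_sets: Sequence[Iterable[str]],
    include_self: bool = True,
) -> CommonSpecificResult:
    """Summarize several enriched-term sets into common / non-common terms.

    The procedure: (1) union all input sets; (2) reduce the union to its
    most-specific terms; (3) for each remaining term, scan candidate terms in
    order of increasing shortest ``is_a`` distance — starting at the term
    itself (distance 0) when ``include_self`` is true, otherwise at its direct
    parents; (4) at the first distance where at least one candidate occurs in
    *every* input set, mark all equally distant qualifying candidates as
    common and stop scanning for that term; (5) if no candidate at any
    distance occurs in all sets, the term is non-common; (6) finally remove
    from the common set every term that is a proper ancestor of another
    common term.
    """
    if len(input_sets) == 0:
        raise ValueError("need at least one input term set")
    sets = [set(s) for s in input_sets]
    union: set[str] = set().union(*sets)
    for t in union:
        dag._require(t)

    specific = most_specific(dag, union)
    common: set[str] = set()
    non_common: set[str] = set()
    hits_per_child: dict[str, tuple[list[str], int]] = {}
    for child in sorted(specific):
        by_dist = dag.ancestors_by_distance(child)
        start = 0 if include_self else 1
        found = False
        for d in sorted(by_dist):
            if d < start:
                continue
            hits = sorted(t for t in by_dist[d] if all(t in s for s in sets))
            if hits:
                common.update(hits)
                hits_per_child[child] = (hits, d)
                found = True
                break
        if not found:
            non_common.add(child)

    final_common = most_specific(dag, common)
    provenance: dict[str, list[tuple[str, int]]] = {t: [] for t in final_common}
    for child, (hits, d) in hits_per_child.items():
        for t in hits:
            if t in final_common:
                provenance[t].append((child, d))
    return CommonSpecificResult(final_common, non_common, provenance)


def propagate_annotations(dag: GoDag, annotations: AnnotationMap) -> AnnotationMap:
    """Close every gene's term set under ancestors (true-path rule)."""
    unknown = annotations.terms() - dag.terms.keys()
    if unknown:
        raise KeyError(f"annotation terms not in ontology: {sorted(unknown)}")
    closure_cache: dict[str, frozenset[str]] = {}

    def closure(term: str) -> frozenset[str]:
        if term not in closure_cache:
            closure_cache[term] = frozenset({term} | dag.ancestors(term))
        return closure_cache[term]

    propagated = {
        gene: set().union(*(closure(t) for t in ts)) if ts else set()
        for gene, ts in annotations.gene_to_terms.items()
    }
    return AnnotationMap(propagated, propagated=True)


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, p_(j) * m / j), returned in input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multitest.multipletests(p, method="fdr_bh")[1]


def enrich(
    study: Iterable[str],
    population: Iterable[str],
    annotations: AnnotationMap,
    q_crit: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher over-representation tests for every annotated term.

    For each term annotating K >= 1 population genes, the p-value is the
    hypergeometric upper tail P(X >= k) of the 2x2 table
    [[k, n-k], [K-k, N-n-K+k]] with study size n and population size N.
    Benjamini–Hochberg adjustment runs across all tested terms; ``enriched``
    flags q <= q_crit.  Population genes absent from the annotation map count
    with empty term sets.  Returns a DataFrame with columns
    term, k, n, K, N, p, q, enriched, sorted by p.
    """
    study = set(study)
    population = set(population)
    if not study <= population:
        extra = sorted(study - population)[:5]
        raise ValueError(f"study set is not a subset of the population (e.g. {extra})")
    n = len(study)
    N = len(population)

    term_pop: dict[str, int] = collections.Counter()
    term_study: dict[str, int] = collections.Counter()
    for gene in population:
        for term in annotations.gene_to_terms.get(gene, ()):
            term_pop[term] += 1
            if gene in study:
                term_study[term] += 1

    rows = []
    for term, K in sorted(term_pop.items()):
        k = term_study.get(term, 0)
        # upper tail of Hypergeometric(N, K, n) at k
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    result = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
    else:
        result["q"] = pd.Series(dtype=float)
    result["enriched"] = result["q"] <= q_crit
    return result.sort_values(["p", "term"], ignore_index=True)
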