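"""Graph-based ontology semantics.

Semantic similarity between ontology terms is computed from the ontology
graph alone (a Wang-style aggregate of edge-weight products over the terms'
common ancestors), so it is independent of annotation-corpus frequencies.
On top of the pairwise similarity the module provides the two one-sided
semantic *specificity* statistics between a translatome term list and a
transcriptome term list, cross-dataset reference distributions for those
statistics, and GOslim roll-up specificity degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: default semantic contribution of an edge, by relation type
DEFAULT_EDGE_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

SUPPORTED_RELATIONS = frozenset(DEFAULT_EDGE_WEIGHTS)


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or term lookups."""


@dataclass
class OntologyGraph:
    """A rooted DAG of ontology terms with typed child->parent edges.

    Parameters
    ----------
    graph
        ``networkx.MultiDiGraph`` whose edges run child -> parent and whose
        edge keys are relation types (``is_a`` or ``part_of``).
    weights
        Semantic contribution per relation type, each in (0, 1).
    """

    graph: nx.MultiDiGraph
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EDGE_WEIGHTS))

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise OntologyError(f"ontology graph contains a cycle: {cycle}")
        for rel, w in self.weights.items():
            if not 0.0 < w < 1.0:
                raise OntologyError(f"edge weight for {rel!r} must be in (0,1), got {w}")

    # -- basic accessors -------------------------------------------------
    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def name(self, term: str) -> str:
        return self.graph.nodes[term].get("name", term)

    def namespace(self, term: str) -> str | None:
        return self.graph.nodes[term].get("namespace")

    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def edge_set(self) -> set[tuple[str, str, str]]:
        """All (child, parent, relation) triples."""
        return {(u, v, k) for u, v, k in self.graph.edges(keys=True)}

    # -- semantic values -------------------------------------------------
    def svalues(self, term: str) -> dict[str, float]:
        """Semantic value of every ancestor of ``term`` (term itself = 1).

        The S-value of an ancestor ``t`` is the maximum, over all upward
        paths from ``term`` to ``t``, of the product of the traversed edge
        weights.
        """
        if term not in self.graph:
            raise OntologyError(f"unknown term {term!r}")
        closure = nx.descendants(self.graph, term) | {term}  # edges run upward
        sub = self.graph.subgraph(closure)
        s: dict[str, float] = {t: 0.0 for t in closure}
        s[term] = 1.0
        for node in nx.topological_sort(sub):
            for _, parent, rel in sub.out_edges(node, keys=True):
                w = self.weights.get(rel)
                if w is None:
                    continue
                cand = w * s[node]
                if cand > s[parent]:
                    s[parent] = cand
        return s


def pairwise_similarity(
    a: str,
    b: str,
    graph: OntologyGraph,
    *,
    _cache: dict[str, dict[str, float]] | None = None,
) -> float:
    """Semantic similarity of two terms in [0, 1].

    ``sim(a, b) = sum_{t in common ancestors}(S_a(t) + S_b(t)) /
    (sum_t S_a(t) + sum_t S_b(t))``, with each term counted among its own
    ancestors. Identical terms have similarity 1.
    """
    ns_a, ns_b = graph.namespace(a), graph.namespace(b)
    if ns_a != ns_b:
        raise OntologyError(
            f"cross-namespace similarity undefined: {a!r} ({ns_a}) vs {b!r} ({ns_b})"
        )
    if _cache is not None:
        sa = _cache.setdefault(a, graph.svalues(a))
        sb = _cache.setdefault(b, graph.svalues(b))
    else:
        sa, sb = graph.svalues(a), graph.svalues(b)
    common = sa.keys() & sb.keys()
    denom = sum(sa.values()) + sum(sb.values())
    if denom == 0:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / denom


@dataclass
class SpecificityResult:
    """One pair of semantic specificities between two enriched-term lists."""

    m: int  # translatome terms
    n: int  # transcriptome terms
    translatome_specificity: float | None
    transcriptome_specificity: float | None
    max_sim_translatome: pd.Series | None = None
    max_sim_transcriptome: pd.Series | None = None
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None


def _max_similarities(
    terms_a: Sequence[str],
    terms_b: Sequence[str],
    graph: OntologyGraph,
    cache: dict[str, dict[str, float]],
    cross_namespace_zero: bool,
) -> pd.Series:
    """For each term in ``terms_a``, its maximum similarity to ``terms_b``."""
    out = {}
    for t in terms_a:
        best = 0.0
        for u in terms_b:
            if graph.namespace(t) != graph.namespace(u):
                if cross_namespace_zero:
                    continue
                raise OntologyError(f"cross-namespace pair {t!r}/{u!r}")
            best = max(best, pairwise_similarity(t, u, graph, _cache=cache))
            if best == 1.0:
                break
        out[t] = best
    return pd.Series(out, dtype=float)


def one_sided_specificity(
    terms_a: Sequence[str],
    terms_b: Sequence[str],
    graph: OntologyGraph,
    *,
    cross_namespace_zero: bool = True,
    _cache: dict[str, dict[str, float]] | None = None,
) -> float:
    """``1 - mean over terms_a of max similarity to any term of terms_b``."""
    terms_a = list(dict.fromkeys(terms_a))
    terms_b = list(dict.fromkeys(terms_b))
    if not terms_a or not terms_b:
        raise OntologyError("one-sided specificity needs two non-empty term lists")
    cache = _cache if _cache is not None else {}
    ms = _max_similarities(terms_a, terms_b, graph, cache, cross_namespace_zero)
    return float(1.0 - ms.mean())


def semantic_specificity(
    translatome_terms: Sequence[str],
    transcriptome_terms: Sequence[str],
    graph: OntologyGraph,
    *,
    cross_namespace_zero: bool = True,
) -> SpecificityResult:
    """Semantic translatome and transcriptome specificity of two term lists.

    The translatome specificity is 1 minus the average, over the m
    translatome terms, of each term's maximal similarity to any of the n
    transcriptome terms; the transcriptome specificity swaps the roles and
    divides by n. Both lie in [0, 1]; identical lists give 0 and 0.
    """
    tl = list(dict.fromkeys(translatome_terms))
    tc = list(dict.fromkeys(transcriptome_terms))
    missing = [t for t in tl + tc if t not in graph]
    if missing:
        raise OntologyError(f"terms not in ontology: {sorted(set(missing))}")
    if not tl or not tc:
        reason = "empty translatome term list" if not tl else "empty transcriptome term list"
        return SpecificityResult(len(tl), len(tc), None, None, reason=reason)
    cache: dict[str, dict[str, float]] = {}
    ms_tl = _max_similarities(tl, tc, graph, cache, cross_namespace_zero)
    ms_tc = _max_similarities(tc, tl, graph, cache, cross_namespace_zero)
    return SpecificityResult(
        m=len(tl),
        n=len(tc),
        translatome_specificity=float(1.0 - ms_tl.mean()),
        transcriptome_specificity=float(1.0 - ms_tc.mean()),
        max_sim_translatome=ms_tl,
        max_sim_transcriptome=ms_tc,
    )


def reference_distribution(
    transcriptome_term_lists: Mapping[str, Sequence[str]],
    graph: OntologyGraph,
    observed: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Cross-dataset reference distribution of one-sided specificities.

    For each dataset ``i`` the reference values are the one-sided
    specificities of its transcriptome term list against the transcriptome
    term list of every other dataset. When ``observed`` supplies the
    within-pair transcriptome-vs-translatome specificity of dataset ``i``,
    its position relative to the reference (below the median / below the
    minimum) is flagged.
    """
    lists = {k: list(dict.fromkeys(v)) for k, v in transcriptome_term_lists.items()}
    nonempty = {k: v for k, v in lists.items() if v}
    for k in lists.keys() - nonempty.keys():
        logger.info("reference_distribution: dataset %r has an empty term list, skipped", k)
    if len(nonempty) < 3:
        raise OntologyError("reference distribution needs >= 3 datasets with non-empty lists")
    cache: dict[str, dict[str, float]] = {}
    rows = []
    for i, terms_i in nonempty.items():
        vals = [
            one_sided_specificity(terms_i, terms_j, graph, _cache=cache)
            for j, terms_j in nonempty.items()
            if j != i
        ]
        obs = None if observed is None else observed.get(i)
        rows.append(
            {
                "dataset": i,
                "n_reference": len(vals),
                "ref_min": float(np.min(vals)),
                "ref_median": float(np.median(vals)),
                "ref_max": float(np.max(vals)),
                "observed": obs,
                "below_median": None if obs is None else bool(obs < np.median(vals)),
                "below_distribution": None if obs is None else bool(obs < np.min(vals)),
            }
        )
    return pd.DataFrame(rows).set_index("dataset")


def goslim_specificity_degrees(
    per_dataset_terms: Mapping[str, tuple[Iterable[str], Iterable[str]]],
    slim_map: Mapping[str, str] | None = None,
) -> dict:
    """Per-term specificity degrees, slim-category medians, and the
    per-dataset normalized enrichment difference.

    ``per_dataset_terms`` maps a dataset name to its pair of enriched term
    sets ``(transcriptome_terms, translatome_terms)``. A term's
    transcriptome (translatome) specificity degree is the number of
    datasets in which it is enriched only at that level divided by the
    number of datasets in which it is enriched at all. The per-dataset
    normalized difference is ``(#translatome-only - #transcriptome-only) /
    (#translatome-only + #transcriptome-only)``, in [-1, 1].
    """
    n_over: dict[str, int] = {}
    n_tspec: dict[str, int] = {}
    n_pspec: dict[str, int] = {}
    norm_diff = {}
    for ds, (tc_terms, tl_terms) in per_dataset_terms.items():
        tc, tl = set(tc_terms), set(tl_terms)
        for t in tc | tl:
            n_over[t] = n_over.get(t, 0) + 1
        for t in tc - tl:
            n_tspec[t] = n_tspec.get(t, 0) + 1
        for t in tl - tc:
            n_pspec[t] = n_pspec.get(t, 0) + 1
        n_only_tc, n_only_tl = len(tc - tl), len(tl - tc)
        tot = n_only_tc + n_only_tl
        norm_diff[ds] = (n_only_tl - n_only_tc) / tot if tot else float("nan")

    terms = sorted(n_over)
    term_table = pd.DataFrame(
        {
            "n_overrepresented": [n_over[t] for t in terms],
            "transcriptome_degree": [n_tspec.get(t, 0) / n_over[t] for t in terms],
            "translatome_degree": [n_pspec.get(t, 0) / n_over[t] for t in terms],
        },
        index=pd.Index(terms, name="term"),
    )
    if slim_map is not None:
        term_table["slim_category"] = [slim_map.get(t) for t in terms]
        cat = (
            term_table.dropna(subset=["slim_category"])
            .groupby("slim_category")
            .agg(
                n_terms=("n_overrepresented", "size"),
                transcriptome_degree=("transcriptome_degree", "median"),
                translatome_degree=("translatome_degree", "median"),
            )
        )
        cat["degree_difference"] = cat["translatome_degree"] - cat["transcriptome_degree"]
        cat = cat.sort_values("degree_difference", ascending=False)
    else:
        cat = None
    return {
        "term_table": term_table,
        "category_table": cat,
        "normalized_difference": pd.Series(norm_diff, name="normalized_difference"),
    }


# -- OBO I/O -------------------------------------------------------------

def parse_obo(path, weights: Mapping[str, float] | None = None) -> OntologyGraph:
    """Read an OBO 1.2 file into an :class:`OntologyGraph`.

    Obsolete terms are dropped (and counted in the log); only ``is_a`` and
    ``part_of`` edges are retained.
    """
    raw = obonet.read_obo(path, ignore_obsolete=False)
    obsolete = [n for n, d in raw.nodes(data=True) if d.get("is_obsolete") == "true"]
    if obsolete:
        logger.info("parse_obo: dropped %d obsolete terms", len(obsolete))
        raw.remove_nodes_from(obsolete)
    g = nx.MultiDiGraph()
    for n, d in raw.nodes(data=True):
        g.add_node(n, name=d.get("name", n), namespace=d.get("namespace"))
    skipped_relations: set[str] = set()
    for u, v, k in raw.edges(keys=True):
        if k in SUPPORTED_RELATIONS:
            if v in g:
                g.add_edge(u, v, key=k)
        else:
            skipped_relations.add(k)
    if skipped_relations:
        logger.info("parse_obo: ignored relation types %s", sorted(skipped_relations))
    kwargs = {} if weights is None else {"weights": dict(weights)}
    return OntologyGraph(g, **kwargs)


def write_obo(graph: OntologyGraph, path) -> None:
    """Write the graph as a minimal OBO 1.2 document."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(graph.graph.nodes):
            d = graph.graph.nodes[term]
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {d.get('name', term)}\n")
            if d.get("namespace"):
                fh.write(f"namespace: {d['namespace']}\n")
            for _, parent, rel in sorted(graph.graph.out_edges(term, keys=True)):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
            fh.write("\n")
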