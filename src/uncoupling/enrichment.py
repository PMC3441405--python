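"""Over-representation analysis of DEG lists against term catalogs.

The core statistic is the one-sided hypergeometric (Fisher) enrichment
p-value per term, with Benjamini-Hochberg control of the false discovery
rate across terms. An EASE-style conservative variant (overlap reduced by
one) is available behind a flag. The module also provides the between-level
term-overlap summary and the generic network/function specificity degree
used to compare how cellular functions distribute between translatome- and
transcriptome-derived association tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    pass


@dataclass
class AnnotationCatalog:
    """term -> gene-set mapping with optional term metadata."""

    term_to_genes: dict[str, frozenset[str]]
    term_names: dict[str, str] = field(default_factory=dict)
    term_namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.term_to_genes = {t: frozenset(g) for t, g in self.term_to_genes.items()}

    @property
    def terms(self) -> list[str]:
        return list(self.term_to_genes)

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.term_to_genes.values():
            out |= g
        return frozenset(out)

    def restrict_to_universe(self, universe: Iterable[str]) -> "AnnotationCatalog":
        """Intersect every term's gene set with ``universe``; drop empty terms."""
        uni = frozenset(universe)
        kept = {
            t: g & uni for t, g in self.term_to_genes.items() if g & uni
        }
        dropped = len(self.term_to_genes) - len(kept)
        if dropped:
            logger.info("catalog restriction dropped %d empty terms", dropped)
        return AnnotationCatalog(kept, dict(self.term_names), dict(self.term_namespaces))

    @classmethod
    def from_tsv(cls, path) -> "AnnotationCatalog":
        """Read a two-column (gene_id, term_id) TSV."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] < 2:
            raise EnrichmentError("annotation TSV needs two columns: gene_id, term_id")
        gene_col, term_col = df.columns[:2]
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(df[gene_col], df[term_col]):
            mapping.setdefault(term, set()).add(gene)
        return cls({t: frozenset(g) for t, g in mapping.items()})

    def to_tsv(self, path) -> None:
        rows = [
            {"gene_id": g, "term_id": t}
            for t in sorted(self.term_to_genes)
            for g in sorted(self.term_to_genes[t])
        ]
        pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)


def fisher_enrichment(
    degs: Iterable[str],
    universe: Iterable[str],
    catalog: AnnotationCatalog,
    fdr: float = 0.05,
    *,
    ease: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``degs`` per catalog term.

    For a term annotating K of the N universe genes, with n DEGs and
    overlap k, the p-value is P(X >= k) for X ~ Hypergeom(N, K, n). With
    ``ease=True`` the overlap is reduced by one before taking the tail
    (EASE score), a conservative variant. BH step-up flags terms enriched
    at adjusted p < ``fdr``.
    """
    universe = frozenset(universe)
    degs = frozenset(degs)
    if not degs <= universe:
        raise EnrichmentError(
            f"{len(degs - universe)} DEGs are not in the universe"
        )
    cat = catalog.restrict_to_universe(universe)
    N, n = len(universe), len(degs)
    rows = []
    for term in sorted(cat.term_to_genes):
        genes = cat.term_to_genes[term]
        K = len(genes)
        k = len(genes & degs)
        k_eff = max(k - 1, 0) if ease else k
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "n_universe": N,
                "n_term": K,
                "n_deg": n,
                "n_overlap": k,
                "p_value": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "n_universe", "n_term", "n_deg", "n_overlap", "p_value"]
    ).set_index("term")
    if len(result):
        reject, padj, _, _ = multipletests(result["p_value"].to_numpy(), alpha=fdr, method="fdr_bh")
        result["p_adjusted"] = np.maximum(padj, result["p_value"])
        result["enriched"] = reject
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
    return result.sort_values("p_value")


def enriched_terms(result: pd.DataFrame) -> set[str]:
    """Terms flagged enriched in a :func:`fisher_enrichment` result."""
    if result.empty:
        return set()
    return set(result.index[result["enriched"]])


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def term_overlap_summary(
    transcriptome_terms: Iterable[str], translatome_terms: Iterable[str]
) -> dict:
    """Counts and integer percentages of common and level-specific terms.

    Percentages are taken over the union of the two enriched-term sets and
    rounded half away from zero; with two empty sets they are ``None``.
    """
    tc, tl = set(transcriptome_terms), set(translatome_terms)
    common = len(tc & tl)
    tc_only = len(tc - tl)
    tl_only = len(tl - tc)
    total = common + tc_only + tl_only
    if total == 0:
        pct = {"common": None, "transcriptome_specific": None, "translatome_specific": None}
    else:
        pct = {
            "common": _round_half_away(100.0 * common / total),
            "transcriptome_specific": _round_half_away(100.0 * tc_only / total),
            "translatome_specific": _round_half_away(100.0 * tl_only / total),
        }
    return {
        "n_common": common,
        "n_transcriptome_specific": tc_only,
        "n_translatome_specific": tl_only,
        "n_total": total,
        "percent": pct,
    }


def network_specificity_degree(
    n_translatome_networks: int,
    n_transcriptome_networks: int,
    min_networks: int = 5,
) -> float | None:
    """Translatome network specificity degree of one cellular function.

    ``(n_translatome - n_transcriptome) / (n_translatome + n_transcriptome)``,
    in [-1, 1]. Functions whose total associated-network count is at most
    ``min_networks`` are excluded (``None``).
    """
    if n_translatome_networks < 0 or n_transcriptome_networks < 0:
        raise EnrichmentError("network counts must be nonnegative")
    total = n_translatome_networks + n_transcriptome_networks
    if total <= min_networks:
        return None
    return (n_translatome_networks - n_transcriptome_networks) / total


def network_specificity_table(
    counts: pd.DataFrame, min_networks: int = 5
) -> pd.DataFrame:
    """Vectorized :func:`network_specificity_degree` over a function table.

    ``counts`` must have columns ``n_translatome_networks`` and
    ``n_transcriptome_networks`` indexed by function label; excluded
    functions are dropped. Sorted most translatome-specific first.
    """
    degs = {
        fn: network_specificity_degree(
            int(row["n_translatome_networks"]),
            int(row["n_transcriptome_networks"]),
            min_networks,
        )
        for fn, row in counts.iterrows()
    }
    kept = {fn: d for fn, d in degs.items() if d is not None}
    out = counts.loc[list(kept)].copy()
    out["specificity_degree"] = pd.Series(kept)
    return out.sort_values("specificity_degree", ascending=False)
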