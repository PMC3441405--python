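"""Synthetic paired transcriptome/translatome datasets with planted
coupling structure, plus toy ontologies with gene annotations.

The generator emulates a replicated two-group (control vs treated)
log2-intensity microarray design profiled at two RNA levels. Each gene is
planted in one of five coupling classes — coupled (same-direction change at
both levels), antidirectional (opposite directions), transcriptome-only,
translatome-only, unchanged — and the planted per-level signed log2 effects
are recorded as ground truth so downstream callers can be benchmarked on
parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationCatalog
from .prep import GROUPS, LEVELS, PairedExpressionSet
from .semantics import OntologyGraph

import networkx as nx

COUPLING_CLASSES = (
    "coupled",
    "antidirectional",
    "transcriptome_only",
    "translatome_only",
    "unchanged",
)

#: default planted mix: every DEG class equally represented, at the sparse
#: per-level DEG density (a few percent of the measured genes) typical of
#: replicated two-group microarray comparisons
DEFAULT_CLASS_FRACTIONS = {
    "coupled": 0.025,
    "antidirectional": 0.025,
    "transcriptome_only": 0.025,
    "translatome_only": 0.025,
    "unchanged": 0.90,
}


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic paired dataset.

    ``effect_size`` is the absolute planted log2 fold change of every DEG
    (sign random unless ``fixed_direction`` pins it); ``noise_sd`` the
    replicate-level Gaussian sd in log2 units; baselines are uniform in
    log2 space over ``baseline_range`` to mimic microarray dynamic range.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    effect_size: float = 2.0
    noise_sd: float = 0.3
    baseline_range: tuple[float, float] = (6.0, 14.0)
    seed: int = 0
    fixed_direction: int | None = None  # +1 / -1 pins DEG sign
    n_low_signal: int = 0  # features planted majority-absent everywhere

    def __post_init__(self) -> None:
        unknown = set(self.class_fractions) - set(COUPLING_CLASSES)
        if unknown:
            raise SyntheticConfigError(f"unknown coupling classes: {sorted(unknown)}")
        fracs = {c: self.class_fractions.get(c, 0.0) for c in COUPLING_CLASSES}
        if any(f < 0 for f in fracs.values()):
            raise SyntheticConfigError("class fractions must be nonnegative")
        if abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise SyntheticConfigError(
                f"class fractions must sum to 1, got {sum(fracs.values())}"
            )
        self.class_fractions = fracs
        if self.n_replicates < 2:
            raise SyntheticConfigError("need at least 2 replicates per group")
        if self.noise_sd < 0:
            raise SyntheticConfigError("noise_sd must be >= 0")
        if self.n_genes < 1:
            raise SyntheticConfigError("n_genes must be positive")
        if self.n_low_signal < 0 or self.n_low_signal >= self.n_genes:
            raise SyntheticConfigError("n_low_signal must be in [0, n_genes)")


def _largest_remainder_counts(fractions: dict[str, float], total: int) -> dict[str, int]:
    """Integer class counts matching ``fractions`` as closely as possible."""
    raw = {c: fractions[c] * total for c in COUPLING_CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    shortfall = total - sum(counts.values())
    remainders = sorted(
        COUPLING_CLASSES, key=lambda c: (raw[c] - counts[c], c), reverse=True
    )
    for c in remainders[:shortfall]:
        counts[c] += 1
    return counts


@dataclass
class SyntheticTruth:
    """Planted class label and signed per-level log2 effects per gene."""

    table: pd.DataFrame  # columns: class, effect_transcriptome, effect_translatome

    def genes_of_class(self, cls: str) -> pd.Index:
        return self.table.index[self.table["class"] == cls]

    def planted_degs(self, level: str) -> pd.Index:
        col = f"effect_{level}"
        return self.table.index[self.table[col] != 0.0]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "SyntheticTruth":
        return cls(pd.read_csv(path, sep="\t", index_col="gene_id"))


def generate_paired_dataset(
    config: SyntheticConfig,
) -> tuple[PairedExpressionSet, SyntheticTruth]:
    """Draw one paired dataset plus its planted ground truth.

    Class counts follow the requested fractions exactly (largest-remainder
    rounding); class membership is randomly assigned across genes. Treated
    means are shifted by the planted signed effects; all replicates receive
    iid Gaussian noise. Identical seeds give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")

    counts = _largest_remainder_counts(config.class_fractions, n)
    labels = np.concatenate(
        [np.full(counts[c], i) for i, c in enumerate(COUPLING_CLASSES)]
    )
    rng.shuffle(labels)
    classes = np.array(COUPLING_CLASSES)[labels]

    if config.fixed_direction is not None:
        signs = np.full(n, float(np.sign(config.fixed_direction)))
    else:
        signs = rng.choice([-1.0, 1.0], size=n)
    e = config.effect_size
    eff_tc = np.zeros(n)
    eff_tl = np.zeros(n)
    for i, cls in enumerate(classes):
        if cls == "coupled":
            eff_tc[i] = eff_tl[i] = signs[i] * e
        elif cls == "antidirectional":
            eff_tc[i] = signs[i] * e
            eff_tl[i] = -signs[i] * e
        elif cls == "transcriptome_only":
            eff_tc[i] = signs[i] * e
        elif cls == "translatome_only":
            eff_tl[i] = signs[i] * e

    low, high = config.baseline_range
    baseline = rng.uniform(low, high, size=n)
    effects = {"transcriptome": eff_tc, "translatome": eff_tl}
    reps = config.n_replicates
    matrices = {}
    for level, cond in GROUPS:
        mean = baseline + (effects[level] if cond == "treated" else 0.0)
        noise = rng.normal(0.0, config.noise_sd, size=(n, reps))  # scale 0 => exact means
        data = mean[:, None] + noise
        cols = [f"{level[:5]}_{cond[:4]}_{r + 1}" for r in range(reps)]
        matrices[(level, cond)] = pd.DataFrame(data, index=genes, columns=cols)

    detection = None
    if config.n_low_signal > 0:
        # plant the absent features among unchanged genes where possible
        unchanged_pos = np.flatnonzero(classes == "unchanged")
        pool = unchanged_pos if len(unchanged_pos) >= config.n_low_signal else np.arange(n)
        absent_pos = rng.choice(pool, size=config.n_low_signal, replace=False)
        detection = {}
        for key, m in matrices.items():
            det = pd.DataFrame(True, index=genes, columns=m.columns)
            det.iloc[absent_pos] = False
            detection[key] = det

    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "class": classes,
                "effect_transcriptome": eff_tc,
                "effect_translatome": eff_tl,
            },
            index=genes,
        )
    )
    return PairedExpressionSet(matrices, detection), truth


def generate_toy_ontology(
    n_terms: int,
    branching: int = 2,
    seed: int = 0,
    genes: list[str] | None = None,
    part_of_prob: float = 0.15,
    extra_parent_prob: float = 0.15,
    genes_per_term: tuple[int, int] = (1, 3),
) -> tuple[OntologyGraph, AnnotationCatalog, dict[str, str]]:
    """Build a rooted toy DAG ontology with annotations and a slim mapping.

    Terms form a ``branching``-ary tree plus occasional extra parents
    (making a DAG); edges are mostly ``is_a`` with some ``part_of``. Every
    term annotates at least one gene. The slim mapping sends each term to
    its depth-1 ancestor along the primary tree (the root maps to itself).
    """
    if n_terms < 1:
        raise SyntheticConfigError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"TOY:{i:07d}" for i in range(n_terms)]
    g = nx.MultiDiGraph()
    namespace = "toy_process"
    for i, tid in enumerate(ids):
        g.add_node(tid, name=f"toy term {i}", namespace=namespace)
    primary_parent: dict[int, int] = {}
    for i in range(1, n_terms):
        parent = (i - 1) // branching
        primary_parent[i] = parent
        rel = "part_of" if rng.random() < part_of_prob else "is_a"
        g.add_edge(ids[i], ids[parent], key=rel)
        if i >= 2 and rng.random() < extra_parent_prob:
            extra = int(rng.integers(0, i))
            if extra != parent:
                g.add_edge(ids[i], ids[extra], key="is_a")
    graph = OntologyGraph(g)

    if genes is None:
        genes = [f"G{i:05d}" for i in range(max(2 * n_terms, 4))]
    lo, hi = genes_per_term
    term_to_genes = {}
    for tid in ids:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(genes))
        term_to_genes[tid] = frozenset(rng.choice(genes, size=k, replace=False))
    catalog = AnnotationCatalog(
        term_to_genes,
        term_names={tid: g.nodes[tid]["name"] for tid in ids},
        term_namespaces={tid: namespace for tid in ids},
    )

    def depth1_ancestor(i: int) -> int:
        while i > 0 and primary_parent.get(i, 0) != 0:
            i = primary_parent[i]
        return i

    slim_map = {ids[i]: ids[depth1_ancestor(i)] for i in range(n_terms)}
    return graph, catalog, slim_map


def write_dataset(
    directory, pes: PairedExpressionSet, truth: SyntheticTruth
) -> None:
    """Write the expression set (four TSVs + sample sheet) and truth TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pes.to_tsv(directory)
    truth.to_tsv(directory / "truth.tsv")
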