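"""Loading, filtering, normalization and fold-change computation for
paired transcriptome/translatome expression data.

A :class:`PairedExpressionSet` holds four log2-intensity matrices (two RNA
levels x two conditions) over one shared feature universe, with optional
per-array detection calls. Preprocessing follows the standard two-color
microarray route: detection-call filtering of low-signal features, quantile
normalization across all arrays, probe-to-gene averaging, and per-level
log2 fold changes (treated minus control replicate means).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("transcriptome", "translatome")
CONDITIONS = ("control", "treated")
GROUPS = tuple((lv, cond) for lv in LEVELS for cond in CONDITIONS)


class ExpressionError(ValueError):
    pass


@dataclass
class PairedExpressionSet:
    """Four matrices of log2 intensities over one gene/probe universe.

    ``matrices`` maps ``(level, condition)`` to a features-by-replicates
    DataFrame; ``detection`` optionally maps the same keys to boolean
    "present" matrices of identical shape.
    """

    matrices: dict[tuple[str, str], pd.DataFrame]
    detection: dict[tuple[str, str], pd.DataFrame] | None = None

    def __post_init__(self) -> None:
        missing = set(GROUPS) - set(self.matrices)
        if missing:
            raise ExpressionError(f"missing matrices for groups: {sorted(missing)}")
        index = self.matrices[GROUPS[0]].index
        for key, m in self.matrices.items():
            if not m.index.equals(index):
                raise ExpressionError(f"feature universe of {key} differs from {GROUPS[0]}")
            if m.shape[1] < 2:
                raise ExpressionError(f"group {key} has fewer than 2 replicates")
        if self.detection is not None:
            for key, d in self.detection.items():
                if d.shape != self.matrices[key].shape:
                    raise ExpressionError(f"detection matrix shape mismatch for {key}")

    @property
    def features(self) -> pd.Index:
        return self.matrices[GROUPS[0]].index

    def subset(self, features: pd.Index) -> "PairedExpressionSet":
        det = None
        if self.detection is not None:
            det = {k: d.loc[features] for k, d in self.detection.items()}
        return PairedExpressionSet({k: m.loc[features] for k, m in self.matrices.items()}, det)

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for (level, cond), m in self.matrices.items():
            for i, col in enumerate(m.columns, start=1):
                rows.append(
                    {"sample_id": col, "level": level, "condition": cond, "replicate": i}
                )
        return pd.DataFrame(rows, columns=["sample_id", "level", "condition", "replicate"])

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, directory) -> None:
        """Write four matrix TSVs plus ``samples.tsv`` (and detection calls)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for (level, cond), m in self.matrices.items():
            m.to_csv(directory / f"{level}_{cond}.tsv", sep="\t", index_label="feature_id")
        if self.detection is not None:
            for (level, cond), d in self.detection.items():
                d.astype(int).to_csv(
                    directory / f"detection_{level}_{cond}.tsv", sep="\t",
                    index_label="feature_id",
                )
        self.sample_sheet().to_csv(directory / "samples.tsv", sep="\t", index=False)

    @classmethod
    def from_tsv(cls, directory) -> "PairedExpressionSet":
        directory = Path(directory)
        matrices = {}
        detection = {}
        for level, cond in GROUPS:
            matrices[(level, cond)] = pd.read_csv(
                directory / f"{level}_{cond}.tsv", sep="\t", index_col="feature_id"
            )
            det_path = directory / f"detection_{level}_{cond}.tsv"
            if det_path.exists():
                detection[(level, cond)] = (
                    pd.read_csv(det_path, sep="\t", index_col="feature_id").astype(bool)
                )
        return cls(matrices, detection or None)


def filter_low_signal(
    pes: PairedExpressionSet, majority_fraction: float = 0.5
) -> tuple[PairedExpressionSet, int]:
    """Drop features flagged absent in the majority of arrays of *every* group.

    A feature is removed when, within each of the four level-condition
    groups, the fraction of arrays calling it absent exceeds
    ``majority_fraction``. Without detection calls the set passes through
    unchanged with a logged warning.
    """
    if not 0.5 <= majority_fraction <= 1.0:
        raise ExpressionError("majority_fraction must be in [0.5, 1]")
    if pes.detection is None:
        logger.warning("filter_low_signal: no detection calls, passing through")
        return pes, 0
    absent_everywhere = pd.Series(True, index=pes.features)
    for key in GROUPS:
        det = pes.detection.get(key)
        if det is None:
            raise ExpressionError(f"missing detection calls for group {key}")
        absent_frac = 1.0 - det.mean(axis=1)
        absent_everywhere &= absent_frac > majority_fraction
    kept = pes.features[~absent_everywhere]
    n_removed = int(absent_everywhere.sum())
    logger.info("filter_low_signal removed %d features", n_removed)
    return pes.subset(kept), n_removed


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns (arrays) of a features-by-arrays matrix.

    Every column is mapped onto the common reference distribution of
    rank-wise cross-column means; tied input values receive the mean of
    their tied ranks' reference values. Columns of the output share one
    sorted value vector, so the operation is idempotent.
    """
    if matrix.shape[1] < 2:
        raise ExpressionError("quantile normalization needs >= 2 columns")
    if matrix.isna().any().any():
        bad = [
            (str(idx), str(col))
            for col in matrix.columns
            for idx in matrix.index[matrix[col].isna()]
        ]
        raise ExpressionError(f"missing values at (feature, array): {bad[:10]}")
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(p):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # group ties: mean of the reference values at the tied positions
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [n]))
        targets = np.empty(n)
        for s, e in zip(starts, ends):
            targets[s:e] = reference[s:e].mean()
        out[order, j] = targets
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantile_normalize_set(pes: PairedExpressionSet) -> PairedExpressionSet:
    """Quantile-normalize jointly across all arrays of all four groups."""
    joint = pd.concat(
        {key: m for key, m in pes.matrices.items()}, axis=1
    )
    joint.columns = [f"{lv}|{cond}|{col}" for (lv, cond), m in pes.matrices.items() for col in m.columns]
    normed = quantile_normalize(joint)
    matrices = {}
    start = 0
    for key, m in pes.matrices.items():
        stop = start + m.shape[1]
        block = normed.iloc[:, start:stop].copy()
        block.columns = m.columns
        matrices[key] = block
        start = stop
    return PairedExpressionSet(matrices, pes.detection)


def collapse_probes_to_genes(
    matrix: pd.DataFrame, probe_gene_map: Mapping[str, str] | pd.Series
) -> tuple[pd.DataFrame, int]:
    """Average probe rows mapping to the same gene.

    ``probe_gene_map`` maps probe id -> gene id; a probe mapped to more
    than one gene is an error. Probes without a mapping are dropped and
    counted in the returned tally.
    """
    if isinstance(probe_gene_map, pd.Series):
        dup = probe_gene_map.index[probe_gene_map.index.duplicated()]
        if len(dup):
            conflicts = [
                p for p in dup.unique() if probe_gene_map.loc[[p]].nunique() > 1
            ]
            if conflicts:
                raise ExpressionError(f"probes mapped to multiple genes: {conflicts[:10]}")
            probe_gene_map = probe_gene_map[~probe_gene_map.index.duplicated()]
        mapping = probe_gene_map.to_dict()
    else:
        mapping = dict(probe_gene_map)
    genes = matrix.index.map(lambda p: mapping.get(p))
    unmapped = genes.isna()
    n_unmapped = int(unmapped.sum())
    if n_unmapped:
        logger.info("collapse_probes_to_genes dropped %d unmapped probes", n_unmapped)
    kept = matrix.loc[~unmapped]
    collapsed = kept.groupby(genes[~unmapped]).mean()
    collapsed.index.name = "gene_id"
    return collapsed, n_unmapped


def collapse_set(
    pes: PairedExpressionSet, probe_gene_map: Mapping[str, str] | pd.Series
) -> tuple[PairedExpressionSet, int]:
    """Apply :func:`collapse_probes_to_genes` to all four matrices."""
    matrices = {}
    n_unmapped = 0
    for key, m in pes.matrices.items():
        matrices[key], n_unmapped = collapse_probes_to_genes(m, probe_gene_map)
    return PairedExpressionSet(matrices, None), n_unmapped


def compute_fold_changes(pes: PairedExpressionSet) -> pd.DataFrame:
    """Per-gene, per-level mean log2 fold change (treated minus control)."""
    out = {}
    for level in LEVELS:
        treated = pes.matrices[(level, "treated")].mean(axis=1)
        control = pes.matrices[(level, "control")].mean(axis=1)
        out[f"fc_{level}"] = treated - control
    return pd.DataFrame(out, index=pes.features)
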