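"""Coupling/uncoupling classification of paired DEG calls.

A gene significant at both RNA levels with homodirectional change is
*coupled*; uncoupled genes are those significant at both levels in
opposite directions (antidirectional), or significant at exactly one level
(transcriptome-only / translatome-only). Genes significant nowhere are
unchanged. Summaries report class percentages over DEGs, the
translatome-only : transcriptome-only ratio, a significance-threshold
sweep, and translational enhancement/buffering counts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASSES = (
    "coupled",
    "antidirectional",
    "transcriptome_only",
    "translatome_only",
    "unchanged",
)
DEG_CLASSES = CLASSES[:4]


class CouplingError(ValueError):
    pass


def _classify_one(sig_tc: bool, sig_tl: bool, same_dir: bool) -> str:
    if sig_tc and sig_tl:
        return "coupled" if same_dir else "antidirectional"
    if sig_tc:
        return "transcriptome_only"
    if sig_tl:
        return "translatome_only"
    return "unchanged"


def classify_coupling(
    transcriptome: pd.DataFrame, translatome: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene coupling class from two DEG tables over one universe.

    Both tables need ``log2fc``, ``direction`` and ``significant`` columns
    (as produced by the rank-product or t-test callers). Direction comes
    from the caller's per-gene direction, not the fold-change sign.
    """
    if not transcriptome.index.sort_values().equals(translatome.index.sort_values()):
        diff = set(transcriptome.index).symmetric_difference(translatome.index)
        raise CouplingError(f"gene universes differ; symmetric difference: {sorted(diff)[:20]}")
    tl = translatome.loc[transcriptome.index]
    tc = transcriptome
    disagree = (
        tc["significant"]
        & ((tc["direction"] == "up") != (tc["log2fc"] >= 0))
    )
    if disagree.any():
        logger.info(
            "classify_coupling: %d transcriptome calls where caller direction "
            "disagrees with fold-change sign (caller direction used)",
            int(disagree.sum()),
        )
    sig_tc = tc["significant"].to_numpy(bool)
    sig_tl = tl["significant"].to_numpy(bool)
    same_dir = (tc["direction"].to_numpy() == tl["direction"].to_numpy())
    classes = [
        _classify_one(a, b, s) for a, b, s in zip(sig_tc, sig_tl, same_dir)
    ]
    return pd.DataFrame(
        {
            "coupling_class": pd.Categorical(classes, categories=CLASSES),
            "fc_transcriptome": tc["log2fc"],
            "fc_translatome": tl["log2fc"],
            "sig_transcriptome": sig_tc,
            "sig_translatome": sig_tl,
            "direction_transcriptome": tc["direction"],
            "direction_translatome": tl["direction"],
        },
        index=tc.index,
    )


def summarize_uncoupling(table: pd.DataFrame) -> dict:
    """Counts and percentages per coupling class.

    Percentages are over DEGs only (unchanged genes excluded); the percent
    uncoupled pools the antidirectional and the two single-level classes.
    With zero DEGs all percentages are ``None``.
    """
    if table.empty:
        raise CouplingError("empty coupling table")
    counts = table["coupling_class"].value_counts().reindex(CLASSES, fill_value=0)
    n_degs = int(counts[list(DEG_CLASSES)].sum())
    n_uncoupled = n_degs - int(counts["coupled"])
    if n_degs == 0:
        percent = {c: None for c in DEG_CLASSES}
        percent_uncoupled = None
    else:
        percent = {c: 100.0 * counts[c] / n_degs for c in DEG_CLASSES}
        percent_uncoupled = 100.0 * n_uncoupled / n_degs
    n_tc_only, n_tl_only = int(counts["transcriptome_only"]), int(counts["translatome_only"])
    if n_tc_only > 0:
        ratio = n_tl_only / n_tc_only
    else:
        ratio = float("inf") if n_tl_only > 0 else None
    return {
        "counts": {c: int(counts[c]) for c in CLASSES},
        "n_genes": int(len(table)),
        "n_degs": n_degs,
        "n_uncoupled": n_uncoupled,
        "percent": percent,
        "percent_uncoupled": percent_uncoupled,
        "translatome_to_transcriptome_only_ratio": ratio,
        "ratio_nearest_int": None if ratio in (None, float("inf")) else round(ratio),
    }


def threshold_sweep(
    transcriptome: pd.DataFrame,
    translatome: pd.DataFrame,
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Recompute class proportions across a grid of significance cutoffs.

    The tables must carry a per-gene ``pfp`` (or ``p_adjusted``) column and
    a ``direction`` column; significance is re-derived at each threshold.
    Returns a tidy (threshold, class, count, proportion-of-DEGs) table.
    """
    for thr in thresholds:
        if not 0 < thr <= 1:
            raise CouplingError(f"threshold {thr} outside (0, 1]")
    col = "pfp" if "pfp" in transcriptome.columns else "p_adjusted"
    rows = []
    for thr in thresholds:
        tc = transcriptome.copy()
        tl = translatome.copy()
        tc["significant"] = tc[col] < thr
        tl["significant"] = tl[col] < thr
        summary = summarize_uncoupling(classify_coupling(tc, tl))
        for cls in CLASSES:
            rows.append(
                {
                    "threshold": thr,
                    "coupling_class": cls,
                    "count": summary["counts"][cls],
                    "proportion_of_degs": (
                        None
                        if cls == "unchanged" or summary["n_degs"] == 0
                        else summary["counts"][cls] / summary["n_degs"]
                    ),
                }
            )
    return pd.DataFrame(rows)


def buffering_counts(
    fold_changes: pd.DataFrame, genes: Iterable[str] | None = None
) -> dict:
    """Translational enhancement vs buffering counts.

    A gene is enhanced when its translatome (polysomal) fold change
    strictly exceeds its transcriptome (total) fold change, buffered when
    strictly below; equal fold changes are tied and counted separately.
    ``genes`` restricts the scope (typically the DEG union).
    """
    fc = fold_changes if genes is None else fold_changes.loc[list(genes)]
    diff = fc["fc_translatome"] - fc["fc_transcriptome"]
    enhanced = int((diff > 0).sum())
    buffered = int((diff < 0).sum())
    tied = int((diff == 0).sum())
    total = enhanced + buffered
    return {
        "enhanced": enhanced,
        "buffered": buffered,
        "tied": tied,
        "percent_enhanced": 100.0 * enhanced / total if total else None,
        "percent_buffered": 100.0 * buffered / total if total else None,
    }
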