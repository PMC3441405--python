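"""End-to-end orchestration: preprocessing, DEG calling at both RNA
levels, coupling classification, enrichment, semantic specificity and the
independence tests, from one declarative configuration.

The report is a plain JSON-serializable dictionary validated against the
schema published in ``schemas/report.schema.json``; per-stage tables are
written as TSVs next to it when an output directory is configured. Every
seed and interpretation choice is recorded in the report so a run is
self-documenting and byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import coupling as cp
from . import enrichment as en
from . import independence as ind
from . import prep
from . import rankprod as rp
from . import semantics as sem
from . import synthetic as syn
from ._schema import validate as validate_schema

logger = logging.getLogger(__name__)

_SCHEMA_PATH = Path(__file__).resolve().parents[2] / "schemas" / "report.schema.json"


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """One pipeline run: either a synthetic block or input paths."""

    synthetic: dict | None = None
    input_dir: str | None = None
    probe_gene_map: str | None = None
    ontology_obo: str | None = None
    annotations: str | None = None
    slim_map: str | None = None
    toy_ontology: dict | None = None
    deg_method: str = "rankprod"
    deg_threshold: float = 0.2
    n_permutations: int = 1000
    n_bootstrap: int = 100_000
    majority_fraction: float = 0.5
    quantile_normalization: bool = True
    log2_transform: bool = False
    threshold_grid: Sequence[float] | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None and self.input_dir is None:
            raise PipelineError("config needs either a synthetic block or an input_dir")
        if self.synthetic is not None and self.input_dir is not None:
            raise PipelineError("synthetic block and input_dir are mutually exclusive")
        if self.deg_method not in ("rankprod", "ttest"):
            raise PipelineError(f"unknown DEG method {self.deg_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _deg_table(
    config: PipelineConfig, pes: prep.PairedExpressionSet, level: str, seed: int
) -> pd.DataFrame:
    control = pes.matrices[(level, "control")]
    treated = pes.matrices[(level, "treated")]
    if config.deg_method == "rankprod":
        return rp.rankprod_deg_table(
            control,
            treated,
            n_permutations=config.n_permutations,
            seed=seed,
            threshold=config.deg_threshold,
        )
    table = rp.ttest_bh_caller(control, treated, alpha=config.deg_threshold)
    table["significant"] = table["p_adjusted"] < config.deg_threshold
    return table


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the report dict (and write outputs)."""
    notes: list[str] = [
        "rank product variant: unpaired, all control x treated replicate pairings",
        "bootstrap universe: all genes surviving expression filters",
    ]
    skipped: list[str] = []
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # -- inputs ----------------------------------------------------------
    truth = None
    if config.synthetic is not None:
        syn_cfg = syn.SyntheticConfig(**config.synthetic)
        pes, truth = syn.generate_paired_dataset(syn_cfg)
    else:
        pes = prep.PairedExpressionSet.from_tsv(config.input_dir)
        if config.log2_transform:
            import numpy as np

            pes = prep.PairedExpressionSet(
                {k: np.log2(m) for k, m in pes.matrices.items()}, pes.detection
            )
            notes.append("input intensities log2-transformed")

    # -- preprocessing ---------------------------------------------------
    n_features_in = len(pes.features)
    pes, n_removed = prep.filter_low_signal(pes, config.majority_fraction)
    if config.quantile_normalization:
        pes = prep.quantile_normalize_set(pes)
    if config.probe_gene_map:
        mapping = pd.read_csv(config.probe_gene_map, sep="\t", index_col=0).iloc[:, 0]
        pes, n_unmapped = prep.collapse_set(pes, mapping)
        notes.append(f"probe collapse dropped {n_unmapped} unmapped probes")
    fold_changes = prep.compute_fold_changes(pes)

    # -- DEG calling -----------------------------------------------------
    deg_tables = {}
    for i, level in enumerate(prep.LEVELS):
        deg_tables[level] = _deg_table(config, pes, level, seed=config.seed + 10 * i)
    deg_sets = {
        level: rp.call_degs(t, config.deg_threshold)[0] for level, t in deg_tables.items()
    }

    # -- coupling --------------------------------------------------------
    coupling_table = cp.classify_coupling(
        deg_tables["transcriptome"], deg_tables["translatome"]
    )
    coupling_summary = cp.summarize_uncoupling(coupling_table)
    deg_union = coupling_table.index[
        coupling_table["coupling_class"] != "unchanged"
    ]
    buffering = cp.buffering_counts(fold_changes, deg_union if len(deg_union) else None)
    sweep = None
    if config.threshold_grid:
        sweep = cp.threshold_sweep(
            deg_tables["transcriptome"], deg_tables["translatome"], config.threshold_grid
        )

    # -- ontology stages -------------------------------------------------
    graph = catalog = slim = None
    if config.toy_ontology is not None:
        graph, catalog, slim = syn.generate_toy_ontology(
            genes=list(pes.features), **config.toy_ontology
        )
    elif config.ontology_obo is not None:
        graph = sem.parse_obo(config.ontology_obo)
        if config.annotations:
            catalog = en.AnnotationCatalog.from_tsv(config.annotations)
        if config.slim_map:
            slim_df = pd.read_csv(config.slim_map, sep="\t", dtype=str)
            slim = dict(zip(slim_df.iloc[:, 0], slim_df.iloc[:, 1]))

    enrichment_block: dict[str, Any] | None = None
    enriched_lists: dict[str, list[str]] = {}
    enrich_tables = {}
    if catalog is not None:
        universe = set(pes.features)
        for level in prep.LEVELS:
            res = en.fisher_enrichment(deg_sets[level], universe, catalog)
            enrich_tables[level] = res
            enriched_lists[level] = sorted(en.enriched_terms(res))
        enrichment_block = {
            "transcriptome_enriched_terms": enriched_lists["transcriptome"],
            "translatome_enriched_terms": enriched_lists["translatome"],
            "overlap": en.term_overlap_summary(
                enriched_lists["transcriptome"], enriched_lists["translatome"]
            ),
        }
    else:
        skipped.append("enrichment: no annotation catalog configured")

    semantics_block = None
    if graph is not None and enriched_lists:
        spec = sem.semantic_specificity(
            enriched_lists["translatome"], enriched_lists["transcriptome"], graph
        )
        semantics_block = {
            "m": spec.m,
            "n": spec.n,
            "translatome_specificity": spec.translatome_specificity,
            "transcriptome_specificity": spec.transcriptome_specificity,
            "reason": spec.reason,
        }
        if not spec.defined:
            skipped.append(f"semantic specificity undefined: {spec.reason}")
    else:
        skipped.append("semantics: no ontology configured or no enrichment run")

    # -- independence ----------------------------------------------------
    indep = ind.independence_tests(
        deg_sets["transcriptome"],
        deg_sets["translatome"],
        pes.features,
        n_iter=config.n_bootstrap,
        seed=config.seed + 100,
    )

    report: dict[str, Any] = {
        "config": {
            "deg_method": config.deg_method,
            "deg_threshold": config.deg_threshold,
            "seed": config.seed,
            "n_permutations": config.n_permutations,
            "n_bootstrap": config.n_bootstrap,
            "notes": notes,
        },
        "prep": {
            "n_features_in": n_features_in,
            "n_low_signal_removed": n_removed,
            "n_genes": int(len(pes.features)),
        },
        "degs": {
            level: {
                "n_significant": int(len(deg_sets[level])),
                "n_up": int(
                    (deg_tables[level].loc[list(deg_sets[level]), "direction"] == "up").sum()
                ),
                "n_down": int(
                    (deg_tables[level].loc[list(deg_sets[level]), "direction"] == "down").sum()
                ),
            }
            for level in prep.LEVELS
        },
        "coupling": {
            "counts": coupling_summary["counts"],
            "n_degs": coupling_summary["n_degs"],
            "percent_uncoupled": coupling_summary["percent_uncoupled"],
            "percent": coupling_summary["percent"],
            "translatome_to_transcriptome_only_ratio": (
                None
                if coupling_summary["translatome_to_transcriptome_only_ratio"]
                in (None, float("inf"))
                else coupling_summary["translatome_to_transcriptome_only_ratio"]
            ),
        },
        "buffering": buffering,
        "enrichment": enrichment_block,
        "semantics": semantics_block,
        "independence": indep.to_dict(),
        "skipped": skipped,
    }
    if truth is not None:
        planted = truth.table["class"].value_counts().to_dict()
        report["planted"] = {c: int(planted.get(c, 0)) for c in syn.COUPLING_CLASSES}

    validate_report(report)

    if out:
        for level in prep.LEVELS:
            deg_tables[level].to_csv(out / f"deg_{level}.tsv", sep="\t", index_label="gene_id")
        coupling_table.to_csv(out / "coupling.tsv", sep="\t", index_label="gene_id")
        for level, res in enrich_tables.items():
            res.to_csv(out / f"enrichment_{level}.tsv", sep="\t")
        if sweep is not None:
            sweep.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
        if truth is not None:
            truth.to_tsv(out / "truth.tsv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report


def load_report_schema() -> dict:
    with open(_SCHEMA_PATH) as fh:
        return json.load(fh)


def validate_report(report: Mapping[str, Any]) -> None:
    """Check a report against the published schema (structural subset)."""
    try:
        schema = load_report_schema()
    except FileNotFoundError:  # installed without the repo checkout
        logger.warning("report schema file not found; skipping validation")
        return
    validate_schema(dict(report), schema)


def multi_dataset_report(
    reports: Mapping[str, Mapping[str, Any]],
    graph: sem.OntologyGraph | None = None,
    slim_map: Mapping[str, str] | None = None,
) -> dict:
    """Cross-dataset roll-up of per-dataset pipeline reports.

    Produces the per-dataset uncoupling table, counts of datasets where
    uncoupled DEGs outnumber coupled ones, independence-test outcome
    counts at p < 0.01 and, when an ontology graph is supplied and the
    reports carry enriched term lists, the cross-dataset reference
    distribution of one-sided specificities plus GOslim roll-up degrees.
    """
    if len(reports) < 2:
        raise PipelineError("multi_dataset_report needs >= 2 reports")
    rows = []
    for name, rep in reports.items():
        cpl = rep["coupling"]
        indep = rep.get("independence") or {}
        pu = cpl.get("percent_uncoupled")
        rows.append(
            {
                "dataset": name,
                "n_degs": cpl["n_degs"],
                "percent_uncoupled": pu,
                "uncoupled_majority": None if pu is None else bool(pu > 50.0),
                "lrt_p": indep.get("lrt_p"),
                "overlap_p": indep.get("overlap_p"),
                "mi_p": indep.get("mi_p"),
                "mi_midrange_position": indep.get("mi_midrange_position"),
            }
        )
    table = pd.DataFrame(rows).set_index("dataset")
    summary: dict[str, Any] = {
        "per_dataset": table,
        "n_datasets": len(reports),
        "n_uncoupled_majority": int(table["uncoupled_majority"].fillna(False).sum()),
        "n_lrt_significant": int((table["lrt_p"].astype(float) < 0.01).sum()),
        "n_overlap_significant": int((table["overlap_p"].astype(float) < 0.01).sum()),
        "n_mi_significant": int((table["mi_p"].astype(float) < 0.01).sum()),
    }
    term_lists = {
        name: rep.get("enrichment") or {} for name, rep in reports.items()
    }
    tc_lists = {
        name: block.get("transcriptome_enriched_terms", [])
        for name, block in term_lists.items()
    }
    if graph is not None and sum(bool(v) for v in tc_lists.values()) >= 3:
        observed = {
            name: (rep.get("semantics") or {}).get("transcriptome_specificity")
            for name, rep in reports.items()
        }
        summary["reference_distribution"] = sem.reference_distribution(
            tc_lists, graph, observed={k: v for k, v in observed.items() if v is not None}
        )
        per_dataset_terms = {
            name: (
                block.get("transcriptome_enriched_terms", []),
                block.get("translatome_enriched_terms", []),
            )
            for name, block in term_lists.items()
            if block
        }
        if per_dataset_terms:
            summary["goslim"] = sem.goslim_specificity_degrees(per_dataset_terms, slim_map)
    return summary
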