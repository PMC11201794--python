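"""End-to-end orchestration: simulate → preprocess → DE → meta → score → enrich.

Each stage writes plain TSV outputs plus a JSON run manifest recording the
seed, thresholds and per-stage row counts, so a run is reproducible from
its manifest alone.  Given identical inputs and seed the pipeline is
idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, io
from .cohort_de import count_shared_degs, run_de
from .enrichment import (
    PathwayCatalog,
    cross_cohort_pathway_counts,
    hypergeom_ora,
    rollup_ancestors,
)
from .meta import (
    GeneEffect,
    compute_effects,
    forest_data,
    geometric_mean_score,
    run_meta,
    select_signature,
)
from .preprocess import CohortDataset, preprocess_cohort
from .synthetic import SyntheticConfig, generate_multicohort, make_toy_catalog, write_fixture

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a full run needs.

    With ``input_dir=None`` the synthetic generator provides the cohorts
    (the default fixture: 5 cohorts of 4+4 samples, 1000 genes, 50 planted
    up-regulated genes at delta=2) together with a toy pathway catalog whose
    first set is the planted signature.  With ``input_dir`` set, cohorts
    are read from ``*_expression.tsv`` / ``*_phenotype.tsv`` pairs plus
    ``probe_map.tsv``; a GMT and hierarchy may be supplied via ``gmt_path``
    / ``hierarchy_path``.
    """

    out_dir: str | Path = "pipeline_out"
    seed: int = 0
    input_dir: str | Path | None = None
    gmt_path: str | Path | None = None
    hierarchy_path: str | Path | None = None
    synthetic: SyntheticConfig | None = None
    es_min: float = 1.0
    fdr_max: float = 0.05
    min_cohorts: int = 5
    shared_min_cohorts: int = 4
    deg_mode: str = "auto"
    offset: float = 1.0
    n_forest_genes: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must lie in (0, 1]")
        if self.es_min < 0:
            raise ValueError("es_min must be non-negative")
        if self.min_cohorts < 1:
            raise ValueError("min_cohorts must be >= 1")
        if self.deg_mode not in ("auto", "stringent", "relaxed", "fc_only"):
            raise ValueError(f"unknown deg_mode {self.deg_mode!r}")


def _load_input_cohorts(input_dir: Path) -> tuple[list[CohortDataset], dict[str, str]]:
    expr_files = sorted(input_dir.glob("*_expression.tsv"))
    if not expr_files:
        raise FileNotFoundError(f"no *_expression.tsv files in {input_dir}")
    cohorts = []
    for expr in expr_files:
        cid = expr.name.replace("_expression.tsv", "")
        cohorts.append(io.load_cohort(expr, input_dir / f"{cid}_phenotype.tsv", cid))
    probe_map = io.read_probe_map(input_dir / "probe_map.tsv")
    return cohorts, probe_map


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run manifest.

    Stage order: simulate (or load) → preprocess → de → meta → score →
    enrich.  Any stage error aborts the run with the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "es_min": config.es_min,
            "fdr_max": config.fdr_max,
            "min_cohorts": config.min_cohorts,
            "shared_min_cohorts": config.shared_min_cohorts,
            "deg_mode": config.deg_mode,
        },
        "stages": {},
        "files": {},
    }

    # ---- simulate / load -------------------------------------------------
    stage = "simulate" if config.input_dir is None else "load"
    try:
        catalog: PathwayCatalog | None = None
        if config.input_dir is None:
            syn = config.synthetic or SyntheticConfig(seed=config.seed)
            sim = generate_multicohort(syn)
            fixture_dir = out / "fixture"
            files = write_fixture(sim, fixture_dir, create=True)
            manifest["files"].update(files)
            cohorts, probe_map = sim.cohorts, sim.probe_map
            gene_ids = sorted({g for g in probe_map.values()})
            catalog = make_toy_catalog(
                sorted(sim.truth.signature_genes), gene_ids, seed=syn.seed
            )
            io.write_gmt(catalog, out / "toy_catalog.gmt")
            io.write_hierarchy(catalog.hierarchy, out / "toy_hierarchy.tsv")
            manifest["files"]["gmt"] = str(out / "toy_catalog.gmt")
        else:
            cohorts, probe_map = _load_input_cohorts(Path(config.input_dir))
            if config.gmt_path is not None:
                catalog = io.read_gmt(config.gmt_path)
                if config.hierarchy_path is not None:
                    catalog.hierarchy = io.read_hierarchy(config.hierarchy_path)
        manifest["stages"][stage] = {
            "n_cohorts": len(cohorts),
            "n_probes": [c.matrix.data.shape[0] for c in cohorts],
        }
        logger.info("%s: %d cohorts", stage, len(cohorts))
    except Exception as exc:  # noqa: BLE001 — stage accounting
        raise StageError(stage, exc) from exc

    # ---- preprocess ------------------------------------------------------
    try:
        processed = [
            preprocess_cohort(c, probe_map=probe_map, offset=config.offset)
            for c in cohorts
        ]
        for cohort in processed:
            io.write_expression(
                cohort.matrix, out / f"{cohort.cohort_id}_preprocessed.tsv"
            )
        manifest["stages"]["preprocess"] = {
            "n_genes": [c.matrix.data.shape[0] for c in processed]
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("preprocess", exc) from exc

    # ---- per-cohort differential expression -----------------------------
    try:
        de_tables: dict[str, pd.DataFrame] = {}
        for cohort in processed:
            table = run_de(cohort, mode=config.deg_mode)
            de_tables[cohort.cohort_id] = table
            io.write_table(
                table.reset_index(), out / f"{cohort.cohort_id}_de.tsv"
            )
        shared = count_shared_degs(
            de_tables, min_cohorts=min(config.shared_min_cohorts, len(de_tables))
        )
        io.write_table(shared, out / "shared_degs.tsv")
        manifest["stages"]["de"] = {
            "n_degs": {
                cid: int((t["deg_call"] != "none").sum()) for cid, t in de_tables.items()
            },
            "n_shared": len(shared),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("de", exc) from exc

    # ---- meta-analysis ---------------------------------------------------
    try:
        eligible = [
            c for c in processed
            if len(c.samples_in("control")) >= 2 and len(c.samples_in("treated")) >= 2
        ]
        eligible_ids = {c.cohort_id for c in eligible}
        held_out = [c for c in processed if c.cohort_id not in eligible_ids]
        if config.min_cohorts > len(eligible):
            raise ValueError(
                f"min_cohorts={config.min_cohorts} exceeds the "
                f"{len(eligible)} cohorts eligible for meta-analysis"
            )
        meta = run_meta(eligible, min_cohorts_measured=2)
        io.write_table(meta, out / "meta.tsv")
        signature = select_signature(
            meta, es_min=config.es_min, fdr_max=config.fdr_max,
            min_cohorts=config.min_cohorts,
        )
        io.write_table(signature.table, out / "signature.tsv")

        forest_dir = out / "forests"
        forest_dir.mkdir(exist_ok=True)
        effects_by_cohort = {c.cohort_id: compute_effects(c) for c in eligible}
        for gene in signature.genes[: config.n_forest_genes]:
            effects = [
                GeneEffect(gene=gene, cohort=cid, g=float(eff.loc[gene, "g"]),
                           var_g=float(eff.loc[gene, "var_g"]),
                           n_t=int(eff.loc[gene, "n_t"]), n_c=int(eff.loc[gene, "n_c"]))
                for cid, eff in effects_by_cohort.items()
                if gene in eff.index
            ]
            pooled = meta.loc[meta["gene"] == gene].iloc[0].to_dict()
            io.write_table(forest_data(gene, effects, pooled),
                           forest_dir / f"{gene}_forest.tsv")
        manifest["stages"]["meta"] = {
            "n_eligible_cohorts": len(eligible),
            "n_genes_tested": len(meta),
            "n_signature": len(signature),
        }
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("meta", exc) from exc

    # ---- signature scoring ----------------------------------------------
    try:
        score_rows = []
        if len(signature):
            for cohort in processed:
                frame = geometric_mean_score(cohort.matrix, signature, cohort.groups)
                means = frame.attrs["group_means"]
                score_rows.append(
                    {
                        "cohort_id": cohort.cohort_id,
                        "held_out": cohort.cohort_id not in eligible_ids,
                        "mean_score_control": means.get("control"),
                        "mean_score_treated": means.get("treated"),
                        "score_difference": means.get("treated", float("nan"))
                        - means.get("control", float("nan")),
                        "n_signature_genes_found": frame.attrs["n_genes_found"],
                    }
                )
        scores = pd.DataFrame(
            score_rows,
            columns=["cohort_id", "held_out", "mean_score_control",
                     "mean_score_treated", "score_difference",
                     "n_signature_genes_found"],
        )
        io.write_table(scores, out / "signature_scores.tsv")
        manifest["stages"]["score"] = {"n_cohorts_scored": len(scores)}
    except Exception as exc:  # noqa: BLE001
        raise StageError("score", exc) from exc

    # ---- enrichment ------------------------------------------------------
    try:
        if catalog is not None and len(signature):
            universe = sorted(
                {str(g) for c in processed for g in c.matrix.feature_ids}
            )
            ora = hypergeom_ora(signature.genes, catalog, universe)
            io.write_table(ora.drop(columns="overlap_genes"), out / "enrichment.tsv")
            if catalog.hierarchy is not None and len(ora):
                io.write_table(rollup_ancestors(ora, catalog), out / "ancestor_rollup.tsv")
            per_cohort = []
            for cid, table in de_tables.items():
                degs = list(table.index[table["deg_call"] != "none"])
                if degs:
                    per_cohort.append((cid, hypergeom_ora(degs, catalog, universe)))
            if len(per_cohort) >= 2:
                io.write_table(
                    cross_cohort_pathway_counts(per_cohort, fdr_max=config.fdr_max),
                    out / "pathway_cohort_counts.tsv",
                )
            manifest["stages"]["enrich"] = {"n_pathways_tested": len(ora)}
        else:
            manifest["stages"]["enrich"] = {"skipped": True}
    except Exception as exc:  # noqa: BLE001
        raise StageError("enrich", exc) from exc

    io.write_manifest(manifest, out / "run_manifest.json")
    manifest["files"]["manifest"] = str(out / "run_manifest.json")
    return manifest
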