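"""End-to-end orchestration: arrays -> ratios/p-values -> TFS groups -> enrichment.

A run is described by a config (YAML) naming either a simulation design or a
manifest of hybridization files, the call thresholds, the error-model
parameters, and optional gene-set collections.  The run writes
comparison_results.tsv, tfs_assignments.tsv, class_summary.tsv,
enrichment.tsv and run_report.json to the output directory; the report
records parameters, the seed, and per-stage counts, and is identical for
identical config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd
import yaml

from . import io as aio
from . import synthetic
from .enrichment import DEFAULT_MIN_GENES, DEFAULT_P_CUT, run_collections
from .normalize import ErrorModelParams, exclusion_reasons, lowess_normalize, combine_replicates
from .tfs import (
    N_COMPARISONS,
    Thresholds,
    apparent_fdr,
    classify_probes,
    collapse_redundant,
    expected_false_positives,
    summarize_classes,
)

logger = logging.getLogger("tfsarray")


class ConfigError(ValueError):
    """Aggregated configuration problems (one message per problem)."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid config:\n  - " + "\n  - ".join(problems))


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    simulation: synthetic.SimulationDesign | None = None
    manifest: Path | None = None
    annotation: Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    error_model: ErrorModelParams = field(default_factory=ErrorModelParams)
    enrichment_p_cut: float = DEFAULT_P_CUT
    enrichment_min_genes: int = DEFAULT_MIN_GENES
    collections: dict[str, Path] = field(default_factory=dict)
    out_dir: Path = Path("./results")
    seed: int = 0
    overwrite: bool = False

    def validate(self) -> None:
        problems: list[str] = []
        if (self.simulation is None) == (self.manifest is None):
            problems.append("exactly one of 'simulation' or 'manifest' must be given")
        if self.manifest is not None and not Path(self.manifest).exists():
            problems.append(f"manifest file not found: {self.manifest}")
        if self.annotation is not None and not Path(self.annotation).exists():
            problems.append(f"annotation file not found: {self.annotation}")
        for name, path in self.collections.items():
            if not Path(path).exists():
                problems.append(f"collection {name!r}: GMT file not found: {path}")
        if self.simulation is not None:
            try:
                self.simulation.validate()
            except ValueError as exc:
                problems.append(str(exc))
        if problems:
            raise ConfigError(problems)


def _build_design(sim: Mapping, seed: int) -> tuple[synthetic.SimulationDesign | None, list[str]]:
    problems: list[str] = []
    sim = dict(sim)
    n_planted = sim.pop("n_planted", None)
    effect = sim.pop("effect", 2.0)
    sim.setdefault("seed", seed)
    valid = {f.name for f in dataclasses.fields(synthetic.SimulationDesign)}
    unknown = set(sim) - valid
    if unknown:
        problems.append(f"unknown simulation keys: {sorted(unknown)}")
        return None, problems
    try:
        if n_planted is not None and "planted_patterns" not in sim:
            sim["planted_patterns"] = synthetic.random_planted_patterns(
                sim.get("n_genes", 2000), n_planted, effect=effect, seed=sim["seed"]
            )
        design = synthetic.SimulationDesign(**sim)
    except (TypeError, ValueError) as exc:
        problems.append(str(exc))
        return None, problems
    return design, problems


def validate_config(path) -> PipelineConfig:
    """Parse and validate a YAML config, reporting all problems at once."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(["config must be a YAML mapping"])
    problems: list[str] = []
    base = Path(path).parent

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    seed = int(doc.get("seed", 0))
    design = None
    if "simulation" in doc:
        design, pb = _build_design(doc["simulation"] or {}, seed)
        problems.extend(pb)

    thresholds = Thresholds()
    try:
        thresholds = Thresholds(**(doc.get("thresholds") or {}))
    except (TypeError, ValueError) as exc:
        problems.append(f"thresholds: {exc}")
    error_model = ErrorModelParams()
    try:
        error_model = ErrorModelParams(**(doc.get("error_model") or {}))
    except (TypeError, ValueError) as exc:
        problems.append(f"error_model: {exc}")

    enr = doc.get("enrichment") or {}
    collections = {
        str(name): _resolve(p) for name, p in (enr.get("collections") or {}).items()
    }

    cfg = PipelineConfig(
        simulation=design,
        manifest=_resolve(doc["manifest"]) if doc.get("manifest") else None,
        annotation=_resolve(doc["annotation"]) if doc.get("annotation") else None,
        thresholds=thresholds,
        error_model=error_model,
        enrichment_p_cut=float(enr.get("p_cut", DEFAULT_P_CUT)),
        enrichment_min_genes=int(enr.get("min_genes", DEFAULT_MIN_GENES)),
        collections=collections,
        out_dir=_resolve(doc.get("out_dir", "./results")),
        seed=seed,
        overwrite=bool(doc.get("overwrite", False)),
    )
    try:
        cfg.validate()
    except ConfigError as exc:
        problems.extend(exc.problems)
    if problems:
        raise ConfigError(sorted(set(problems), key=problems.index))
    return cfg


class PipelineResult(NamedTuple):
    report: dict
    tables: dict[str, pd.DataFrame]


def _load_hybridizations(cfg: PipelineConfig):
    if cfg.simulation is not None:
        logger.info("stage simulate: %d genes", cfg.simulation.n_genes)
        sim = synthetic.simulate_experiment(cfg.simulation)
        return sim.hybridizations, sim.annotation, sim.truth
    files = aio.read_manifest(cfg.manifest)
    hybs = {k: [aio.read_hybridization(f) for f in v] for k, v in files.items()}
    if cfg.annotation is not None:
        ann = aio.read_probe_annotation(cfg.annotation)
        gene_of = dict(zip(ann["probe_id"], ann["gene_id"]))
        for tables in hybs.values():
            for t in tables:
                t["gene_id"] = t["probe_id"].map(gene_of).fillna("")
    else:
        any_table = next(iter(hybs.values()))[0]
        ann = any_table[["probe_id", "gene_id"]].copy()
    return hybs, ann, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run simulate/load -> normalize -> classify -> enrich -> report."""
    config.validate()
    th, em = config.thresholds, config.error_model

    stage = "load"
    try:
        hybs, annotation, truth = _load_hybridizations(config)

        stage = "normalize"
        comparison_results: dict[int, pd.DataFrame] = {}
        probes_in = probes_excluded = 0
        for comp in range(1, N_COMPARISONS + 1):
            normalized = []
            for hyb in hybs[comp]:
                probes_in += len(hyb)
                probes_excluded += int((exclusion_reasons(hyb) != "ok").sum())
                normalized.append(lowess_normalize(hyb, params=em))
            comparison_results[comp] = combine_replicates(normalized, em)
            logger.info(
                "stage normalize: comparison %d, %d probes combined",
                comp, len(comparison_results[comp]),
            )

        stage = "classify"
        per_probe = classify_probes(comparison_results, th)
        n_probes_analyzed = len(per_probe)
        sig_calls = sum(
            int((per_probe[f"call_{k}"] != 0).sum()) for k in range(1, 5)
        )
        n_sig_any = int((per_probe["tfs"] != "0.0000").sum())
        per_gene = collapse_redundant(per_probe)
        summary = summarize_classes(per_gene)
        expected = expected_false_positives(n_probes_analyzed, th.p_max)
        expected_among_selected = expected_false_positives(n_sig_any, th.p_max)
        fdr = (
            apparent_fdr(expected_among_selected, sig_calls) if sig_calls > 0 else 0.0
        )

        stage = "enrich"
        genes_of_interest = per_gene[per_gene["tfs"] != "0.0000"]
        groups = {
            code: set(sub["gene_id"])
            for code, sub in genes_of_interest.groupby("tfs", sort=True)
        }
        universe = sorted(set(per_gene["gene_id"]))
        enrichment_tables = []
        enriched_sets = {}
        if config.collections:
            collections = {
                name: aio.read_gmt(p) for name, p in sorted(config.collections.items())
            }
            results = run_collections(
                groups, collections, universe,
                p_cut=config.enrichment_p_cut,
                min_genes=config.enrichment_min_genes,
            )
            for name, res in results.items():
                rec = res["records"].copy()
                rec.insert(0, "collection", name)
                enrichment_tables.append(rec)
                enriched_sets[name] = {
                    "kept_sets": len(res["selection"].kept_sets),
                    "kept_groups": len(res["selection"].kept_groups),
                }
        enrichment_df = (
            pd.concat(enrichment_tables, ignore_index=True)
            if enrichment_tables
            else pd.DataFrame(
                columns=["collection", "tfs_group", "set_name", "k", "m", "K", "N", "score", "p"]
            )
        )

        stage = "report"
        tables = {
            "comparison_results": _wide_results(comparison_results),
            "tfs_assignments": per_gene.drop(
                columns=[c for c in ("min_p",) if c in per_gene.columns]
            ),
            "class_summary": summary.by_group,
            "enrichment": enrichment_df,
        }
        report = {
            "package": "tfsarray",
            "version": _version(),
            "seed": config.seed,
            "parameters": {
                "thresholds": dataclasses.asdict(th),
                "error_model": dataclasses.asdict(em),
                "enrichment": {
                    "p_cut": config.enrichment_p_cut,
                    "min_genes": config.enrichment_min_genes,
                },
            },
            "counts": {
                "probes_in": probes_in,
                "probes_excluded": probes_excluded,
                "probes_analyzed_per_array": probes_in - probes_excluded,
                "n_probes_with_result": n_probes_analyzed,
                "n_significant_calls": sig_calls,
                "n_probes_significant_any": n_sig_any,
                "expected_by_chance": expected,
                "apparent_fdr_percent": fdr,
                "n_genes": len(per_gene["gene_id"].unique()),
                "genes_of_interest": summary.n_of_interest,
                "classified": summary.n_classified,
                "percent_classified": summary.percent_classified,
                "other": summary.n_other,
                "per_class": {
                    row["tfs_class"]: int(row["n_genes"])
                    for _, row in summary.by_class.iterrows()
                },
                "enriched": enriched_sets,
            },
        }

        stage = "write"
        out = Path(config.out_dir)
        aio.write_results(tables, out, overwrite=config.overwrite)
        if truth is not None:
            truth_path = out / "truth.tsv"
            if truth_path.exists() and not config.overwrite:
                raise FileExistsError(f"{truth_path} exists")
            synthetic.write_truth(truth, truth_path)
            aio.write_probe_annotation(annotation, out / "probe_annotation.tsv")
        with open(out / "run_report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    return PipelineResult(report, tables)


def _wide_results(comparison_results: Mapping[int, pd.DataFrame]) -> pd.DataFrame:
    wide = None
    for k in range(1, N_COMPARISONS + 1):
        t = comparison_results[k].rename(
            columns={
                c: f"{c}_{k}"
                for c in ("log2_ratio", "se", "p", "fold", "n_used")
            }
        )
        if wide is None:
            wide = t
        else:
            other = t.drop(columns=["gene_id"])
            wide = wide.merge(other, on="probe_id", how="outer")
    assert wide is not None
    return wide.sort_values("probe_id", kind="mergesort").reset_index(drop=True)


def _version() -> str:
    from . import __version__

    return __version__
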