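"""End-to-end orchestration: filter -> fish -> disease map -> enrich -> networks.

One configured run consumes the full input bundle (compound SDF + descriptor
table + formula table, target-annotated ligand library, disease protein list,
annotation GMT) and emits intermediate TSVs plus a machine-readable report.
Reruns on identical inputs are bit-identical; a stage failure aborts with the
stage name and leaves a FAILED marker next to whatever partial outputs exist.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .admet import AdmetThresholds, apply_admet_rules, filter_summary, write_filter_table
from .chem import read_descriptor_table, read_formula_table, read_sdf
from .enrichment import (
    AnnotationDB,
    cluster_terms,
    hypergeom_enrich,
    module_annotation,
    write_enrichment_tsv,
    write_modules_tsv,
)
from .errors import StageError
from .fishing import DiseaseGeneSet, LigandLibrary, herb_target_overlap, map_to_disease, predict_target_map
from .network import build_ct_network, build_tf_network, degree_stats, mean_modules_per_target

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    compounds_sdf: str
    descriptors_tsv: str
    formula_tsv: str
    library_sdf: str
    library_annot_tsv: str
    disease_file: str
    annotations_gmt: str
    out_dir: str
    background_txt: str | None = None
    threshold: float = 0.8
    admet: AdmetThresholds = field(default_factory=AdmetThresholds)
    p_cutoff: float = 0.05
    jaccard_threshold: float = 0.5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        admet = AdmetThresholds(**raw.pop("admet", {}))
        return cls(admet=admet, **raw)

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    config: dict[str, Any]
    version: str
    n_compounds_input: int = 0
    n_compounds_retained: int = 0
    per_herb_retained: dict[str, int] = field(default_factory=dict)
    n_predicted_targets: int = 0
    n_no_hit_compounds: int = 0
    n_disease_targets: int = 0
    disease_percent: float = 0.0
    n_compounds_with_disease_target: int = 0
    venn: dict[str, Any] | None = None
    ct_network: dict[str, Any] | None = None
    tf_network: dict[str, Any] | None = None
    n_enriched_terms: int = 0
    n_functional_modules: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"herbnet pipeline report (v{self.version})",
            f"compounds: {self.n_compounds_input} in, {self.n_compounds_retained} past ADME rules",
            f"predicted targets: {self.n_predicted_targets} "
            f"({self.n_no_hit_compounds} compounds without hits)",
            f"disease targets: {self.n_disease_targets} ({self.disease_percent}%) "
            f"over {self.n_compounds_with_disease_target} compounds",
        ]
        if self.venn:
            lines.append(
                f"herb overlap: union {self.venn['union_size']}, "
                f"common to all {self.venn['intersection_size']}"
            )
        if self.ct_network:
            ct = self.ct_network
            lines.append(
                f"C-T network: {ct['n_nodes']} nodes, {ct['n_ct_edges']} compound-target edges, "
                f"mean degree {ct['mean_degree_per_compound']}/compound, "
                f"{ct['mean_degree_per_target']}/target"
            )
        lines.append(
            f"enrichment: {self.n_enriched_terms} terms, {self.n_functional_modules} modules"
        )
        if self.tf_network:
            tf = self.tf_network
            lines.append(
                f"T-F network: {tf['n_pairs']} pairs, {tf['n_targets']} targets, "
                f"{tf['n_modules']} modules, {tf['mean_modules_per_target']} modules/target"
            )
        return "\n".join(lines) + "\n"


def _stage(name: str, out_dir: Path):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out_dir / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise StageError(name, exc) from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order and write intermediate TSVs plus the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    report = RunReport(config=config.echo(), version=__version__)

    with _stage("load", out):
        compounds = read_sdf(config.compounds_sdf)
        descriptors = read_descriptor_table(config.descriptors_tsv)
        formula = read_formula_table(config.formula_tsv)
        report.n_compounds_input = len(compounds)

    with _stage("filter", out):
        result = apply_admet_rules(descriptors, config.admet)
        write_filter_table(result, formula, out / "filtered.tsv")
        summary = filter_summary(result, formula)
        summary.to_csv(out / "filter_summary.tsv", sep="\t")
        retained_ids = set(result.retained)
        retained = [m for m in compounds if m.id in retained_ids]
        report.n_compounds_retained = len(retained)
        report.per_herb_retained = {
            h: int(summary.loc[h, "n_retained"]) for h in formula.herb_codes
        }

    with _stage("fishing", out):
        library = LigandLibrary.from_files(config.library_sdf, config.library_annot_tsv)
        ctmap = predict_target_map(retained, library, threshold=config.threshold)
        ctmap.write_tsv(out / "associations.tsv")
        (out / "no_hits.tsv").write_text("\n".join(ctmap.no_hits) + "\n")
        report.n_predicted_targets = len(ctmap.predicted_targets)
        report.n_no_hit_compounds = len(ctmap.no_hits)

    with _stage("disease_mapping", out):
        disease = DiseaseGeneSet.from_file(config.disease_file)
        disease_map, pct = map_to_disease(ctmap, disease)
        disease_map.write_tsv(out / "disease_associations.tsv")
        report.n_disease_targets = len(disease_map.predicted_targets)
        report.disease_percent = pct
        report.n_compounds_with_disease_target = len(disease_map.compound_ids)

    with _stage("herb_overlap", out):
        per_herb: dict[str, set[str]] = {}
        for c, t, _ in disease_map.associations:
            per_herb.setdefault(formula.herb_of(c), set()).add(t)
        if 2 <= len(per_herb) <= 6:
            venn = herb_target_overlap(per_herb)
            report.venn = {
                "union_size": venn.union_size,
                "intersection_size": venn.intersection_size,
                "set_sizes": dict(venn.set_sizes),
            }

    with _stage("enrichment", out):
        background = None
        if config.background_txt:
            background = [
                l.strip() for l in Path(config.background_txt).read_text().splitlines() if l.strip()
            ]
        db = AnnotationDB.from_gmt(config.annotations_gmt, background=background)
        query = disease_map.predicted_targets
        enriched, modules = [], []
        if query & db.background:
            enriched = hypergeom_enrich(query, db, p_cutoff=config.p_cutoff)
            if enriched:
                modules = cluster_terms(enriched, db, jaccard_threshold=config.jaccard_threshold)
        write_enrichment_tsv(enriched, out / "enrichment.tsv")
        write_modules_tsv(modules, out / "modules.tsv")
        report.n_enriched_terms = len(enriched)
        report.n_functional_modules = len(modules)

    with _stage("networks", out):
        ct_net = build_ct_network(formula, disease_map)
        ct_net.write_tables(out / "ct")
        if disease_map.associations:
            stats = degree_stats(ct_net, ("compound", "target"))
            report.ct_network = {
                "n_nodes": ct_net.n_nodes,
                "n_edges": ct_net.n_edges,
                "n_ct_edges": stats.n_edges,
                "class_counts": ct_net.class_counts(),
                "mean_degree_per_compound": stats.mean_degree["compound"],
                "mean_degree_per_target": stats.mean_degree["target"],
            }
        annot = module_annotation(modules, query) if modules else {}
        if annot:
            tf_net = build_tf_network(query, annot)
            tf_net.write_tables(out / "tf")
            report.tf_network = {
                "n_pairs": tf_net.n_edges,
                "n_targets": len(tf_net.nodes_of_class("target")),
                "n_modules": len(tf_net.nodes_of_class("function_module")),
                "mean_modules_per_target": mean_modules_per_target(tf_net),
            }

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.to_text())
    return report
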