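"""End-to-end orchestration: inputs -> gold standard -> model -> predictions
-> module discovery -> enrichment, with a machine-readable run report."""

from __future__ import annotations

import datetime as _dt
import glob
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from iiinet import data_io, enrichment, features, gold_standard, iii_model, module_discovery
from iiinet.data_io import canonical_pair
from iiinet.errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    catalog: str
    ppi: str
    ddi: str
    expr_dir: str
    localization: str
    annotation: str
    out_dir: str
    high_threshold: float = iii_model.DEFAULT_HIGH_THRESHOLD
    low_threshold: float = iii_model.DEFAULT_LOW_THRESHOLD
    min_module_size: int = 3
    max_module_size: int = 30
    min_density: float = 0.7
    alpha: float = enrichment.DEFAULT_ALPHA
    split_cutoff: str = "2012-01-01"
    ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.high_threshold < self.low_threshold:
            raise ConfigError("high_threshold must be >= low_threshold")
        if self.min_module_size > self.max_module_size:
            raise ConfigError("min_module_size must be <= max_module_size")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def candidate_pairs_from_ppi(ppi_records, catalog):
    """Isoform cross products of the distinct gene-level PPIs (the
    PPI-confirmation filter applied up front)."""
    gene_pairs = sorted({canonical_pair(r.gene_a, r.gene_b) for r in ppi_records})
    pairs = set()
    for ga, gb in gene_pairs:
        isos_a = catalog.isoforms_of_gene(ga)
        isos_b = catalog.isoforms_of_gene(gb)
        for ia in isos_a:
            for ib in isos_b:
                pairs.add(canonical_pair(ia, ib))
    return sorted(pairs), gene_pairs


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and write artifacts + report to out_dir.

    Returns the run report (also written as report.json).
    """
    os.makedirs(config.out_dir, exist_ok=True)
    report: dict = {"config": asdict(config), "counts": {}}
    counts = report["counts"]

    def stage(name):
        logger.info("stage: %s", name)

    stage("read inputs")
    catalog = data_io.read_isoform_catalog(config.catalog)
    ppi = data_io.read_ppi_table(config.ppi)
    ddi = data_io.read_ddi_table(config.ddi)
    expr_paths = sorted(glob.glob(os.path.join(config.expr_dir, "*.tsv")))
    if not expr_paths:
        raise ValidationError(f"no expression matrices found in {config.expr_dir}")
    datasets = [data_io.read_expression_matrix(p) for p in expr_paths]
    localization = data_io.read_localization(config.localization)
    annotation = data_io.read_annotation(config.annotation)
    data_io.validate_against_catalog(
        catalog, ppi=ppi, datasets=datasets, localization=localization,
        annotation=annotation,
    )
    counts["isoforms"] = len(catalog)
    counts["genes"] = len(catalog.genes)
    counts["ppi_records"] = len(ppi)
    counts["ddi_records"] = len(ddi)
    counts["datasets"] = len(datasets)

    stage("gold standard")
    cutoff = _dt.date.fromisoformat(config.split_cutoff)
    gold = gold_standard.build_gold_standard(ppi, catalog, localization, cutoff)
    counts["gsp"] = len(gold.positives)
    counts["gsp_train"] = len(gold.positives_train)
    counts["gsp_test"] = len(gold.positives_test)
    counts["gsn"] = len(gold.negatives)
    data_io.write_gold_standard(gold, os.path.join(config.out_dir, "gold_standard.tsv"))

    stage("fit model")
    train_pairs = sorted(gold.positives_train) + sorted(gold.negatives)
    train_labels = [1] * len(gold.positives_train) + [0] * len(gold.negatives)
    if not gold.positives_train or not gold.negatives:
        raise ValidationError(
            "training requires non-empty positive-train and negative sets"
        )
    train_features = features.build_feature_vectors(train_pairs, datasets, catalog, ddi)
    coeffs = iii_model.fit_logistic(train_features, train_labels, ridge=config.ridge)
    report["coefficients"] = {
        "alpha0": coeffs.alpha0,
        "alpha_corr": {
            ds.dataset_id: c for ds, c in zip(datasets, coeffs.alpha_corr)
        },
        "alpha_ddi": coeffs.alpha_ddi,
    }

    stage("evaluate on test split")
    if gold.positives_test and gold.negatives:
        test_pairs = sorted(gold.positives_test) + sorted(gold.negatives)
        test_labels = [1] * len(gold.positives_test) + [0] * len(gold.negatives)
        test_features = features.build_feature_vectors(
            test_pairs, datasets, catalog, ddi
        )
        ev = iii_model.evaluate_on_test(
            coeffs, test_features, test_labels,
            high_threshold=config.high_threshold,
            low_threshold=config.low_threshold,
        )
        report["evaluation"] = {
            "high": {"precision": ev.high_precision, "recall": ev.high_recall},
            "low": {"precision": ev.low_precision, "recall": ev.low_recall},
        }
    else:
        report["evaluation"] = None
        logger.warning("empty test split; skipping held-out evaluation")

    stage("predict")
    candidates, gene_pairs = candidate_pairs_from_ppi(ppi, catalog)
    counts["candidate_pairs"] = len(candidates)
    candidate_features = features.build_feature_vectors(
        candidates, datasets, catalog, ddi
    )
    predictions = iii_model.predict(
        candidate_features, coeffs, gene_pairs, catalog,
        high_threshold=config.high_threshold,
        low_threshold=config.low_threshold,
    )
    counts["predictions_high"] = sum(p.tier == iii_model.TIER_HIGH for p in predictions)
    counts["predictions_low"] = sum(p.tier == iii_model.TIER_LOW for p in predictions)
    counts["predictions_rescued"] = sum(
        p.tier == iii_model.TIER_RESCUED for p in predictions
    )
    counts["predictions_total"] = len(predictions)
    data_io.write_predictions(
        predictions,
        os.path.join(config.out_dir, "predictions.tsv"),
        [ds.dataset_id for ds in datasets],
    )

    stage("module discovery")
    network = module_discovery.IIINetwork.from_predictions(predictions)
    modules = module_discovery.discover_modules(
        network,
        min_size=config.min_module_size,
        max_size=config.max_module_size,
        min_density=config.min_density,
        seed=config.seed,
    )
    counts["network_nodes"] = len(network.nodes)
    counts["network_edges"] = len(network.edges)
    counts["modules"] = len(modules)
    counts["mean_module_size"] = (
        sum(len(m.members) for m in modules) / len(modules) if modules else 0.0
    )

    stage("enrichment")
    universe = sorted(network.nodes)
    enrichment_results = []
    top_terms: dict[str, list[str]] = {}
    if universe:
        for mod in modules:
            results = enrichment.enrich_module(mod, annotation, universe)
            enrichment_results.extend(results)
            top_terms[mod.module_id] = [
                r.term_id for r in results if r.adjusted_p < config.alpha
            ][:5]
    enrichment.write_enrichment(
        enrichment_results, os.path.join(config.out_dir, "enrichment.tsv")
    )
    data_io.write_modules(
        modules, os.path.join(config.out_dir, "modules.tsv"), top_terms
    )
    rates: dict = {}
    if modules and universe:
        random_modules = module_discovery.randomize_modules(
            modules, universe, seed=config.seed, network=network
        )
        for ns in data_io.NAMESPACES:
            rates[ns] = {
                "discovered": enrichment.enrichment_rate(
                    modules, annotation, universe, alpha=config.alpha, namespace=ns
                ),
                "randomized": enrichment.enrichment_rate(
                    random_modules, annotation, universe, alpha=config.alpha, namespace=ns
                ),
            }
    report["enrichment_rates"] = rates

    report_path = os.path.join(config.out_dir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("report written to %s", report_path)
    return report
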