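"""Synthetic input worlds with planted ground truth.

A world contains all six pipeline inputs (catalog, PPIs, DDIs, expression
matrices, localization, annotations) plus the planted truth: which isoform
pairs truly interact, and which dense modules were planted.

Generation model
----------------
* Gene-level PPIs are drawn first; true isoform-isoform interactions (IIIs)
  exist only within PPIs, matching the candidate universe of the predictor.
* Planted modules are groups of isoforms (one per gene) whose genes are
  fully connected by PPIs and whose isoform pairs are all true IIIs.
* Co-expression: isoforms of a true-III connected component share a latent
  factor per dataset with loading chosen so each within-component pair has
  expected |Pearson r| equal to the configured strength; loadings carry
  random signs, so the absolute value is what carries signal.  Matrices
  are shifted per row to be non-negative, which preserves correlations.
* DDIs: each true III gets, with configured probability, a supporting
  domain pair at a confidence drawn from the configured mix, on top of
  random background DDIs.
* Localization and annotations are sampled so the gold standard and the
  enrichment analysis are exercised: membrane/nucleus labels by priors,
  one coherent GO term and one pathway term per planted module, plus
  random background terms.

All randomness flows from one seeded generator; equal seeds give
byte-identical files.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from iiinet.data_io import (
    AnnotationMap,
    DDIRecord,
    ExpressionDataset,
    Isoform,
    IsoformCatalog,
    LocalizationMap,
    PPIRecord,
    Pair,
    canonical_pair,
    write_annotation,
    write_catalog,
    write_ddi_table,
    write_expression_matrix,
    write_localization,
    write_ppi_table,
)
from iiinet.errors import ConfigError
from iiinet.features import PairFeatureVector
from iiinet.iii_model import CoefficientVector, _sigmoid


@dataclass
class SyntheticWorldConfig:
    seed: int
    n_genes: int = 200
    #: categorical distribution of isoforms per gene
    isoform_counts: tuple[int, ...] = (1, 2, 3)
    isoform_count_probs: tuple[float, ...] = (0.35, 0.45, 0.20)
    n_domains: int = 200
    max_domains_per_isoform: int = 3
    n_background_ddis: int = 20
    ddi_true_rate: float = 0.8
    ddi_confidence_mix: tuple[float, float, float] = (0.5, 0.3, 0.2)  # high/med/low
    n_ppis: int = 200
    true_iii_rate: float = 0.35
    isoform_spec_rate: float = 0.3
    n_datasets: int = 5
    samples_per_dataset: int = 60
    corr_strength_true: float = 0.8
    corr_strength_false: float = 0.0
    dataset_presence_rate: float = 0.95
    p_membrane: float = 0.10
    p_nucleus: float = 0.30
    n_background_terms: int = 30
    annotation_coherence: float = 0.9
    n_planted_modules: int = 4
    planted_module_size: int = 5
    date_start: _dt.date = _dt.date(2009, 1, 1)
    date_end: _dt.date = _dt.date(2013, 12, 31)

    def validate(self) -> None:
        probs = (
            self.true_iii_rate,
            self.isoform_spec_rate,
            self.ddi_true_rate,
            self.dataset_presence_rate,
            self.p_membrane,
            self.p_nucleus,
            self.annotation_coherence,
            self.corr_strength_false,
            *self.isoform_count_probs,
            *self.ddi_confidence_mix,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if not (0.0 <= self.corr_strength_true < 1.0):
            raise ConfigError("corr_strength_true must lie in [0, 1)")
        for name in ("n_genes", "n_domains", "n_datasets"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.samples_per_dataset < 2:
            raise ConfigError("samples_per_dataset must be >= 2")
        if self.n_planted_modules > 0:
            if self.planted_module_size < 3:
                raise ConfigError("planted modules need size >= 3")
            if self.n_planted_modules * self.planted_module_size > self.n_genes:
                raise ConfigError("planted modules exceed the gene pool")


@dataclass
class SyntheticWorld:
    config: SyntheticWorldConfig
    catalog: IsoformCatalog
    ppi: list[PPIRecord]
    ddi: list[DDIRecord]
    datasets: list[ExpressionDataset]
    localization: LocalizationMap
    annotation: AnnotationMap
    true_iiis: frozenset[Pair]
    planted_modules: list[frozenset[str]]


def _loading(target_abs_r: float) -> float:
    # pair sharing one unit factor with loading L and unit noise has
    # r = L^2 / (L^2 + 1) -> L = sqrt(r / (1 - r))
    if target_abs_r <= 0.0:
        return 0.0
    return float(np.sqrt(target_abs_r / (1.0 - target_abs_r)))


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    counts = rng.choice(
        config.isoform_counts, size=config.n_genes, p=config.isoform_count_probs
    )
    isoforms: list[Isoform] = []
    gene_isoforms: dict[str, list[str]] = {}
    domain_pool = [f"PF{i:05d}" for i in range(1, config.n_domains + 1)]
    serial = 0
    for gene, k in zip(genes, counts):
        gene_isoforms[gene] = []
        for _ in range(int(k)):
            serial += 1
            iso_id = f"NM_{serial:06d}"
            n_dom = int(rng.integers(1, config.max_domains_per_isoform + 1))
            domains = frozenset(
                rng.choice(domain_pool, size=n_dom, replace=False).tolist()
            )
            isoforms.append(
                Isoform(
                    isoform_id=iso_id,
                    gene_id=gene,
                    domains=domains,
                    mrna_length=int(rng.integers(500, 10000)),
                    protein_length=int(rng.integers(100, 3000)),
                )
            )
            gene_isoforms[gene].append(iso_id)
    catalog = IsoformCatalog(isoforms)

    # -- functional isoforms: the isoform-resolved interaction capability of
    # each gene.  True IIIs are exactly functional x functional within each
    # PPI, so a false candidate pair always contains a non-functional isoform
    # (which will carry no co-expression signal at all).  Per-pair truth
    # probability is ~ q^2 = true_iii_rate.
    q = float(np.sqrt(config.true_iii_rate))
    functional: set[str] = {
        iso.isoform_id for iso in catalog if rng.random() < q
    }

    # -- planted modules: fully PPI-connected genes, one functional isoform each
    planted_modules: list[frozenset[str]] = []
    ppi_pairs: set[Pair] = set()
    module_gene_pool = rng.permutation(genes).tolist()
    for m in range(config.n_planted_modules):
        module_genes = module_gene_pool[
            m * config.planted_module_size : (m + 1) * config.planted_module_size
        ]
        members = [
            gene_isoforms[g][int(rng.integers(0, len(gene_isoforms[g])))]
            for g in module_genes
        ]
        functional.update(members)
        planted_modules.append(frozenset(members))
        for i in range(len(module_genes)):
            for j in range(i + 1, len(module_genes)):
                ppi_pairs.add(canonical_pair(module_genes[i], module_genes[j]))

    # -- background PPIs
    attempts = 0
    while len(ppi_pairs) < config.n_ppis and attempts < config.n_ppis * 50:
        attempts += 1
        ga, gb = rng.choice(genes, size=2, replace=False)
        ppi_pairs.add(canonical_pair(str(ga), str(gb)))

    # -- true IIIs: all functional cross pairs of each PPI
    true_iiis: set[Pair] = set()
    for ga, gb in sorted(ppi_pairs):
        for ia in gene_isoforms[ga]:
            if ia not in functional:
                continue
            for ib in gene_isoforms[gb]:
                if ib in functional and ia != ib:
                    true_iiis.add(canonical_pair(ia, ib))

    # -- PPI records with timestamps; some isoform-specified
    span = (config.date_end - config.date_start).days
    ppi_records: list[PPIRecord] = []
    iii_by_ppi: dict[Pair, list[Pair]] = {}
    for pair in true_iiis:
        gp = canonical_pair(
            catalog.gene_of(pair[0]), catalog.gene_of(pair[1])
        )
        iii_by_ppi.setdefault(gp, []).append(pair)
    for ga, gb in sorted(ppi_pairs):
        ts = config.date_start + _dt.timedelta(days=int(rng.integers(0, span + 1)))
        ppi_records.append(PPIRecord(ga, gb, None, None, ts).canonical())
        true_here = sorted(iii_by_ppi.get((ga, gb), []))
        if true_here and rng.random() < config.isoform_spec_rate:
            ia, ib = true_here[int(rng.integers(0, len(true_here)))]
            # record must name isoforms in the same order as its gene columns
            if catalog.gene_of(ia) != ga:
                ia, ib = ib, ia
            ts2 = config.date_start + _dt.timedelta(days=int(rng.integers(0, span + 1)))
            ppi_records.append(PPIRecord(ga, gb, ia, ib, ts2).canonical())

    # -- DDIs: supporting records for true IIIs + background
    ddi_records: list[DDIRecord] = []
    seen_ddi: set[DDIRecord] = set()
    confidences = ("high", "medium", "low")
    for ia, ib in sorted(true_iiis):
        if rng.random() >= config.ddi_true_rate:
            continue
        da = sorted(catalog.domains_of(ia))[int(rng.integers(0, len(catalog.domains_of(ia))))]
        db = sorted(catalog.domains_of(ib))[int(rng.integers(0, len(catalog.domains_of(ib))))]
        conf = confidences[int(rng.choice(3, p=config.ddi_confidence_mix))]
        rec = DDIRecord(da, db, conf).canonical()
        if rec not in seen_ddi:
            seen_ddi.add(rec)
            ddi_records.append(rec)
    for _ in range(config.n_background_ddis):
        da, db = rng.choice(domain_pool, size=2, replace=False)
        conf = confidences[int(rng.choice(3, p=config.ddi_confidence_mix))]
        rec = DDIRecord(str(da), str(db), conf).canonical()
        if rec not in seen_ddi:
            seen_ddi.add(rec)
            ddi_records.append(rec)

    # -- expression: one latent factor per interacting PPI, loaded only by
    # its functional isoforms.  Loadings are degree-normalized (an isoform
    # splits its signal variance across its PPI factors), so a pair with
    # sole factors reaches |r| ~ corr_strength_true and hub pairs decay by
    # 1/sqrt(m_a * m_b); false pairs share no factor and sit near 0.
    all_iso_ids = [iso.isoform_id for iso in catalog]
    interacting_ppis = sorted(
        {
            canonical_pair(catalog.gene_of(a), catalog.gene_of(b))
            for a, b in true_iiis
        }
    )
    factor_index = {gp: f for f, gp in enumerate(interacting_ppis)}
    factors_of_iso: dict[str, list[int]] = {}
    for ga, gb in interacting_ppis:
        for gene, other in ((ga, gb), (gb, ga)):
            if not any(i in functional for i in gene_isoforms[other]):
                continue
            for iso in gene_isoforms[gene]:
                if iso in functional:
                    factors_of_iso.setdefault(iso, []).append(
                        factor_index[(ga, gb)]
                    )
    lam_total = _loading(config.corr_strength_true)
    lam_false = _loading(config.corr_strength_false)
    datasets: list[ExpressionDataset] = []
    for d in range(1, config.n_datasets + 1):
        s = config.samples_per_dataset
        z = rng.normal(size=(len(all_iso_ids), s))
        if lam_false > 0.0:
            global_factor = rng.normal(size=s)
            signs = rng.choice((-1.0, 1.0), size=len(all_iso_ids))
            z += lam_false * signs[:, None] * global_factor[None, :]
        factor_values = rng.normal(size=(len(interacting_ppis), s))
        for row, iso in enumerate(all_iso_ids):
            loads = factors_of_iso.get(iso)
            if not loads:
                continue
            lam = lam_total / np.sqrt(len(loads))
            for f in loads:
                sign = -1.0 if rng.random() < 0.5 else 1.0
                z[row] += sign * lam * factor_values[f]
        present = rng.random(len(all_iso_ids)) < config.dataset_presence_rate
        kept = [iso for iso, keep in zip(all_iso_ids, present) if keep]
        zk = z[present]
        # per-row shift to non-negative; constant shifts preserve Pearson r
        zk = zk - zk.min(axis=1, keepdims=True) + 0.01
        matrix = pd.DataFrame(
            np.round(zk, 6),
            index=pd.Index(kept, name="isoform_id"),
            columns=[f"S{j:02d}" for j in range(1, s + 1)],
        )
        datasets.append(ExpressionDataset(dataset_id=f"E{d:02d}", matrix=matrix))

    # -- localization
    localization: LocalizationMap = {}
    for iso in all_iso_ids:
        comps_set = set()
        if rng.random() < config.p_membrane:
            comps_set.add("plasma_membrane")
        if rng.random() < config.p_nucleus:
            comps_set.add("nucleus")
        if not comps_set:
            comps_set.add("cytoplasm")
        localization[iso] = frozenset(comps_set)

    # -- annotations: coherent terms for planted modules + background terms
    annotation: AnnotationMap = {}
    for m, module in enumerate(planted_modules, start=1):
        for ns, prefix in (("GO", "GO:9%06d" % m), ("pathway", "path:hsa9%04d" % m)):
            members = {
                iso for iso in sorted(module) if rng.random() < config.annotation_coherence
            }
            extra = rng.choice(all_iso_ids, size=2, replace=False)
            members.update(str(x) for x in extra)
            if members:
                annotation[prefix] = (ns, frozenset(members))
    for t in range(1, config.n_background_terms + 1):
        ns = "GO" if t % 2 else "pathway"
        size = int(rng.integers(3, 25))
        members = frozenset(
            str(x) for x in rng.choice(all_iso_ids, size=min(size, len(all_iso_ids)), replace=False)
        )
        term = f"GO:{t:07d}" if ns == "GO" else f"path:hsa{t:05d}"
        annotation[term] = (ns, members)

    return SyntheticWorld(
        config=config,
        catalog=catalog,
        ppi=ppi_records,
        ddi=ddi_records,
        datasets=datasets,
        localization=localization,
        annotation=annotation,
        true_iiis=frozenset(true_iiis),
        planted_modules=planted_modules,
    )


def sample_model_pairs(
    n: int,
    coeffs: CoefficientVector,
    seed: int,
    ddi_probs: tuple[float, float, float, float] = (0.55, 0.15, 0.15, 0.15),
) -> tuple[list[PairFeatureVector], list[int]]:
    """Draw labeled feature vectors directly from the logistic model family.

    Correlation features are uniform on [0, 1]; the DDI score is categorical
    over {0,1,2,3}; labels are Bernoulli with probability given by the model.
    Useful for parameter-recovery checks against known coefficients.
    """
    rng = np.random.default_rng(seed)
    k = coeffs.n_datasets
    corr = rng.uniform(0.0, 1.0, size=(n, k))
    ddi = rng.choice(4, size=n, p=ddi_probs)
    features = [
        PairFeatureVector(
            isoform_a=f"NM_{2 * i + 1:06d}",
            isoform_b=f"NM_{2 * i + 2:06d}",
            ddi=int(ddi[i]),
            corr=tuple(float(c) for c in corr[i]),
        )
        for i in range(n)
    ]
    eta = (
        coeffs.alpha0
        + corr @ np.asarray(coeffs.alpha_corr)
        + coeffs.alpha_ddi * ddi
    )
    labels = (rng.random(n) < _sigmoid(eta)).astype(int).tolist()
    return features, labels


def world_to_files(world: SyntheticWorld, directory: str) -> dict[str, str]:
    """Write every input table in its on-disk dialect; returns path map."""
    os.makedirs(directory, exist_ok=True)
    expr_dir = os.path.join(directory, "expr")
    os.makedirs(expr_dir, exist_ok=True)
    paths = {
        "catalog": os.path.join(directory, "catalog.tsv"),
        "ppi": os.path.join(directory, "ppi.tsv"),
        "ddi": os.path.join(directory, "ddi.tsv"),
        "localization": os.path.join(directory, "localization.tsv"),
        "annotation": os.path.join(directory, "annotation.tsv"),
        "expr_dir": expr_dir,
    }
    write_catalog(world.catalog, paths["catalog"])
    write_ppi_table(world.ppi, paths["ppi"])
    write_ddi_table(world.ddi, paths["ddi"])
    write_localization(world.localization, paths["localization"])
    write_annotation(world.annotation, paths["annotation"])
    for ds in world.datasets:
        write_expression_matrix(ds, os.path.join(expr_dir, f"{ds.dataset_id}.tsv"))
    # planted truth, for evaluation only (not consumed by the pipeline)
    truth_path = os.path.join(directory, "truth_iii.tsv")
    with open(truth_path, "w") as fh:
        fh.write("isoform_a\tisoform_b\n")
        for a, b in sorted(world.true_iiis):
            fh.write(f"{a}\t{b}\n")
    paths["truth_iii"] = truth_path
    modules_path = os.path.join(directory, "truth_modules.tsv")
    with open(modules_path, "w") as fh:
        fh.write("module_id\tmembers\n")
        for i, module in enumerate(world.planted_modules, start=1):
            fh.write(f"T{i:04d}\t{';'.join(sorted(module))}\n")
    paths["truth_modules"] = modules_path
    return paths
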