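"""Readers/writers for all tabular inputs and outputs, with strict validation.

Every on-disk format is a flat TSV with a header row.  Identifier pairs are
stored in canonical (lexicographically sorted) order everywhere; readers
canonicalize, writers assume canonical input.

Dialects
--------
isoform catalog : isoform_id, gene_id, domains (";"-joined, may be empty),
                  mrna_length, protein_length (both optional, blank allowed)
PPI table       : gene_a, gene_b, isoform_a, isoform_b, timestamp (ISO date);
                  isoform columns blank for gene-level records
DDI table       : domain_a, domain_b, confidence in {high, medium, low}
expression      : first column isoform_id, remaining columns numeric samples;
                  one file per dataset, dataset_id = filename stem
localization    : isoform_id, compartments (";"-joined controlled vocabulary)
annotation      : term_id, namespace in {GO, pathway}, isoform_ids (";"-joined)
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd

from iiinet.errors import ValidationError

logger = logging.getLogger(__name__)

CONFIDENCE_LEVELS = ("high", "medium", "low")
NAMESPACES = ("GO", "pathway")
#: Controlled vocabulary for subcellular compartments.  Only plasma_membrane
#: and nucleus carry semantics downstream (negative-set construction); the
#: rest are accepted so localization tables can be realistic.
COMPARTMENTS = frozenset(
    {
        "plasma_membrane",
        "nucleus",
        "cytoplasm",
        "mitochondrion",
        "extracellular",
        "endoplasmic_reticulum",
        "golgi",
        "lysosome",
        "peroxisome",
    }
)

Pair = tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Return the pair ordered lexicographically (unordered-pair semantics)."""
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Isoform:
    isoform_id: str
    gene_id: str
    domains: frozenset[str]
    mrna_length: Optional[int] = None
    protein_length: Optional[int] = None


class IsoformCatalog:
    """Genes, their isoforms, and each isoform's domain composition.

    Enforces: unique isoform_id, each isoform maps to exactly one gene.
    """

    def __init__(self, isoforms: Iterable[Isoform]):
        self._by_id: dict[str, Isoform] = {}
        self._by_gene: dict[str, list[str]] = {}
        for iso in isoforms:
            if iso.isoform_id in self._by_id:
                raise ValidationError(
                    f"duplicate isoform_id {iso.isoform_id!r} in catalog"
                )
            if not iso.isoform_id or not iso.gene_id:
                raise ValidationError("isoform_id and gene_id must be non-empty")
            if iso.mrna_length is not None and iso.mrna_length <= 0:
                raise ValidationError(
                    f"isoform {iso.isoform_id!r}: mrna_length must be positive"
                )
            if iso.protein_length is not None and iso.protein_length <= 0:
                raise ValidationError(
                    f"isoform {iso.isoform_id!r}: protein_length must be positive"
                )
            self._by_id[iso.isoform_id] = iso
            self._by_gene.setdefault(iso.gene_id, []).append(iso.isoform_id)

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, isoform_id: str) -> bool:
        return isoform_id in self._by_id

    def __iter__(self) -> Iterator[Isoform]:
        return iter(self._by_id.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IsoformCatalog):
            return NotImplemented
        return self._by_id == other._by_id

    @property
    def isoform_ids(self) -> list[str]:
        return list(self._by_id)

    @property
    def genes(self) -> list[str]:
        return list(self._by_gene)

    def gene_of(self, isoform_id: str) -> str:
        return self._by_id[isoform_id].gene_id

    def isoforms_of_gene(self, gene_id: str) -> list[str]:
        return list(self._by_gene.get(gene_id, []))

    def domains_of(self, isoform_id: str) -> frozenset[str]:
        return self._by_id[isoform_id].domains

    def get(self, isoform_id: str) -> Isoform:
        return self._by_id[isoform_id]


@dataclass(frozen=True)
class PPIRecord:
    """One gene-level PPI record, optionally isoform-specified, with a date."""

    gene_a: str
    gene_b: str
    isoform_a: Optional[str]
    isoform_b: Optional[str]
    timestamp: _dt.date

    def canonical(self) -> "PPIRecord":
        if self.gene_a <= self.gene_b:
            return self
        return PPIRecord(
            self.gene_b, self.gene_a, self.isoform_b, self.isoform_a, self.timestamp
        )

    @property
    def is_isoform_specified(self) -> bool:
        return self.isoform_a is not None and self.isoform_b is not None


@dataclass(frozen=True)
class DDIRecord:
    domain_a: str
    domain_b: str
    confidence: str

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"unknown DDI confidence {self.confidence!r}; "
                f"expected one of {CONFIDENCE_LEVELS}"
            )

    def canonical(self) -> "DDIRecord":
        if self.domain_a <= self.domain_b:
            return self
        return DDIRecord(self.domain_b, self.domain_a, self.confidence)


@dataclass
class ExpressionDataset:
    """Isoforms x samples matrix of non-negative expression values."""

    dataset_id: str
    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 2:
            raise ValidationError(
                f"dataset {self.dataset_id!r}: needs >= 2 samples, "
                f"got {self.matrix.shape[1]} (correlation undefined)"
            )
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValidationError(
                f"dataset {self.dataset_id!r}: duplicate isoform row {dup!r}"
            )
        if (self.matrix.to_numpy() < 0).any():
            raise ValidationError(
                f"dataset {self.dataset_id!r}: negative expression values"
            )

    @property
    def sample_count(self) -> int:
        return self.matrix.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return self.dataset_id == other.dataset_id and self.matrix.equals(other.matrix)


LocalizationMap = dict[str, frozenset[str]]
#: term_id -> (namespace, annotated isoform ids)
AnnotationMap = dict[str, tuple[str, frozenset[str]]]


def dual_localized(localization: LocalizationMap) -> set[str]:
    """Isoforms carrying both the plasma_membrane and nucleus labels."""
    return {
        iso
        for iso, comps in localization.items()
        if "plasma_membrane" in comps and "nucleus" in comps
    }


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str, required: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _parse_opt_int(value: str, path: str, row: int, col: str) -> Optional[int]:
    if value == "":
        return None
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"{path} row {row}: {col}={value!r} is not an integer")


def read_isoform_catalog(path: str) -> IsoformCatalog:
    df = _read_tsv(path, ["isoform_id", "gene_id", "domains"])
    isoforms = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        domains = frozenset(d for d in row.domains.split(";") if d)
        isoforms.append(
            Isoform(
                isoform_id=row.isoform_id,
                gene_id=row.gene_id,
                domains=domains,
                mrna_length=_parse_opt_int(
                    getattr(row, "mrna_length", ""), path, i, "mrna_length"
                ),
                protein_length=_parse_opt_int(
                    getattr(row, "protein_length", ""), path, i, "protein_length"
                ),
            )
        )
    try:
        return IsoformCatalog(isoforms)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_ppi_table(path: str) -> list[PPIRecord]:
    """Read PPI records, canonicalize gene order, collapse exact duplicates."""
    df = _read_tsv(path, ["gene_a", "gene_b", "isoform_a", "isoform_b", "timestamp"])
    records: list[PPIRecord] = []
    seen: set[PPIRecord] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not row.gene_a or not row.gene_b:
            raise ValidationError(f"{path} row {i}: empty gene identifier")
        try:
            ts = _dt.date.fromisoformat(row.timestamp)
        except ValueError:
            raise ValidationError(
                f"{path} row {i}: unparseable timestamp {row.timestamp!r}"
            )
        iso_a = row.isoform_a or None
        iso_b = row.isoform_b or None
        if (iso_a is None) != (iso_b is None):
            raise ValidationError(
                f"{path} row {i}: isoform specification must name both isoforms"
            )
        rec = PPIRecord(row.gene_a, row.gene_b, iso_a, iso_b, ts).canonical()
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    return records


def read_ddi_table(path: str) -> list[DDIRecord]:
    df = _read_tsv(path, ["domain_a", "domain_b", "confidence"])
    records: list[DDIRecord] = []
    seen: set[DDIRecord] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = DDIRecord(row.domain_a, row.domain_b, row.confidence).canonical()
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        if rec not in seen:
            seen.add(rec)
            records.append(rec)
    return records


def read_expression_matrix(path: str, dataset_id: Optional[str] = None) -> ExpressionDataset:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if dataset_id is None:
        dataset_id = os.path.splitext(os.path.basename(path))[0]
    df.index = df.index.astype(str)
    try:
        matrix = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric expression value ({exc})")
    return ExpressionDataset(dataset_id=dataset_id, matrix=matrix)


def read_localization(path: str) -> LocalizationMap:
    df = _read_tsv(path, ["isoform_id", "compartments"])
    out: LocalizationMap = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        comps = frozenset(c for c in row.compartments.split(";") if c)
        unknown = comps - COMPARTMENTS
        if unknown:
            raise ValidationError(
                f"{path} row {i}: unknown compartment label(s) {sorted(unknown)}"
            )
        out[row.isoform_id] = comps
    return out


def read_annotation(path: str) -> AnnotationMap:
    df = _read_tsv(path, ["term_id", "namespace", "isoform_ids"])
    out: AnnotationMap = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.namespace not in NAMESPACES:
            raise ValidationError(
                f"{path} row {i}: namespace {row.namespace!r} not in {NAMESPACES}"
            )
        members = frozenset(m for m in row.isoform_ids.split(";") if m)
        if not members:
            raise ValidationError(f"{path} row {i}: term {row.term_id!r} has no isoforms")
        out[row.term_id] = (row.namespace, members)
    return out


def validate_against_catalog(
    catalog: IsoformCatalog,
    ppi: Optional[Sequence[PPIRecord]] = None,
    datasets: Optional[Sequence[ExpressionDataset]] = None,
    localization: Optional[LocalizationMap] = None,
    annotation: Optional[AnnotationMap] = None,
) -> None:
    """Cross-file checks that individual readers cannot perform alone."""
    if ppi is not None:
        for rec in ppi:
            for iso, gene in ((rec.isoform_a, rec.gene_a), (rec.isoform_b, rec.gene_b)):
                if iso is None:
                    continue
                if iso not in catalog:
                    raise ValidationError(f"PPI isoform {iso!r} not in catalog")
                if catalog.gene_of(iso) != gene:
                    raise ValidationError(
                        f"PPI isoform {iso!r} belongs to gene "
                        f"{catalog.gene_of(iso)!r}, record says {gene!r}"
                    )
    if datasets is not None:
        for ds in datasets:
            stray = set(ds.matrix.index) - set(catalog.isoform_ids)
            if stray:
                raise ValidationError(
                    f"dataset {ds.dataset_id!r}: rows not in catalog: "
                    f"{sorted(stray)[:5]}"
                )
    if localization is not None:
        stray = set(localization) - set(catalog.isoform_ids)
        if stray:
            raise ValidationError(
                f"localization isoforms not in catalog: {sorted(stray)[:5]}"
            )
    if annotation is not None:
        all_ids = set(catalog.isoform_ids)
        for term, (_, members) in annotation.items():
            stray = members - all_ids
            if stray:
                raise ValidationError(
                    f"annotation term {term!r}: isoforms not in catalog: "
                    f"{sorted(stray)[:5]}"
                )


# ---------------------------------------------------------------------------
# Writers (and matching readers for outputs)
# ---------------------------------------------------------------------------


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_predictions(predictions: Sequence, path: str, dataset_ids: Sequence[str]) -> None:
    """Write one row per predicted isoform pair with full evidence values.

    Evidence columns mirror the model features: the DDI score and one
    absolute-correlation column per expression dataset (blank = missing).
    """
    if len(predictions) == 0:
        logger.warning("writing empty prediction set to %s (header only)", path)
    corr_cols = [f"corr_{d}" for d in dataset_ids]
    header = [
        "isoform_a",
        "isoform_b",
        "gene_a",
        "gene_b",
        "logit_score",
        "tier",
        "ddi_score",
        *corr_cols,
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in predictions:
            corr = [
                "" if c is None else _fmt_float(c) for c in p.evidence.corr
            ]
            row = [
                p.pair[0],
                p.pair[1],
                p.gene_pair[0],
                p.gene_pair[1],
                _fmt_float(p.logit_score),
                p.tier,
                str(p.evidence.ddi),
                *corr,
            ]
            fh.write("\t".join(row) + "\n")


def read_predictions(path: str):
    """Read a prediction TSV back into IIIPrediction objects (lossless)."""
    from iiinet.features import PairFeatureVector
    from iiinet.iii_model import IIIPrediction

    df = _read_tsv(
        path,
        ["isoform_a", "isoform_b", "gene_a", "gene_b", "logit_score", "tier", "ddi_score"],
    )
    corr_cols = [c for c in df.columns if c.startswith("corr_")]
    out = []
    for row in df.itertuples(index=False):
        corr = tuple(
            None if getattr(row, c) == "" else float(getattr(row, c)) for c in corr_cols
        )
        fv = PairFeatureVector(
            isoform_a=row.isoform_a,
            isoform_b=row.isoform_b,
            ddi=int(row.ddi_score),
            corr=corr,
        )
        out.append(
            IIIPrediction(
                pair=(row.isoform_a, row.isoform_b),
                gene_pair=(row.gene_a, row.gene_b),
                logit_score=float(row.logit_score),
                tier=row.tier,
                evidence=fv,
            )
        )
    return out


def write_modules(modules: Sequence, path: str, top_terms: Optional[Mapping[str, Sequence[str]]] = None) -> None:
    """Write modules as module_id, member list, density, top enriched terms."""
    if len(modules) == 0:
        logger.warning("writing empty module set to %s (header only)", path)
    with open(path, "w") as fh:
        fh.write("module_id\tmembers\tdensity\ttop_terms\n")
        for m in modules:
            terms = ";".join((top_terms or {}).get(m.module_id, []))
            fh.write(
                f"{m.module_id}\t{';'.join(sorted(m.members))}\t"
                f"{_fmt_float(m.density)}\t{terms}\n"
            )


def read_modules(path: str):
    from iiinet.module_discovery import IsoformModule

    df = _read_tsv(path, ["module_id", "members", "density"])
    out = []
    for row in df.itertuples(index=False):
        out.append(
            IsoformModule(
                module_id=row.module_id,
                members=frozenset(m for m in row.members.split(";") if m),
                density=float(row.density),
            )
        )
    return out


def write_gold_standard(gold, path: str) -> None:
    """Export labeled pairs: isoform_a, isoform_b, label, provenance."""
    with open(path, "w") as fh:
        fh.write("isoform_a\tisoform_b\tlabel\tprovenance\n")
        for label, pairs in (
            ("pos_train", gold.positives_train),
            ("pos_test", gold.positives_test),
            ("neg", gold.negatives),
        ):
            for a, b in sorted(pairs):
                prov = gold.provenance.get((a, b), "localization")
                fh.write(f"{a}\t{b}\t{label}\t{prov}\n")


def write_catalog(catalog: IsoformCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("isoform_id\tgene_id\tdomains\tmrna_length\tprotein_length\n")
        for iso in catalog:
            ml = "" if iso.mrna_length is None else str(iso.mrna_length)
            pl = "" if iso.protein_length is None else str(iso.protein_length)
            fh.write(
                f"{iso.isoform_id}\t{iso.gene_id}\t"
                f"{';'.join(sorted(iso.domains))}\t{ml}\t{pl}\n"
            )


def write_ppi_table(records: Sequence[PPIRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tisoform_a\tisoform_b\ttimestamp\n")
        for r in records:
            fh.write(
                f"{r.gene_a}\t{r.gene_b}\t{r.isoform_a or ''}\t"
                f"{r.isoform_b or ''}\t{r.timestamp.isoformat()}\n"
            )


def write_ddi_table(records: Sequence[DDIRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("domain_a\tdomain_b\tconfidence\n")
        for r in records:
            fh.write(f"{r.domain_a}\t{r.domain_b}\t{r.confidence}\n")


def write_expression_matrix(dataset: ExpressionDataset, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("isoform_id\t" + "\t".join(map(str, dataset.matrix.columns)) + "\n")
        for iso, row in dataset.matrix.iterrows():
            fh.write(str(iso) + "\t" + "\t".join(_fmt_float(v) for v in row) + "\n")


def write_localization(localization: LocalizationMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("isoform_id\tcompartments\n")
        for iso in sorted(localization):
            fh.write(f"{iso}\t{';'.join(sorted(localization[iso]))}\n")


def write_annotation(annotation: AnnotationMap, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("term_id\tnamespace\tisoform_ids\n")
        for term in sorted(annotation):
            ns, members = annotation[term]
            fh.write(f"{term}\t{ns}\t{';'.join(sorted(members))}\n")
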