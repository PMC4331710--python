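"""Gold-standard positive/negative isoform-pair sets and the date-based split.

Positives (GSP) come from two rules: (a) isoform-specified PPI records give
their isoform pair directly; (b) a gene-level PPI whose two genes each have
exactly one catalog isoform gives that unique pair.  Positives are split
into train/test by the earliest supporting record's date: strictly after
the cutoff goes to test.

Negatives (GSN) are cross pairs between GSP-covered isoforms localized to
the plasma membrane only and those localized to the nucleus only; isoforms
carrying both labels are excluded from both sides, and any pair already in
the GSP is removed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from iiinet.data_io import (
    IsoformCatalog,
    LocalizationMap,
    PPIRecord,
    Pair,
    canonical_pair,
)
from iiinet.errors import ContractViolation, ValidationError

DEFAULT_CUTOFF = _dt.date(2012, 1, 1)

PROV_ISOFORM_SPECIFIED = "isoform_specified"
PROV_SINGLE_ISOFORM = "single_isoform"


@dataclass
class GoldStandard:
    positives_train: frozenset[Pair]
    positives_test: frozenset[Pair]
    negatives: frozenset[Pair]
    provenance: dict[Pair, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        positives = self.positives_train | self.positives_test
        if self.positives_train & self.positives_test:
            raise ValidationError("train/test positive sets overlap")
        if self.negatives & positives:
            raise ValidationError("negative set overlaps positives")

    @property
    def positives(self) -> frozenset[Pair]:
        return self.positives_train | self.positives_test

    @property
    def covered_isoforms(self) -> frozenset[str]:
        return frozenset(i for pair in self.positives for i in pair)


def _implied_pairs(
    record: PPIRecord, catalog: IsoformCatalog
) -> list[tuple[Pair, str]]:
    """Pairs a single PPI record contributes to the GSP, with provenance."""
    out: list[tuple[Pair, str]] = []
    if record.is_isoform_specified:
        for iso, gene in (
            (record.isoform_a, record.gene_a),
            (record.isoform_b, record.gene_b),
        ):
            if iso not in catalog:
                raise ValidationError(f"isoform {iso!r} not in catalog")
            if catalog.gene_of(iso) != gene:
                raise ValidationError(
                    f"isoform {iso!r} maps to gene {catalog.gene_of(iso)!r}, "
                    f"but PPI record says {gene!r}"
                )
        out.append(
            (canonical_pair(record.isoform_a, record.isoform_b), PROV_ISOFORM_SPECIFIED)
        )
    else:
        isos_a = catalog.isoforms_of_gene(record.gene_a)
        isos_b = catalog.isoforms_of_gene(record.gene_b)
        if len(isos_a) == 1 and len(isos_b) == 1:
            pair = canonical_pair(isos_a[0], isos_b[0])
            if pair[0] != pair[1]:  # homodimer of a single-isoform gene: self-pair ok
                out.append((pair, PROV_SINGLE_ISOFORM))
            else:
                out.append((pair, PROV_SINGLE_ISOFORM))
    return out


def build_gsp(
    ppi: Sequence[PPIRecord], catalog: IsoformCatalog
) -> tuple[frozenset[Pair], dict[Pair, str]]:
    """Gold-standard positive pairs with per-pair provenance.

    When a pair is supported by both rules, the isoform_specified tag wins.
    """
    provenance: dict[Pair, str] = {}
    for record in ppi:
        for pair, tag in _implied_pairs(record, catalog):
            if tag == PROV_ISOFORM_SPECIFIED or pair not in provenance:
                provenance[pair] = tag
    return frozenset(provenance), provenance


def split_gsp_by_timestamp(
    pairs: Iterable[Pair],
    ppi: Sequence[PPIRecord],
    catalog: IsoformCatalog,
    cutoff: _dt.date = DEFAULT_CUTOFF,
) -> tuple[frozenset[Pair], frozenset[Pair]]:
    """Partition GSP pairs: earliest supporting record after cutoff -> test.

    "After" is strict: a record dated exactly on the cutoff goes to train.
    A pair supported by several records uses the earliest date, so a pair
    known before the cutoff never leaks into the test set.
    """
    earliest: dict[Pair, _dt.date] = {}
    for record in ppi:
        for pair, _tag in _implied_pairs(record, catalog):
            prev = earliest.get(pair)
            if prev is None or record.timestamp < prev:
                earliest[pair] = record.timestamp
    train, test = set(), set()
    for pair in pairs:
        if pair not in earliest:
            raise ContractViolation(f"GSP pair {pair} has no supporting PPI record")
        (test if earliest[pair] > cutoff else train).add(pair)
    return frozenset(train), frozenset(test)


def build_gsn(
    covered_isoforms: Iterable[str],
    localization: LocalizationMap,
    gsp_pairs: Iterable[Pair] = (),
) -> frozenset[Pair]:
    """Membrane-only x nucleus-only cross pairs among GSP-covered isoforms.

    An isoform assigned to both compartments is excluded from both sides;
    pairs already present in the GSP are removed.
    """
    covered = set(covered_isoforms)
    membrane, nucleus = [], []
    for iso in covered:
        comps = localization.get(iso, frozenset())
        has_m = "plasma_membrane" in comps
        has_n = "nucleus" in comps
        if has_m and has_n:
            continue  # dual-localized: excluded entirely
        if has_m:
            membrane.append(iso)
        elif has_n:
            nucleus.append(iso)
    gsp = set(gsp_pairs)
    pairs = {
        canonical_pair(m, n) for m in membrane for n in nucleus if m != n
    }
    return frozenset(pairs - gsp)


def build_gold_standard(
    ppi: Sequence[PPIRecord],
    catalog: IsoformCatalog,
    localization: LocalizationMap,
    cutoff: _dt.date = DEFAULT_CUTOFF,
) -> GoldStandard:
    """Run GSP construction, the date split, and GSN construction end to end."""
    gsp, provenance = build_gsp(ppi, catalog)
    train, test = split_gsp_by_timestamp(gsp, ppi, catalog, cutoff)
    negatives = build_gsn(frozenset(i for p in gsp for i in p), localization, gsp)
    return GoldStandard(
        positives_train=train,
        positives_test=test,
        negatives=negatives,
        provenance=provenance,
    )
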