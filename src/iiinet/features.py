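"""Per-pair explanatory variables: one DDI score + one |Pearson r| per dataset.

The DDI score is the maximum confidence-mapped score (high=3, medium=2,
low=1, no match=0) over all cross pairs of the two isoforms' domain sets.
Each expression dataset contributes the absolute sample Pearson correlation
of the two isoforms' expression profiles; the entry is missing when either
isoform is absent from the dataset or has zero variance in it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from iiinet.data_io import (
    DDIRecord,
    ExpressionDataset,
    IsoformCatalog,
    Pair,
    canonical_pair,
)
from iiinet.errors import ContractViolation, ValidationError

CONFIDENCE_SCORE = {"high": 3, "medium": 2, "low": 1}


@dataclass(frozen=True)
class PairFeatureVector:
    """Features of one canonical isoform pair.

    ``corr`` holds one entry per configured expression dataset, ``None``
    marking a missing value (isoform absent or zero variance).
    """

    isoform_a: str
    isoform_b: str
    ddi: int
    corr: tuple[Optional[float], ...]

    def __post_init__(self) -> None:
        if self.ddi not in (0, 1, 2, 3):
            raise ContractViolation(f"ddi score {self.ddi} outside {{0,1,2,3}}")
        for c in self.corr:
            if c is not None and not (0.0 <= c <= 1.0):
                raise ContractViolation(f"correlation {c} outside [0, 1]")

    @property
    def pair(self) -> Pair:
        return (self.isoform_a, self.isoform_b)

    @property
    def missing_mask(self) -> tuple[bool, ...]:
        return tuple(c is None for c in self.corr)

    def corr_imputed(self) -> np.ndarray:
        """Correlation vector with missing entries imputed as 0 (no evidence)."""
        return np.array([0.0 if c is None else c for c in self.corr])

    def as_model_row(self) -> np.ndarray:
        """Feature row in model order: E1..EK then DDI (no intercept)."""
        return np.append(self.corr_imputed(), float(self.ddi))


def abs_pearson(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """|sample Pearson correlation| of two equal-length vectors.

    Returns None (missing) when either vector has zero variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ContractViolation(
            f"vectors must be 1-D of equal length, got {xa.shape} and {ya.shape}"
        )
    if xa.size < 2:
        raise ContractViolation("correlation needs at least 2 observations")
    xc = xa - xa.mean()
    yc = ya - ya.mean()
    nx = math.sqrt(float(xc @ xc))
    ny = math.sqrt(float(yc @ yc))
    if nx == 0.0 or ny == 0.0:
        return None
    r = float(xc @ yc) / (nx * ny)
    return min(abs(r), 1.0)


def _ddi_index(ddi: Iterable[DDIRecord]) -> dict[frozenset[str], int]:
    index: dict[frozenset[str], int] = {}
    for rec in ddi:
        key = frozenset((rec.domain_a, rec.domain_b))
        score = CONFIDENCE_SCORE[rec.confidence]
        if score > index.get(key, 0):
            index[key] = score
    return index


def ddi_score(
    domains_a: Iterable[str],
    domains_b: Iterable[str],
    ddi: Iterable[DDIRecord],
) -> int:
    """Highest confidence score over all cross domain pairs; 0 if none match."""
    index = _ddi_index(ddi)
    best = 0
    for da in domains_a:
        for db in domains_b:
            best = max(best, index.get(frozenset((da, db)), 0))
    return best


class _DatasetView:
    """Row-standardized view of one dataset for fast pairwise correlations."""

    def __init__(self, dataset: ExpressionDataset):
        mat = dataset.matrix.to_numpy(dtype=float)
        centered = mat - mat.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        self._rows: dict[str, Optional[np.ndarray]] = {}
        for i, iso in enumerate(dataset.matrix.index):
            if norms[i] == 0.0:
                self._rows[iso] = None  # zero variance
            else:
                self._rows[iso] = centered[i] / norms[i]

    def abs_corr(self, iso_a: str, iso_b: str) -> Optional[float]:
        ua = self._rows.get(iso_a)
        ub = self._rows.get(iso_b)
        if ua is None or ub is None:
            return None
        return min(abs(float(ua @ ub)), 1.0)


def build_feature_vectors(
    pairs: Sequence[Pair],
    datasets: Sequence[ExpressionDataset],
    catalog: IsoformCatalog,
    ddi: Sequence[DDIRecord],
) -> list[PairFeatureVector]:
    """Assemble one feature vector per isoform pair (canonical order)."""
    index = _ddi_index(ddi)
    views = [_DatasetView(ds) for ds in datasets]
    out: list[PairFeatureVector] = []
    for a, b in pairs:
        if a not in catalog or b not in catalog:
            missing = a if a not in catalog else b
            raise ValidationError(f"pair references unknown isoform {missing!r}")
        a, b = canonical_pair(a, b)
        best = 0
        for da in catalog.domains_of(a):
            for db in catalog.domains_of(b):
                best = max(best, index.get(frozenset((da, db)), 0))
        corr = tuple(v.abs_corr(a, b) for v in views)
        out.append(PairFeatureVector(isoform_a=a, isoform_b=b, ddi=best, corr=corr))
    return out
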