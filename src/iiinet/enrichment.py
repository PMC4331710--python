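"""Hypergeometric term enrichment per module and the discovered-vs-random
enrichment-rate comparison.

For a module of size n (counted within the universe of N isoforms), a term
annotating K universe isoforms of which k fall in the module gets the
upper-tail p-value P(X >= k), X ~ Hypergeometric(N, K, n).  P-values are
Benjamini-Hochberg adjusted within each module, separately per namespace.
A module is "enriched" in a namespace when any of its terms has adjusted
p below alpha; the enrichment rate is the fraction of such modules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from iiinet.data_io import AnnotationMap, NAMESPACES
from iiinet.errors import ContractViolation
from iiinet.module_discovery import IsoformModule

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: str
    term_id: str
    namespace: str
    k: int  # module members annotated with the term
    K: int  # universe isoforms annotated with the term
    n: int  # module size counted within the universe
    N: int  # universe size
    p_value: float
    adjusted_p: float


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); 1.0 at k = 0."""
    if not (0 <= k <= min(K, n)) or K > N or n > N:
        raise ContractViolation(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 0.0), 1.0)


def enrich_module(
    module: IsoformModule,
    annotation: AnnotationMap,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Enrichment results for every term sharing >= 1 isoform with the module,
    BH-adjusted within the module per namespace, sorted by p-value."""
    uni = set(universe)
    if not uni:
        raise ContractViolation("empty annotation universe")
    if not set(module.members) <= uni:
        raise ContractViolation(
            f"module {module.module_id} has members outside the universe"
        )
    n = len(set(module.members) & uni)
    N = len(uni)
    raw: list[EnrichmentResult] = []
    for term_id in sorted(annotation):
        namespace, annotated = annotation[term_id]
        ann_in_uni = annotated & uni
        k = len(set(module.members) & ann_in_uni)
        if k == 0:
            continue
        K = len(ann_in_uni)
        raw.append(
            EnrichmentResult(
                module_id=module.module_id,
                term_id=term_id,
                namespace=namespace,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=hypergeom_upper_tail(k, K, n, N),
                adjusted_p=1.0,  # placeholder, filled below
            )
        )
    out: list[EnrichmentResult] = []
    for namespace in NAMESPACES:
        group = [r for r in raw if r.namespace == namespace]
        if not group:
            continue
        _, adj, _, _ = multipletests([r.p_value for r in group], method="fdr_bh")
        for r, a in zip(group, adj):
            out.append(
                EnrichmentResult(
                    module_id=r.module_id,
                    term_id=r.term_id,
                    namespace=r.namespace,
                    k=r.k,
                    K=r.K,
                    n=r.n,
                    N=r.N,
                    p_value=r.p_value,
                    adjusted_p=max(float(a), r.p_value),
                )
            )
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


def enrichment_rate(
    modules: Sequence[IsoformModule],
    annotation: AnnotationMap,
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    namespace: str = "GO",
) -> float:
    """Fraction of modules with >= 1 term at adjusted p < alpha in the namespace."""
    if not modules:
        return 0.0
    uni = set(universe)
    enriched = 0
    for mod in modules:
        results = enrich_module(mod, annotation, uni)
        if any(r.namespace == namespace and r.adjusted_p < alpha for r in results):
            enriched += 1
    return enriched / len(modules)


def write_enrichment(results: Sequence[EnrichmentResult], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "module_id\tterm_id\tnamespace\tk\tK\tn\tN\tp_value\tadjusted_p\n"
        )
        for r in results:
            fh.write(
                f"{r.module_id}\t{r.term_id}\t{r.namespace}\t{r.k}\t{r.K}\t"
                f"{r.n}\t{r.N}\t{r.p_value!r}\t{r.adjusted_p!r}\n"
            )
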