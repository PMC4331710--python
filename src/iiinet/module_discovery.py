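"""Overlapping dense module discovery in the III network, plus a random null.

The discovery algorithm is a deterministic greedy seed-and-extend over the
unweighted network: every edge (in descending degree-sum order) seeds a
module, which grows by the neighbor that maximizes the resulting density,
as long as density stays above the cutoff and the size cap is respected.
Modules may overlap; duplicate and subset member sets are pruned.

The null generator draws, for each discovered module, a uniformly random
member set of the same size from the node universe, preserving the size
multiset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from iiinet.data_io import Pair, canonical_pair
from iiinet.errors import ConfigError, ContractViolation, ValidationError


class IIINetwork:
    """Unweighted, undirected isoform network without self-loops."""

    def __init__(self, edges: Iterable[Pair], nodes: Iterable[str] = ()):
        self.adjacency: dict[str, set[str]] = {n: set() for n in nodes}
        self.edges: set[Pair] = set()
        for a, b in edges:
            if a == b:
                raise ValidationError(f"self-loop edge on {a!r} not allowed")
            pair = canonical_pair(a, b)
            self.edges.add(pair)
            self.adjacency.setdefault(a, set()).add(b)
            self.adjacency.setdefault(b, set()).add(a)

    @property
    def nodes(self) -> set[str]:
        return set(self.adjacency)

    def degree(self, node: str) -> int:
        return len(self.adjacency[node])

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    @classmethod
    def from_predictions(cls, predictions: Sequence) -> "IIINetwork":
        """Build the network from predictions, dropping isoform self-pairs."""
        return cls(p.pair for p in predictions if p.pair[0] != p.pair[1])


@dataclass(frozen=True)
class IsoformModule:
    module_id: str
    members: frozenset[str]
    density: float


def graph_density(members: Iterable[str], network: IIINetwork) -> float:
    """Simple-graph density 2E/(n(n-1)) of the induced subgraph."""
    mem = set(members)
    n = len(mem)
    if n < 2:
        raise ContractViolation("density needs at least 2 members")
    e_in = sum(
        1 for a, b in network.edges if a in mem and b in mem
    )
    return 2.0 * e_in / (n * (n - 1))


def discover_modules(
    network: IIINetwork,
    min_size: int = 3,
    max_size: int = 30,
    min_density: float = 0.7,
    seed: int = 0,
) -> list[IsoformModule]:
    """Greedy seed-and-extend discovery of overlapping dense modules.

    The algorithm is fully deterministic; ``seed`` is accepted for interface
    symmetry with the randomized null but does not influence the result.
    """
    if min_size < 2:
        raise ConfigError("min_size must be >= 2")
    if max_size < min_size:
        raise ConfigError("max_size must be >= min_size")
    if not (0.0 < min_density <= 1.0):
        raise ConfigError("min_density must lie in (0, 1]")

    seeds = sorted(
        network.edges,
        key=lambda e: (-(network.degree(e[0]) + network.degree(e[1])), e),
    )
    emitted: list[IsoformModule] = []
    emitted_sets: list[frozenset[str]] = []
    for edge in seeds:
        members = set(edge)
        e_in = 1
        # snapshot of the densest admissible state seen along the growth path,
        # so a perfect clique is not diluted by one extra barely-dense neighbor
        snapshot: Optional[frozenset[str]] = None
        snapshot_density = -1.0
        while True:
            n = len(members)
            density_now = 2.0 * e_in / (n * (n - 1))
            if n >= min_size and density_now >= max(min_density, snapshot_density):
                snapshot = frozenset(members)
                snapshot_density = density_now
            if n >= max_size:
                break
            candidates = sorted(
                {nb for m in members for nb in network.adjacency[m]} - members
            )
            best_node: Optional[str] = None
            best_density = -1.0
            for cand in candidates:
                gained = len(network.adjacency[cand] & members)
                density = 2.0 * (e_in + gained) / ((n + 1) * n)
                if density > best_density:
                    best_density = density
                    best_node = cand
            if best_node is None or best_density < min_density:
                break
            e_in += len(network.adjacency[best_node] & members)
            members.add(best_node)
        if snapshot is None:
            continue
        fs = snapshot
        if any(fs <= prev for prev in emitted_sets):
            continue
        emitted_sets.append(fs)
        emitted.append(
            IsoformModule(
                module_id=f"M{len(emitted) + 1:04d}",
                members=fs,
                density=graph_density(fs, network),
            )
        )
    for mod in emitted:
        assert min_size <= len(mod.members) <= max_size
        assert mod.density >= min_density
    return emitted


def randomize_modules(
    modules: Sequence[IsoformModule],
    universe: Iterable[str],
    seed: int,
    network: Optional[IIINetwork] = None,
) -> list[IsoformModule]:
    """Size-matched random modules: uniform member sets from the universe.

    Densities are recomputed on the given network (and may fall below the
    discovery cutoff); without a network they are reported as 0.0.
    """
    pool = sorted(set(universe))
    rng = np.random.default_rng(seed)
    out: list[IsoformModule] = []
    for i, mod in enumerate(modules, start=1):
        k = len(mod.members)
        if k > len(pool):
            raise ContractViolation(
                f"universe of {len(pool)} cannot supply a module of size {k}"
            )
        members = frozenset(rng.choice(pool, size=k, replace=False).tolist())
        density = graph_density(members, network) if network is not None else 0.0
        out.append(IsoformModule(module_id=f"R{i:04d}", members=members, density=density))
    return out
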