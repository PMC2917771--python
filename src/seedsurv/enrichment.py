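"""Gene-set over-representation and signature-overlap counting.

Over-representation of a query gene list in annotation sets (GO classes,
KEGG pathways shipped as GMT) is tested with the hypergeometric upper tail
and Benjamini–Hochberg FDR adjustment across sets. Overlaps between 2–4
gene lists are counted exactly per intersection region (Venn regions).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_config import GeneSetCollection, logger


@dataclass
class EnrichmentResult:
    """One tested set: overlap k of the query (size n) with the set
    (size K in the universe of N genes), hypergeometric upper-tail p and
    BH-adjusted q."""

    set_name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    overlap_genes: list[str]


def bh_fdr(p_values) -> np.ndarray:
    """Step-up Benjamini–Hochberg q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str] | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of *query* in every set, with BH
    FDR across tested sets.

    The universe defaults to the collection's explicit background; sets are
    intersected with the universe before testing and sets with no universe
    overlap are skipped. Duplicate query symbols are collapsed.
    """
    if universe is None:
        universe = sets.universe
    if universe is None:
        raise ValueError("no universe: pass one or set GeneSetCollection.universe")
    uni = set(universe)
    q_all = list(dict.fromkeys(query))
    if len(q_all) < len(query):
        logger.info("hypergeom_enrich: collapsed %d duplicate query symbols",
                    len(query) - len(q_all))
    q = set(q_all) & uni
    if not q:
        raise ValueError("query has no overlap with the universe")
    if len(q) < len(q_all):
        logger.info("hypergeom_enrich: %d query genes outside universe ignored",
                    len(q_all) - len(q))
    N, n = len(uni), len(q)
    results: list[EnrichmentResult] = []
    for name, members in sets.sets.items():
        in_uni = set(members) & uni
        if not in_uni:
            continue
        hit = sorted(q & in_uni)
        results.append(EnrichmentResult(
            set_name=name, k=len(hit), K=len(in_uni), n=n, N=N,
            p=hypergeom_test(len(hit), len(in_uni), n, N), q=np.nan,
            overlap_genes=hit,
        ))
    qvals = bh_fdr([r.p for r in results])
    for r, qv in zip(results, qvals):
        r.q = float(qv)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


@dataclass
class OverlapTable:
    """Exact intersection-region counts for 2–4 named gene lists.

    ``regions`` maps a membership pattern (tuple of booleans in list order)
    to the genes exclusive to that pattern; counts sum to the union size.
    """

    list_names: list[str]
    regions: dict[tuple[bool, ...], list[str]]

    @property
    def counts(self) -> dict[tuple[bool, ...], int]:
        return {pat: len(genes) for pat, genes in self.regions.items()}

    def count(self, *names: str) -> int:
        """Genes exactly in the named lists and no other."""
        pat = tuple(n in names for n in self.list_names)
        return len(self.regions.get(pat, []))

    def intersection(self, *names: str) -> set[str]:
        """Genes in all the named lists (regardless of the others)."""
        idx = [self.list_names.index(n) for n in names]
        out: set[str] = set()
        for pat, genes in self.regions.items():
            if all(pat[i] for i in idx):
                out.update(genes)
        return out


def overlap_table(lists: dict[str, list[str]]) -> OverlapTable:
    """Venn-region counts for 2–4 named gene lists."""
    if not 2 <= len(lists) <= 4:
        raise ValueError("overlap_table supports 2 to 4 lists")
    names = list(lists)
    as_sets = {n: set(v) for n, v in lists.items()}
    if any(not s for s in as_sets.values()):
        raise ValueError("all lists must be non-empty")
    regions: dict[tuple[bool, ...], list[str]] = {}
    union = set().union(*as_sets.values())
    for pattern in itertools.product([False, True], repeat=len(names)):
        if not any(pattern):
            continue
        members = union.copy()
        for name, inside in zip(names, pattern):
            members = members & as_sets[name] if inside else members - as_sets[name]
        regions[pattern] = sorted(members)
    return OverlapTable(list_names=names, regions=regions)
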