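"""Context-free biological process linkage (the Dotan-Cohen-style baseline).

Process A links to process B when an unexpectedly large number of the network
neighbors of A's genes — genes not themselves annotated with A — are annotated
with B, judged by the tail of a hypergeometric distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, List

from scipy.stats import hypergeom

from .model import (
    GeneSetCollection,
    LinkRecord,
    ValidationError,
    WeightedNetwork,
)
from .null_models import bh_adjust_monotone


@dataclass(frozen=True)
class NeighborSets:
    """N(A): genes adjacent to A-annotated genes, not annotated with A.
    N(A,B): the members of N(A) additionally annotated with B."""

    n_a: FrozenSet[str]
    n_ab: FrozenSet[str]

    def __post_init__(self):
        if not self.n_ab <= self.n_a:
            raise ValidationError("N(A,B) must be a subset of N(A)")


def neighbor_sets(
    network: WeightedNetwork,
    genesets: GeneSetCollection,
    source: str,
    target: str,
) -> NeighborSets:
    """Compute N(A) and N(A,B) for the ordered pair (source=A, target=B)."""
    ga = genesets.genes_of(source)
    gb = genesets.genes_of(target)
    n_a = set()
    for g in ga:
        if network.has_node(g):
            for nb, _ in network.neighbors(g):
                if nb not in ga:
                    n_a.add(nb)
    return NeighborSets(frozenset(n_a), frozenset(n_a & gb))


def hypergeometric_tail(population: int, successes: int, draws: int, observed: int) -> float:
    """Upper tail P(X >= observed) for X ~ Hypergeom(population, successes, draws)."""
    if not (0 <= successes <= population):
        raise ValidationError(f"successes {successes} outside [0, population={population}]")
    if not (0 <= draws <= population):
        raise ValidationError(f"draws {draws} outside [0, population={population}]")
    if not (0 <= observed <= min(successes, draws)):
        raise ValidationError(
            f"observed {observed} outside [0, min(successes, draws)={min(successes, draws)}]"
        )
    return float(hypergeom.sf(observed - 1, population, successes, draws))


def bpln_link_pvalue(
    network: WeightedNetwork,
    genesets: GeneSetCollection,
    source: str,
    target: str,
    population: str = "exclude_source",
) -> float:
    """Hypergeometric link p-value for the ordered pair (source, target).

    ``population`` selects the sampling frame for the |N(A)| random draws:
    ``"exclude_source"`` (default) draws from U \\ G_A, consistent with N(A)
    never containing A-annotated genes; ``"universe"`` draws from all of U.
    """
    ga = genesets.genes_of(source)
    gb = genesets.genes_of(target)
    u = genesets.universe
    ns = neighbor_sets(network, genesets, source, target)
    if population == "exclude_source":
        pop = len(u - ga)
        succ = len((gb - ga) & u)
    elif population == "universe":
        pop = len(u)
        succ = len(gb & u)
    else:
        raise ValidationError(f"unknown population convention {population!r}")
    draws = len(ns.n_a)
    observed = len(ns.n_ab)
    return hypergeometric_tail(pop, succ, draws, observed)


def build_bpln(
    network: WeightedNetwork,
    genesets: GeneSetCollection,
    alpha: float = 0.01,
    min_interactors: int = 10,
    population: str = "exclude_source",
) -> List[LinkRecord]:
    """Evaluate all ordered pairs with |N(A,B)| >= min_interactors and flag
    significance by BH-adjusted hypergeometric p <= alpha (``bpln_q``).

    The network is first restricted to the annotated universe so the
    neighborhoods live inside the hypergeometric sampling frame.
    """
    processes = genesets.processes
    if len(processes) < 2:
        raise ValidationError("need at least two processes")
    from .io import restrict_to_annotated

    network = restrict_to_annotated(network, genesets)
    records: List[LinkRecord] = []
    for a in processes:
        for b in processes:
            if a == b:
                continue
            ns = neighbor_sets(network, genesets, a, b)
            if len(ns.n_ab) < min_interactors:
                continue
            p = bpln_link_pvalue(network, genesets, a, b, population=population)
            records.append(
                LinkRecord(
                    source=a,
                    target=b,
                    n_neighbors=len(ns.n_a),
                    n_linked=len(ns.n_ab),
                    score=float(len(ns.n_ab)),
                    background=0.0,
                    normalized=float(len(ns.n_ab)),
                    bpln_p=p,
                )
            )
    if records:
        qs = bh_adjust_monotone([r.bpln_p for r in records])
        for rec, q in zip(records, qs):
            rec.bpln_q = float(q)
    return records


def significant_bpln_links(records: List[LinkRecord], alpha: float = 0.01):
    return {(r.source, r.target) for r in records if r.bpln_q is not None and r.bpln_q <= alpha}
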