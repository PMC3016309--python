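"""The contextual linkage score.

For an ordered process pair (A, B), every gene v in N(A,B) — a neighbor of
A's genes, not annotated with A, annotated with B — contributes

    s(v) * f_A(v),    f_A(v) = max over neighbors u of v with u in G_A
                               of w(u, v) * s(u),

i.e. its own perturbation times the best confidence-weighted perturbation
among its A-annotated neighbors. S(A, B) is the sum of contributions. With
unit scores and unit weights S(A, B) reduces to the plain neighbor count
|N(A,B)| of the context-free baseline.

The normalized score subtracts the background S_bg obtained by giving every
gene the average perturbation score: what the link would score if expression
carried no gene-specific information.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .bpln import neighbor_sets
from .model import (
    GeneSetCollection,
    PerturbationTable,
    ValidationError,
    WeightedNetwork,
)

Contributions = Dict[str, Tuple[float, float, float]]


def neighbor_contribution(
    network: WeightedNetwork,
    scores: PerturbationTable,
    genesets: GeneSetCollection,
    source: str,
    gene: str,
) -> float:
    """f_A(gene): maximum weighted perturbation among the gene's neighbors
    annotated with the source process; 0.0 if there is none."""
    ga = genesets.genes_of(source)
    best = 0.0
    if network.has_node(gene):
        for u, w in network.neighbors(gene):
            if u in ga:
                c = w * scores.score(u)
                if c > best:
                    best = c
    return best


def contextual_linkage_score(
    network: WeightedNetwork,
    scores: PerturbationTable,
    genesets: GeneSetCollection,
    source: str,
    target: str,
) -> Tuple[float, Contributions]:
    """S(A, B) and the per-gene contribution terms (s(v), f_A(v), product)."""
    ns = neighbor_sets(network, genesets, source, target)
    contributions: Contributions = {}
    total = 0.0
    for v in sorted(ns.n_ab):
        f = neighbor_contribution(network, scores, genesets, source, v)
        sv = scores.score(v)
        contributions[v] = (sv, f, sv * f)
        total += sv * f
    return total, contributions


def background_table(
    scores: PerturbationTable,
    genesets: GeneSetCollection,
    network: WeightedNetwork = None,
) -> PerturbationTable:
    """A table giving every gene the mean score over measured genes in U."""
    measured = scores.measured_genes & set(genesets.universe)
    if not measured:
        raise ValidationError("no measured genes in the annotated universe")
    mean = sum(scores.score(g) for g in measured) / len(measured)
    genes = set(genesets.universe)
    if network is not None:
        genes |= network.nodes
    return PerturbationTable({g: mean for g in genes}, measured=measured)


def background_score(
    network: WeightedNetwork,
    scores: PerturbationTable,
    genesets: GeneSetCollection,
    source: str,
    target: str,
) -> float:
    """S_bg(A, B): the contextual linkage score recomputed with every gene's
    perturbation replaced by the average over measured genes in U."""
    bg, _ = contextual_linkage_score(
        network, background_table(scores, genesets, network), genesets, source, target
    )
    return bg


def normalized_score(score: float, background: float) -> float:
    """S_norm = S - S_bg; may be negative when the link is less perturbed
    than average expression would predict."""
    return score - background
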