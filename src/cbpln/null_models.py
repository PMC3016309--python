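"""Empirical significance for contextual linkage scores.

Two bespoke null models:

* **Gene-set randomization** — permute gene labels on the gene-process
  bipartite graph. Every process keeps its size and any group of processes
  keeps its exact co-annotation counts; one ordered pair's randomized target
  set is a uniform random set of the same size drawn from the universe.
* **Network randomization** — degree-preserving edge swaps: repeatedly pick
  two edges, propose one of the two rewirings of their endpoints with equal
  probability, and apply it only if it creates neither a self-loop nor an
  existing edge.

The empirical link p-value is the fraction of null scores strictly larger
than the observed score (a (count+1)/(R+1) variant is available since the
strict rule can return exactly 0). Multiple testing is handled by
Benjamini-Hochberg with monotone adjusted values.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._engine import ScoreEngine
from ._swap import swap_edge_arrays
from .model import (
    GeneSetCollection,
    PerturbationTable,
    ValidationError,
    WeightedNetwork,
)


@dataclass
class NullDistribution:
    """R replicate values of the (optionally normalized) linkage score under
    one of the two null models."""

    values: np.ndarray
    generator: str
    seed: int

    def __len__(self) -> int:
        return int(self.values.shape[0])


def child_rng(seed: int, *tokens) -> np.random.Generator:
    """Deterministic stream derived from (seed, tokens); independent of the
    order in which pairs or replicates are evaluated."""
    entropy = [seed & 0xFFFFFFFF] + [zlib.crc32(str(t).encode("utf8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _as_rng(seed_or_rng: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng & 0xFFFFFFFF)


def permute_annotations(
    genesets: GeneSetCollection, seed: Union[int, np.random.Generator]
) -> GeneSetCollection:
    """One uniform random permutation of gene labels on the gene-process
    bipartite graph. Set sizes and all k-wise co-annotation counts are
    preserved exactly."""
    rng = _as_rng(seed)
    universe = sorted(genesets.universe)
    perm = rng.permutation(len(universe))
    mapping = {universe[i]: universe[perm[i]] for i in range(len(universe))}
    new_sets = {name: frozenset(mapping[g] for g in s) for name, s in genesets.sets.items()}
    return GeneSetCollection(new_sets, dict(genesets.descriptions))


def swap_edges(
    network: WeightedNetwork, q: int, seed: Union[int, np.random.Generator]
) -> WeightedNetwork:
    """Degree-preserving randomization with q * |E| swap attempts."""
    if q < 0:
        raise ValidationError("swap multiplier must be >= 0")
    rng = _as_rng(seed)
    nodes = sorted(network.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    rows = sorted((min(u, v), max(u, v), w) for u, v, w in network.edges())
    eu = np.array([index[u] for u, _, _ in rows], dtype=np.int64)
    ev = np.array([index[v] for _, v, _ in rows], dtype=np.int64)
    ew = [w for _, _, w in rows]
    eu, ev = swap_edge_arrays(eu, ev, len(nodes), q, rng)
    g = WeightedNetwork.from_edges(
        (nodes[int(a)], nodes[int(b)], w) for a, b, w in zip(eu, ev, ew)
    )
    g.graph.add_nodes_from(nodes)  # degrees are preserved, so this only re-adds existing nodes
    return g


def geneset_null_distribution(
    network: WeightedNetwork,
    scores: PerturbationTable,
    genesets: GeneSetCollection,
    source: str,
    target: str,
    permutations: int,
    seed: int,
    normalize: bool = True,
    randomize_set: str = "target",
    engine: Optional[ScoreEngine] = None,
) -> NullDistribution:
    """Null scores for one ordered pair under annotation-label permutation.

    By default the *target* set is replaced by its randomized counterpart
    while the source set and the network stay fixed (``randomize_set`` may
    instead randomize the source). Replicate r uses the stream derived from
    (seed, "geneset", source, target, r).
    """
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")
    eng = engine if engine is not None else ScoreEngine(network, genesets, scores)
    a = eng.proc_index[source]
    b = eng.proc_index[target]
    uidx = eng.uidx
    upos = {int(g): i for i, g in enumerate(uidx)}
    pos_b = np.array([upos[int(g)] for g in np.nonzero(eng.memb[:, b])[0]], dtype=np.int64)
    pos_a = np.array([upos[int(g)] for g in np.nonzero(eng.memb[:, a])[0]], dtype=np.int64)
    term = eng.term_rows()[a]
    bg_term = eng.term_rows(s=np.full(eng.n, eng.bg_mean))[a]
    memb_b = eng.memb[:, b]

    values = np.empty(permutations)
    for r in range(permutations):
        rng = child_rng(seed, "geneset", source, target, r)
        perm = rng.permutation(uidx.shape[0])
        if randomize_set == "target":
            sel = uidx[perm[pos_b]]
            v = float(term[sel].sum())
            if normalize:
                v -= float(bg_term[sel].sum())
        elif randomize_set == "source":
            ina = np.zeros(eng.n, dtype=bool)
            ina[uidx[perm[pos_a]]] = True
            memb_rows = ina[:, None]
            t = eng.term_rows(memb=memb_rows)[0]
            v = float(t @ memb_b)
            if normalize:
                tbg = eng.term_rows(memb=memb_rows, s=np.full(eng.n, eng.bg_mean))[0]
                v -= float(tbg @ memb_b)
        else:
            raise ValidationError("randomize_set must be 'target' or 'source'")
        values[r] = v
    return NullDistribution(values, "geneset", seed)


def network_null_distribution(
    network: WeightedNetwork,
    scores: PerturbationTable,
    genesets: GeneSetCollection,
    source: str,
    target: str,
    permutations: int,
    swap_multiplier: int,
    seed: int,
    normalize: bool = True,
    engine: Optional[ScoreEngine] = None,
) -> NullDistribution:
    """Null scores for one ordered pair under degree-preserving edge swaps,
    annotations held fixed. Replicate r uses the stream derived from
    (seed, "network", source, target, r)."""
    if permutations < 1:
        raise ValidationError("permutations must be >= 1")
    eng = engine if engine is not None else ScoreEngine(network, genesets, scores)
    a = eng.proc_index[source]
    memb_b = eng.memb[:, eng.proc_index[target]]
    s_bg = np.full(eng.n, eng.bg_mean)

    values = np.empty(permutations)
    for r in range(permutations):
        rng = child_rng(seed, "network", source, target, r)
        eu, ev = swap_edge_arrays(eng.eu, eng.ev, eng.n, swap_multiplier, rng)
        edges = (eu, ev, eng.ew)
        v = float(eng.term_rows(edges=edges)[a] @ memb_b)
        if normalize:
            v -= float(eng.term_rows(s=s_bg, edges=edges)[a] @ memb_b)
        values[r] = v
    return NullDistribution(values, "network", seed)


def empirical_pvalue(
    observed: float, null: NullDistribution, pseudo_count: bool = False
) -> float:
    """Fraction of null scores strictly larger than the observed score; with
    ``pseudo_count`` the (count+1)/(R+1) estimator that never returns 0."""
    r = len(null)
    if r == 0:
        raise ValidationError("empty null distribution")
    count = int(np.sum(null.values > observed))
    if pseudo_count:
        return (count + 1) / (r + 1)
    return count / r


def bh_adjust_monotone(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone non-decreasing
    in the raw-p ordering and capped at 1; output order matches input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
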