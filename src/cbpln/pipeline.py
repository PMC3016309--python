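"""End-to-end computation of a contextual process-linkage network for one
biological contrast, plus the link-set comparison statistics.

The pipeline restricts the interaction network to the annotated universe,
enumerates ordered process pairs, drops pairs with fewer than K linking
genes, scores the survivors, runs the configured permutation tests with R
replicates each, BH-adjusts per test across the surviving pairs, and keeps
as directed links exactly the pairs whose adjusted p-value passes the FDR
cutoff under every configured test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
from scipy.stats import fisher_exact

from ._engine import ScoreEngine
from ._swap import swap_edge_arrays
from .io import restrict_to_annotated
from .model import (
    CBPLNGraph,
    GeneSetCollection,
    LinkRecord,
    PerturbationTable,
    PipelineConfig,
    ValidationError,
    WeightedNetwork,
)
from .null_models import (
    bh_adjust_monotone,
    child_rng,
    empirical_pvalue,
    geneset_null_distribution,
    network_null_distribution,
)
from .scoring import contextual_linkage_score, background_score

logger = logging.getLogger("cbpln")

Pair = Tuple[str, str]


def _shared_null_pvalues(
    engine: ScoreEngine,
    stat_obs: np.ndarray,
    test: str,
    config: PipelineConfig,
) -> np.ndarray:
    """p-value matrix for all ordered pairs under one test, scoring a single
    randomized annotation set / network per replicate against every pair."""
    r_total = config.permutations
    counts = np.zeros_like(stat_obs)
    term = engine.term_rows()
    bg_s = np.full(engine.n, engine.bg_mean)
    term_bg = engine.term_rows(s=bg_s)
    for r in range(r_total):
        rng = child_rng(config.seed, test, "shared", r)
        if test == "geneset":
            memb_p = engine.permuted_membership(rng)
            if config.randomize_set == "target":
                s_null = term @ memb_p
                bg_null = term_bg @ memb_p
            else:
                s_null = engine.term_rows(memb=memb_p) @ engine.memb
                bg_null = engine.term_rows(memb=memb_p, s=bg_s) @ engine.memb
        else:
            eu, ev = swap_edge_arrays(engine.eu, engine.ev, engine.n, config.swap_multiplier, rng)
            edges = (eu, ev, engine.ew)
            s_null = engine.term_rows(edges=edges) @ engine.memb
            bg_null = engine.term_rows(s=bg_s, edges=edges) @ engine.memb
        stat_null = s_null - bg_null if config.normalize else s_null
        counts += stat_null > stat_obs
    if config.pseudo_count:
        return (counts + 1.0) / (r_total + 1.0)
    return counts / r_total


def compute_cbpln(
    network: WeightedNetwork,
    genesets: GeneSetCollection,
    perturbation: PerturbationTable,
    config: PipelineConfig,
) -> Tuple[List[LinkRecord], CBPLNGraph]:
    """Full pipeline for one contrast; returns every evaluated pair as a
    LinkRecord plus the directed graph of links passing all filters."""
    if len(genesets) < 2:
        raise ValidationError("need at least two processes")
    net = restrict_to_annotated(network, genesets)
    engine = ScoreEngine(net, genesets, perturbation)
    procs = engine.processes
    n_a, n_ab = engine.count_matrices()

    candidates: List[Tuple[int, int]] = [
        (i, j)
        for i in range(len(procs))
        for j in range(len(procs))
        if i != j and n_ab[i, j] >= config.min_interactors
    ]
    if not candidates:
        logger.warning("no ordered pair passes the >=%d interactor filter", config.min_interactors)
        return [], CBPLNGraph.from_records([])

    s_mat, bg_mat = engine.score_matrices()
    stat_obs = s_mat - bg_mat if config.normalize else s_mat

    pmats: Dict[str, np.ndarray] = {}
    for test in config.tests:
        logger.info("running %s randomization: R=%d seed=%d", test, config.permutations, config.seed)
        if config.shared_replicates:
            pmats[test] = _shared_null_pvalues(engine, stat_obs, test, config)
        else:
            pmat = np.full_like(stat_obs, np.nan)
            for i, j in candidates:
                a, b = procs[i], procs[j]
                if test == "geneset":
                    null = geneset_null_distribution(
                        net, perturbation, genesets, a, b,
                        config.permutations, config.seed,
                        normalize=config.normalize,
                        randomize_set=config.randomize_set,
                        engine=engine,
                    )
                else:
                    null = network_null_distribution(
                        net, perturbation, genesets, a, b,
                        config.permutations, config.swap_multiplier, config.seed,
                        normalize=config.normalize, engine=engine,
                    )
                pmat[i, j] = empirical_pvalue(
                    stat_obs[i, j], null, pseudo_count=config.pseudo_count
                )
            pmats[test] = pmat

    qmats: Dict[str, Dict[Tuple[int, int], float]] = {}
    for test in config.tests:
        raw = [pmats[test][i, j] for i, j in candidates]
        adj = bh_adjust_monotone(raw)
        qmats[test] = {pair: float(q) for pair, q in zip(candidates, adj)}

    records: List[LinkRecord] = []
    passing: List[LinkRecord] = []
    for i, j in sorted(candidates, key=lambda ij: (procs[ij[0]], procs[ij[1]])):
        a, b = procs[i], procs[j]
        score, contributions = contextual_linkage_score(net, perturbation, genesets, a, b)
        background = background_score(net, perturbation, genesets, a, b)
        rec = LinkRecord(
            source=a,
            target=b,
            n_neighbors=int(n_a[i]),
            n_linked=int(n_ab[i, j]),
            score=score,
            background=background,
            normalized=score - background,
            p_geneset=float(pmats["geneset"][i, j]) if "geneset" in pmats else None,
            p_network=float(pmats["network"][i, j]) if "network" in pmats else None,
            q_geneset=qmats.get("geneset", {}).get((i, j)),
            q_network=qmats.get("network", {}).get((i, j)),
            contributions=contributions,
        )
        records.append(rec)
        if all(qmats[test][(i, j)] <= config.fdr_alpha for test in config.tests):
            passing.append(rec)
    graph = CBPLNGraph.from_records(passing)
    logger.info("%d candidate pairs, %d links pass all filters", len(records), len(graph))
    return records, graph


def fisher_exact_one_sided(table: Sequence[Sequence[int]]) -> float:
    """One-sided (enrichment) Fisher's exact p for a 2x2 contingency table."""
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if np.any(arr < 0):
        raise ValidationError("counts must be non-negative")
    return float(fisher_exact(arr, alternative="greater")[1])


@dataclass(frozen=True)
class ComparisonResult:
    """Overlap statistics between two link sets over a candidate universe:
    intersection size, Jaccard index, and the one-sided Fisher p for the
    2x2 table {in both, first only, second only, neither}."""

    n_first: int
    n_second: int
    n_intersection: int
    jaccard: float
    fisher_p: float
    contingency: Tuple[Tuple[int, int], Tuple[int, int]]


def compare_link_sets(
    first: Set[Pair], second: Set[Pair], candidates: Set[Pair]
) -> ComparisonResult:
    if not first <= candidates or not second <= candidates:
        raise ValidationError("link sets must be subsets of the candidate pairs")
    inter = len(first & second)
    union = len(first | second)
    table = (
        (inter, len(first - second)),
        (len(second - first), len(candidates) - union),
    )
    return ComparisonResult(
        n_first=len(first),
        n_second=len(second),
        n_intersection=inter,
        jaccard=(inter / union) if union else 0.0,
        fisher_p=fisher_exact_one_sided(table),
        contingency=table,
    )
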