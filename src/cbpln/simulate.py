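"""Synthetic benchmark fixtures with planted inter-process links.

The generator emulates the three pipeline inputs — a confidence-weighted
interaction network (STRING-style integer weights), a gene-set collection,
and a per-gene differential-expression p-value table — with a known ground
truth: for each planted process pair {A, B}, extra high-weight edges run
between A-exclusive and B-exclusive genes, and the genes incident to those
edges receive small expression p-values. Everything else is background:
sparse random edges and uniform p-values.

Because the planted edges are undirected and both endpoint sets carry
perturbation, a planted linkage is signal in *both* directions; the truth
therefore records both ordered pairs (A, B) and (B, A) for every planted
pair. Genuinely one-directional fixtures are built by making one side's
linking-gene count fall below the interactor filter (see the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Set, Tuple

import numpy as np

from .bpln import neighbor_sets
from .io import write_gene_sets, write_network, write_perturbation
from .model import (
    GeneSetCollection,
    PerturbationTable,
    ValidationError,
    WeightedNetwork,
)

Pair = Tuple[str, str]


class GenerationError(RuntimeError):
    """Raised when a planted constraint cannot be met within bounded retries."""


@dataclass(frozen=True)
class FixtureParams:
    """Generator settings; together with ``seed`` they fully determine the
    fixture. Defaults give 9 processes of 25-40 genes on a 500-gene pool with
    5 planted pairs (10 ordered planted links) — small enough that the full
    pipeline runs in minutes, large enough that >=50 non-planted ordered
    pairs survive the interactor filter."""

    n_genes: int = 500
    n_processes: int = 9
    size_min: int = 25
    size_max: int = 40
    overlap_fraction: float = 0.1
    background_edge_p: float = 0.02
    n_planted: int = 5
    planted_edge_p: float = 0.3
    weight_raw_min: int = 500
    weight_raw_max: int = 1000
    planted_weight_raw_min: int = 900
    planted_weight_raw_max: int = 1000
    perturbed_p_max: float = 0.001
    min_interactors: int = 10
    max_retries: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_processes < 1 or self.size_min < 1:
            raise ValidationError("sizes must be >= 1")
        for p in (self.overlap_fraction, self.background_edge_p, self.planted_edge_p):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureTruth:
    """Ground truth of one generated fixture."""

    planted_links: FrozenSet[Pair]
    params: FixtureParams
    perturbed_genes: FrozenSet[str] = field(default_factory=frozenset)


def _draw_processes(params: FixtureParams, rng: np.random.Generator, genes) -> Dict[str, frozenset]:
    sets: Dict[str, frozenset] = {}
    assigned: Set[str] = set()
    for i in range(params.n_processes):
        size = int(rng.integers(params.size_min, params.size_max + 1))
        n_overlap = min(int(round(params.overlap_fraction * size)), len(assigned))
        members: Set[str] = set()
        if n_overlap:
            members |= set(rng.choice(sorted(assigned), size=n_overlap, replace=False).tolist())
        pool = [g for g in genes if g not in assigned and g not in members]
        need = size - len(members)
        if need > len(pool):
            pool = [g for g in genes if g not in members]
        members |= set(rng.choice(pool, size=need, replace=False).tolist())
        sets[f"P{i + 1:02d}"] = frozenset(members)
        assigned |= members
    return sets


def _background_edges(params: FixtureParams, rng: np.random.Generator, genes) -> Dict[frozenset, float]:
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.shape[0]) < params.background_edge_p
    iu, ju = iu[mask], ju[mask]
    raw = rng.integers(params.weight_raw_min, params.weight_raw_max + 1, size=iu.shape[0])
    return {
        frozenset((genes[int(a)], genes[int(b)])): int(w) / 1000.0
        for a, b, w in zip(iu, ju, raw)
    }


def _cross_edges(
    params: FixtureParams, rng: np.random.Generator, a_excl, b_excl
) -> Dict[frozenset, float]:
    edges: Dict[frozenset, float] = {}
    for u in a_excl:
        for v in b_excl:
            if rng.random() < params.planted_edge_p:
                raw = int(rng.integers(params.planted_weight_raw_min, params.planted_weight_raw_max + 1))
                edges[frozenset((u, v))] = raw / 1000.0
    return edges


def generate_fixture(
    params: FixtureParams,
) -> Tuple[WeightedNetwork, GeneSetCollection, PerturbationTable, FixtureTruth]:
    """Generate one fixture; identical params (including seed) give
    byte-identical outputs."""
    rng = np.random.default_rng(params.seed & 0xFFFFFFFF)
    genes = [f"g{i + 1:04d}" for i in range(params.n_genes)]

    sets = _draw_processes(params, rng, genes)
    genesets = GeneSetCollection(sets, {name: "synthetic process" for name in sets})
    procs = sorted(sets)

    # planted unordered pairs; truth records both directions of each.
    # No process joins more than two planted pairs: concentrating many
    # planted pairs on one hub process fattens that hub's network-null tail
    # and blurs the per-pair truth.
    n_pairs_max = len(procs) * (len(procs) - 1) // 2
    if params.n_planted > n_pairs_max:
        raise ValidationError("more planted links than unordered process pairs")
    unordered = [(procs[i], procs[j]) for i in range(len(procs)) for j in range(i + 1, len(procs))]
    order = rng.permutation(len(unordered))
    planted: Set[Pair] = set()
    multiplicity: Dict[str, int] = {}
    for k in order:
        if len(planted) >= 2 * params.n_planted:
            break
        a, b = unordered[int(k)]
        if multiplicity.get(a, 0) >= 2 or multiplicity.get(b, 0) >= 2:
            continue
        planted.add((a, b))
        planted.add((b, a))
        multiplicity[a] = multiplicity.get(a, 0) + 1
        multiplicity[b] = multiplicity.get(b, 0) + 1
    if len(planted) < 2 * params.n_planted:
        raise GenerationError("could not place the requested planted pairs")

    edges = _background_edges(params, rng, genes)

    # planted edges connect genes PRIVATE to each planted process (annotated
    # with no other process): a shared gene would carry the planted wiring
    # and perturbation into third processes, making the truth inseparable
    planted_edge_keys: Set[frozenset] = set()
    for a, b in sorted(p for p in planted if p[0] < p[1]):
        others: Set[str] = set()
        for name, members in sets.items():
            if name not in (a, b):
                others |= members
        a_excl = sorted(sets[a] - sets[b] - others)
        b_excl = sorted(sets[b] - sets[a] - others)
        for attempt in range(params.max_retries + 1):
            cross = _cross_edges(params, rng, a_excl, b_excl)
            trial = dict(edges)
            for key, w in cross.items():
                trial[key] = max(trial.get(key, 0.0), w)
            net = WeightedNetwork.from_edges((*sorted(key), w) for key, w in trial.items())
            ok = all(
                len(neighbor_sets(net, genesets, x, y).n_ab) >= params.min_interactors
                for x, y in ((a, b), (b, a))
            )
            if ok:
                edges = trial
                planted_edge_keys |= set(cross)
                break
        else:
            raise GenerationError(
                f"planted pair ({a}, {b}): |N(A,B)| < {params.min_interactors} "
                f"after {params.max_retries} retries"
            )

    network = WeightedNetwork.from_edges((*sorted(key), w) for key, w in edges.items())

    perturbed: Set[str] = set()
    for key in planted_edge_keys:
        perturbed |= set(key)
    pvals: Dict[str, float] = {}
    for g in genes:
        if g in perturbed:
            pvals[g] = float(rng.uniform(0.0, params.perturbed_p_max))
        else:
            pvals[g] = float(rng.uniform(0.0, 1.0))
    table = PerturbationTable.from_pvalues(pvals, log_base=10.0)

    truth = FixtureTruth(frozenset(planted), params, frozenset(perturbed))
    return network, genesets, table, truth


def write_fixture(
    out_dir,
    network: WeightedNetwork,
    genesets: GeneSetCollection,
    table: PerturbationTable,
    truth: FixtureTruth,
) -> None:
    """Write the three input files (network weights as STRING-style raw
    integers) plus the planted-link truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(network, out / "network.tsv", weight_scale=1000.0)
    write_gene_sets(genesets, out / "gene_sets.gmt")
    write_perturbation(table, out / "perturbation.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("source\ttarget\n")
        for a, b in sorted(truth.planted_links):
            fh.write(f"{a}\t{b}\n")


def generate_directional_fixture(
    seed: int = 0,
) -> Tuple[WeightedNetwork, GeneSetCollection, PerturbationTable, Pair]:
    """A fixture where the linkage is one-directional by construction.

    Five hub genes of the source set SRC carry dense high-weight edges into
    most of the 30 target-set (TGT) genes; hubs and targets are strongly
    perturbed; background wiring is very sparse. Reading SRC→TGT, ~30 TGT
    genes link to SRC (a strong candidate); reading TGT→SRC, only the few
    hubs link back, which falls below the default 10-interactor filter —
    so only the forward link can be called. Returns the pair (SRC, TGT).
    """
    rng = np.random.default_rng(seed & 0xFFFFFFFF)
    blocks = {
        "SRC": [f"s{i:02d}" for i in range(25)],
        "TGT": [f"t{i:02d}" for i in range(30)],
        "BG1": [f"u{i:02d}" for i in range(20)],
        "BG2": [f"v{i:02d}" for i in range(20)],
        "FILL": [f"f{i:02d}" for i in range(60)],
    }
    genesets = GeneSetCollection({k: frozenset(v) for k, v in blocks.items()})
    genes = [g for block in blocks.values() for g in block]

    edges: Dict[frozenset, float] = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if rng.random() < 0.002:
                edges[frozenset((genes[i], genes[j]))] = int(rng.integers(500, 1001)) / 1000.0
    hubs = blocks["SRC"][:5]
    for h in hubs:
        for t in blocks["TGT"]:
            if rng.random() < 0.8:
                edges[frozenset((h, t))] = int(rng.integers(900, 1001)) / 1000.0
    network = WeightedNetwork.from_edges((*sorted(k), w) for k, w in edges.items())

    hot = set(hubs) | set(blocks["TGT"])
    pvals = {
        g: float(rng.uniform(0.0, 1e-4)) if g in hot else float(rng.uniform(0.0, 1.0))
        for g in genes
    }
    table = PerturbationTable.from_pvalues(pvals)
    return network, genesets, table, ("SRC", "TGT")


def evaluate_recovery(
    called_links: Set[Pair], truth: FixtureTruth, candidates: Set[Pair]
) -> Tuple[float, float]:
    """(power, false-positive fraction) of a called link set against the
    planted truth, over the candidate pair universe."""
    if not called_links <= candidates:
        raise ValidationError("called links must be a subset of the candidates")
    planted = set(truth.planted_links)
    if not planted:
        raise ValidationError("fixture has no planted links")
    power = len(called_links & planted) / len(planted)
    negatives = candidates - planted
    fpf = (len(called_links - planted) / len(negatives)) if negatives else 0.0
    return power, fpf
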