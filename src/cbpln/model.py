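"""Core domain types: gene-set collections, weighted interaction networks,
perturbation tables, link records, and pipeline configuration.

Gene identifiers are opaque, case-sensitive strings throughout; matching
identifier namespaces across the three inputs is the caller's responsibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

import networkx as nx


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the offending line."""


class LookupError_(KeyError):
    """Raised when a process or gene identifier is unknown."""


@dataclass(frozen=True)
class GeneSetCollection:
    """Processes and their gene memberships.

    ``sets`` maps a process identifier to its (non-empty) gene set; the
    *universe* is the union of all sets — the set of genes annotated by at
    least one process, which is also the sampling frame for randomization
    and enrichment.
    """

    sets: Mapping[str, frozenset]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
        object.__setattr__(self, "sets", {k: frozenset(v) for k, v in self.sets.items()})
        object.__setattr__(self, "_universe", frozenset().union(*self.sets.values()))

    @property
    def universe(self) -> frozenset:
        """All genes annotated by at least one process (cached)."""
        return self._universe

    @property
    def processes(self) -> List[str]:
        return sorted(self.sets)

    def genes_of(self, process: str) -> frozenset:
        try:
            return self.sets[process]
        except KeyError:
            raise LookupError_(f"unknown process {process!r}") from None

    def __contains__(self, process: str) -> bool:
        return process in self.sets

    def __len__(self) -> int:
        return len(self.sets)


class WeightedNetwork:
    """Undirected simple graph over genes with positive confidence weights.

    Backed by a :class:`networkx.Graph`; no self-loops, no duplicate edges,
    every weight strictly positive.
    """

    def __init__(self, graph: Optional[nx.Graph] = None):
        self.graph = graph if graph is not None else nx.Graph()
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if w is None or not (w > 0):
                raise ValidationError(f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")

    @classmethod
    def from_edges(cls, edges: Iterable[Tuple[str, str, float]]) -> "WeightedNetwork":
        g = nx.Graph()
        for u, v, w in edges:
            g.add_edge(u, v, weight=float(w))
        return cls(g)

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    def edges(self) -> Iterator[Tuple[str, str, float]]:
        for u, v, w in self.graph.edges(data="weight"):
            yield u, v, w

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def has_node(self, g: str) -> bool:
        return g in self.graph

    def weight(self, u: str, v: str) -> float:
        return self.graph[u][v]["weight"]

    def neighbors(self, v: str) -> Iterator[Tuple[str, float]]:
        """Yield ``(neighbor, weight)`` pairs of ``v``."""
        for u, data in self.graph[v].items():
            yield u, data["weight"]

    def degree_sequence(self) -> Dict[str, int]:
        return dict(self.graph.degree())

    def weight_multiset(self) -> List[float]:
        return sorted(w for _, _, w in self.edges())

    def edge_key_set(self) -> Set[frozenset]:
        return {frozenset((u, v)) for u, v, _ in self.edges()}

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.graph.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        mine = {frozenset((u, v)): w for u, v, w in self.edges()}
        theirs = {frozenset((u, v)): w for u, v, w in other.edges()}
        return mine == theirs


class PerturbationTable:
    """Per-gene expression p-values and derived perturbation scores.

    The perturbation score is ``s(g) = |log_b p(g)|`` — large when the gene is
    strongly differentially expressed, zero at p = 1. Genes absent from the
    table score 0 when queried (no expression evidence contributes nothing).
    """

    def __init__(
        self,
        scores: Mapping[str, float],
        pvalues: Optional[Mapping[str, float]] = None,
        measured: Optional[Iterable[str]] = None,
    ):
        for g, s in scores.items():
            if not (s >= 0):
                raise ValidationError(f"negative perturbation score for gene {g!r}: {s}")
        self.scores: Dict[str, float] = dict(scores)
        self.pvalues: Optional[Dict[str, float]] = dict(pvalues) if pvalues is not None else None
        self._measured: Optional[Set[str]] = set(measured) if measured is not None else None

    @classmethod
    def from_pvalues(
        cls,
        pvalues: Mapping[str, float],
        log_base: float = 10.0,
        pvalue_floor: float = 1e-300,
    ) -> "PerturbationTable":
        if not (log_base > 1):
            raise ValidationError(f"log_base must exceed 1, got {log_base}")
        floored: Dict[str, float] = {}
        scores: Dict[str, float] = {}
        lb = math.log(log_base)
        for g, p in pvalues.items():
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"p-value for gene {g!r} outside [0, 1]: {p}")
            p = max(p, pvalue_floor)
            floored[g] = p
            scores[g] = abs(math.log(p) / lb)
        return cls(scores, floored)

    def score(self, gene: str) -> float:
        return self.scores.get(gene, 0.0)

    @property
    def measured_genes(self) -> Set[str]:
        """Genes carrying expression evidence (those with a p-value, or with
        an explicit score when the table was built from scores directly)."""
        if self._measured is not None:
            return set(self._measured)
        if self.pvalues is not None:
            return set(self.pvalues)
        return set(self.scores)

    def scaled(self, c: float) -> "PerturbationTable":
        """A copy with every score multiplied by ``c`` (> 0); the measured-gene
        set is preserved, p-values dropped (they no longer match the scores)."""
        if not (c > 0):
            raise ValidationError("scale factor must be positive")
        return PerturbationTable(
            {g: s * c for g, s in self.scores.items()},
            measured=self.measured_genes,
        )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class LinkRecord:
    """One ordered process pair with its counts, scores and p-values.

    ``contributions`` maps each linking gene v in N(A,B) to the triple
    ``(s(v), f_A(v), s(v) * f_A(v))`` whose products sum to the score.
    """

    source: str
    target: str
    n_neighbors: int
    n_linked: int
    score: float
    background: float
    normalized: float
    p_geneset: Optional[float] = None
    p_network: Optional[float] = None
    q_geneset: Optional[float] = None
    q_network: Optional[float] = None
    bpln_p: Optional[float] = None
    bpln_q: Optional[float] = None
    contributions: Dict[str, Tuple[float, float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_linked > self.n_neighbors:
            raise ValidationError(
                f"link {self.source}->{self.target}: n_linked {self.n_linked} "
                f"exceeds n_neighbors {self.n_neighbors}"
            )


@dataclass
class PipelineConfig:
    """Tunable knobs of the full linkage pipeline.

    permutations
        Number of null replicates R per significance test.
    swap_multiplier
        Q: edge-swap attempts per network edge when randomizing the network.
    fdr_alpha
        Benjamini–Hochberg significance cutoff applied per test.
    min_interactors
        K: minimum |N(A,B)| for an ordered pair to enter testing (and the
        BH family).
    log_base, pvalue_floor
        Controls for deriving perturbation scores from expression p-values.
    weight_scale, weight_min
        Raw-weight threshold and divisor applied when reading edge lists
        (defaults match STRING-style integer confidences in 150–1000).
    normalize
        Subtract the average-expression background score from the observed
        score (and from every null replicate identically).
    tests
        Subset of {"geneset", "network"} to run.
    randomize_set
        Which process of the ordered pair the annotation permutation
        replaces: "target" (default) or "source".
    shared_replicates
        Score one randomized annotation/network per replicate against all
        candidate pairs (distributionally identical per pair; far cheaper)
        instead of drawing per-pair replicates.
    pseudo_count
        Use (count+1)/(R+1) empirical p-values instead of the strict
        count/R rule.
    """

    permutations: int = 10000
    swap_multiplier: int = 100
    fdr_alpha: float = 0.01
    min_interactors: int = 10
    log_base: float = 10.0
    weight_scale: float = 1000.0
    weight_min: float = 500.0
    normalize: bool = True
    tests: Tuple[str, ...] = ("geneset", "network")
    seed: int = 0
    pvalue_floor: float = 1e-300
    randomize_set: str = "target"
    shared_replicates: bool = True
    pseudo_count: bool = False

    def __post_init__(self):
        if self.permutations < 1:
            raise ValidationError("permutations (R) must be >= 1")
        if self.swap_multiplier < 0:
            raise ValidationError("swap_multiplier (Q) must be >= 0")
        if not (0 < self.fdr_alpha <= 1):
            raise ValidationError("fdr_alpha must lie in (0, 1]")
        if self.min_interactors < 0:
            raise ValidationError("min_interactors (K) must be >= 0")
        if not (self.log_base > 1):
            raise ValidationError("log_base must exceed 1")
        bad = set(self.tests) - {"geneset", "network"}
        if bad:
            raise ValidationError(f"unknown tests: {sorted(bad)}")
        if self.randomize_set not in ("target", "source"):
            raise ValidationError("randomize_set must be 'target' or 'source'")


@dataclass
class CBPLNGraph:
    """Directed graph over processes; an edge A→B carries the LinkRecord of a
    link that passed every configured filter. Both A→B and B→A may appear."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @classmethod
    def from_records(cls, records: Iterable[LinkRecord]) -> "CBPLNGraph":
        g = nx.DiGraph()
        for rec in records:
            g.add_edge(rec.source, rec.target, record=rec)
        return cls(g)

    @property
    def links(self) -> Set[Tuple[str, str]]:
        return set(self.graph.edges)

    def record(self, source: str, target: str) -> LinkRecord:
        return self.graph.edges[source, target]["record"]

    def __len__(self) -> int:
        return self.graph.number_of_edges()
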