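"""Readers and writers for the three inputs (GMT gene sets, weighted edge
lists, perturbation tables), the link-table output, and SIF subnetworks."""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple

import pandas as pd

from .model import (
    GeneSetCollection,
    LinkRecord,
    ParseError,
    PerturbationTable,
    ValidationError,
    WeightedNetwork,
)

LINK_COLUMNS = [
    "source",
    "target",
    "n_neighbors",
    "n_linked",
    "score",
    "background",
    "normalized",
    "p_geneset",
    "q_geneset",
    "p_network",
    "q_network",
    "bpln_p",
    "bpln_q",
    "contributions",
]


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``name, description, gene, gene, ...``.

    Duplicate genes within a line are collapsed; a line with fewer than three
    fields, or whose gene fields are all empty, is an error.
    """
    sets: Dict[str, frozenset] = {}
    descriptions: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3")
            name, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
            descriptions[name] = desc
    if not sets:
        raise ValidationError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(genesets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in genesets.processes:
            desc = genesets.descriptions.get(name, "")
            genes = "\t".join(sorted(genesets.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_network(path, weight_min: float = 500.0, weight_scale: float = 1000.0) -> WeightedNetwork:
    """Read a 3-column edge list (gene1, gene2, raw weight).

    Rows below ``weight_min`` and self-loops are dropped; duplicate undirected
    pairs keep the maximum weight; surviving weights are divided by
    ``weight_scale`` (STRING-style confidences in 150-1000 land in (0, 1]).
    """
    best: Dict[frozenset, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            u, v = fields[0], fields[1]
            try:
                w = float(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from None
            if w < weight_min or u == v:
                continue
            key = frozenset((u, v))
            if w > best.get(key, float("-inf")):
                best[key] = w
    if not best:
        raise ValidationError(f"{path}: network empty after weight filtering")
    return WeightedNetwork.from_edges(
        (tuple(sorted(key)) + (w / weight_scale,)) for key, w in best.items()
    )


def write_network(network: WeightedNetwork, path, weight_scale: float = 1.0) -> None:
    """Write a 3-column edge list; weights are multiplied by ``weight_scale``
    (use 1000 to emit STRING-style raw confidences)."""
    rows = sorted((min(u, v), max(u, v), w) for u, v, w in network.edges())
    with open(path, "w") as fh:
        for u, v, w in rows:
            raw = w * weight_scale
            fh.write(f"{u}\t{v}\t{raw!r}\n" if raw != int(raw) else f"{u}\t{v}\t{int(raw)}\n")


def read_perturbation(path, log_base: float = 10.0, pvalue_floor: float = 1e-300) -> PerturbationTable:
    """Read a 2-column table (gene, expression p-value) and derive scores
    ``s(g) = |log_b p|``; zero p-values are floored at ``pvalue_floor``."""
    pvals: Dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            g = fields[0]
            try:
                p = float(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric p-value {fields[1]!r}") from None
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{path}:{lineno}: p-value for gene {g!r} outside [0, 1]: {p}")
            pvals[g] = p
    return PerturbationTable.from_pvalues(pvals, log_base=log_base, pvalue_floor=pvalue_floor)


def write_perturbation(table: PerturbationTable, path) -> None:
    if table.pvalues is None:
        raise ValidationError("table has no p-values to write")
    with open(path, "w") as fh:
        for g in sorted(table.pvalues):
            fh.write(f"{g}\t{table.pvalues[g]!r}\n")


def restrict_to_annotated(network: WeightedNetwork, genesets: GeneSetCollection) -> WeightedNetwork:
    """Induced subgraph on the annotated universe, isolated nodes removed."""
    u = genesets.universe
    sub = network.graph.subgraph(n for n in network.graph if n in u).copy()
    sub.remove_nodes_from([n for n, d in sub.degree() if d == 0])
    if sub.number_of_edges() == 0:
        raise ValidationError("network empty after restriction to the annotated universe")
    return WeightedNetwork(sub)


def extract_link_subnetwork(
    network: WeightedNetwork,
    genesets: GeneSetCollection,
    source: str,
    target: str,
) -> Tuple[List[Tuple[str, str, float]], Dict[str, str]]:
    """Edges between the two gene sets of a link, for interpretation.

    Returns the edges (u, v, w) with u in G_A and v in G_B, excluding any edge
    whose endpoints are both in G_A or both in G_B (within-set interactions
    are not part of the link), plus a label for every annotated gene:
    ``"A"``, ``"B"``, or ``"both"``.
    """
    ga = genesets.genes_of(source)
    gb = genesets.genes_of(target)
    edges: List[Tuple[str, str, float]] = []
    for u, v, w in network.edges():
        crosses = (u in ga and v in gb) or (v in ga and u in gb)
        within = (u in ga and v in ga) or (u in gb and v in gb)
        if crosses and not within:
            # orientation is unique here: exactly one endpoint lies in G_A
            a, b = (u, v) if u in ga else (v, u)
            edges.append((a, b, w))
    labels = {}
    for g in ga | gb:
        labels[g] = "both" if (g in ga and g in gb) else ("A" if g in ga else "B")
    edges.sort()
    return edges, labels


def write_sif(edges: List[Tuple[str, str, float]], path, relation: str = "interacts") -> None:
    with open(path, "w") as fh:
        for u, v, _ in edges:
            fh.write(f"{u}\t{relation}\t{v}\n")


def _fmt(x) -> str:
    if x is None:
        return ""
    return repr(float(x))


def _fmt_contributions(contrib: Dict[str, Tuple[float, float, float]]) -> str:
    parts = [f"{g}:{s!r}:{f!r}:{p!r}" for g, (s, f, p) in sorted(contrib.items())]
    return ";".join(parts)


def _parse_contributions(text: str) -> Dict[str, Tuple[float, float, float]]:
    out: Dict[str, Tuple[float, float, float]] = {}
    if not text or pd.isna(text):
        return out
    for part in str(text).split(";"):
        g, s, f, p = part.rsplit(":", 3)
        out[g] = (float(s), float(f), float(p))
    return out


def write_links(records: List[LinkRecord], path) -> None:
    """Write link records as TSV, sorted by (source, target); round-trips
    losslessly through :func:`read_links`."""
    rows = []
    for rec in sorted(records, key=lambda r: (r.source, r.target)):
        rows.append(
            {
                "source": rec.source,
                "target": rec.target,
                "n_neighbors": rec.n_neighbors,
                "n_linked": rec.n_linked,
                "score": _fmt(rec.score),
                "background": _fmt(rec.background),
                "normalized": _fmt(rec.normalized),
                "p_geneset": _fmt(rec.p_geneset),
                "q_geneset": _fmt(rec.q_geneset),
                "p_network": _fmt(rec.p_network),
                "q_network": _fmt(rec.q_network),
                "bpln_p": _fmt(rec.bpln_p),
                "bpln_q": _fmt(rec.bpln_q),
                "contributions": _fmt_contributions(rec.contributions),
            }
        )
    df = pd.DataFrame(rows, columns=LINK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_links(path) -> List[LinkRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        def opt(col: str) -> Optional[float]:
            val = row[col]
            return float(val) if val != "" else None

        records.append(
            LinkRecord(
                source=row["source"],
                target=row["target"],
                n_neighbors=int(row["n_neighbors"]),
                n_linked=int(row["n_linked"]),
                score=float(row["score"]),
                background=float(row["background"]),
                normalized=float(row["normalized"]),
                p_geneset=opt("p_geneset"),
                q_geneset=opt("q_geneset"),
                p_network=opt("p_network"),
                q_network=opt("q_network"),
                bpln_p=opt("bpln_p"),
                bpln_q=opt("bpln_q"),
                contributions=_parse_contributions(row["contributions"]),
            )
        )
    return records
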