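"""Array-based scoring engine.

Computes contextual linkage scores for all ordered process pairs at once from
flat edge arrays and a boolean membership matrix. The readable per-pair
implementation in :mod:`cbpln.scoring` is the reference; this engine exists
because the permutation nulls evaluate the same functional thousands of
times. Both are cross-checked in the test suite.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .model import GeneSetCollection, PerturbationTable, WeightedNetwork

EdgeArrays = Tuple[np.ndarray, np.ndarray, np.ndarray]  # (eu, ev, ew), single direction


class ScoreEngine:
    def __init__(
        self,
        network: WeightedNetwork,
        genesets: GeneSetCollection,
        scores: PerturbationTable,
        processes: Optional[List[str]] = None,
    ):
        self.genesets = genesets
        self.processes: List[str] = list(processes) if processes is not None else genesets.processes
        self.proc_index = {p: i for i, p in enumerate(self.processes)}

        genes = sorted(set(genesets.universe) | network.nodes)
        self.genes = genes
        self.index = {g: i for i, g in enumerate(genes)}
        self.n = len(genes)

        rows = sorted((min(u, v), max(u, v), w) for u, v, w in network.edges())
        self.eu = np.array([self.index[u] for u, _, _ in rows], dtype=np.int64)
        self.ev = np.array([self.index[v] for _, v, _ in rows], dtype=np.int64)
        self.ew = np.array([w for _, _, w in rows], dtype=np.float64)

        self.memb = np.zeros((self.n, len(self.processes)), dtype=bool)
        for j, p in enumerate(self.processes):
            self.memb[[self.index[g] for g in genesets.sets[p]], j] = True

        self.s = np.array([scores.score(g) for g in genes], dtype=np.float64)
        measured = scores.measured_genes & set(genesets.universe)
        self.bg_mean: Optional[float] = (
            float(np.mean([scores.score(g) for g in sorted(measured)])) if measured else None
        )
        # engine indices of universe genes, in sorted-gene order
        self.uidx = np.array(sorted(self.index[g] for g in genesets.universe), dtype=np.int64)

    # -- membership helpers -------------------------------------------------

    def permuted_membership(self, rng: np.random.Generator) -> np.ndarray:
        """Membership matrix after one uniform permutation of gene labels on
        the gene-process bipartite graph (set sizes and all co-annotation
        counts are preserved)."""
        perm = rng.permutation(self.uidx.shape[0])
        out = self.memb.copy()
        out[self.uidx[perm], :] = self.memb[self.uidx, :]
        return out

    # -- scoring ------------------------------------------------------------

    def _doubled(self, edges: Optional[EdgeArrays]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        eu, ev, ew = edges if edges is not None else (self.eu, self.ev, self.ew)
        return np.concatenate([eu, ev]), np.concatenate([ev, eu]), np.concatenate([ew, ew])

    def term_rows(
        self,
        memb: Optional[np.ndarray] = None,
        s: Optional[np.ndarray] = None,
        edges: Optional[EdgeArrays] = None,
    ) -> np.ndarray:
        """T[a, v] = s(v) * f_A(v), zeroed on G_A, so that S = T @ memb."""
        src, dst, w = self._doubled(edges)
        if memb is None:
            memb = self.memb
        if s is None:
            s = self.s
        t = np.zeros((memb.shape[1], self.n))
        for a in range(memb.shape[1]):
            ina = memb[:, a]
            mask = ina[src]
            if mask.any():
                fa = np.zeros(self.n)
                np.maximum.at(fa, dst[mask], w[mask] * s[src[mask]])
                fa[ina] = 0.0
                t[a] = s * fa
        return t

    def score_matrices(
        self,
        memb_rows: Optional[np.ndarray] = None,
        memb_cols: Optional[np.ndarray] = None,
        edges: Optional[EdgeArrays] = None,
    ) -> Tuple[np.ndarray, np.ndarray]:
        """(S, S_bg) for all ordered pairs: S[a, b] = S(A, B). ``memb_rows``
        provides the source-side annotations, ``memb_cols`` the target side
        (both default to the observed membership)."""
        if memb_cols is None:
            memb_cols = self.memb if memb_rows is None else memb_rows
        if memb_rows is None:
            memb_rows = self.memb
        t = self.term_rows(memb=memb_rows, edges=edges)
        s_mat = t @ memb_cols
        if self.bg_mean is None:
            raise ValueError("no measured genes in the annotated universe")
        tbg = self.term_rows(memb=memb_rows, s=np.full(self.n, self.bg_mean), edges=edges)
        return s_mat, tbg @ memb_cols

    def statistic_matrix(
        self,
        normalize: bool,
        memb_rows: Optional[np.ndarray] = None,
        memb_cols: Optional[np.ndarray] = None,
        edges: Optional[EdgeArrays] = None,
    ) -> np.ndarray:
        s_mat, bg_mat = self.score_matrices(memb_rows, memb_cols, edges)
        return s_mat - bg_mat if normalize else s_mat

    # -- neighborhood counts -------------------------------------------------

    def count_matrices(self, edges: Optional[EdgeArrays] = None) -> Tuple[np.ndarray, np.ndarray]:
        """(|N(A)| vector, |N(A,B)| matrix) under the observed annotations."""
        src, dst, _ = self._doubled(edges)
        p = len(self.processes)
        n_a = np.zeros(p, dtype=np.int64)
        n_ab = np.zeros((p, p), dtype=np.int64)
        for a in range(p):
            ina = self.memb[:, a]
            adj = np.zeros(self.n, dtype=bool)
            adj[dst[ina[src]]] = True
            adj[ina] = False
            n_a[a] = int(adj.sum())
            n_ab[a] = adj.astype(np.int64) @ self.memb
        return n_a, n_ab
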