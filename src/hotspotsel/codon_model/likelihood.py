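"""Felsenstein pruning over codon site patterns.

The engine flattens a labeled tree into postorder arrays (collapsing a
basal bifurcation, since the reversible model makes the root placement
immaterial), compresses alignment columns into weighted patterns, and
caches the spectral decomposition of each omega-class rate matrix.
"""

from __future__ import annotations

import warnings

import numpy as np

from hotspotsel.codon_model.frequencies import CodonFrequencies, f3x4_frequencies
from hotspotsel.codon_model.matrix import (
    BACKGROUND,
    FOREGROUND,
    CodonModelParams,
    EigenSystem,
    build_rate_matrix,
)
from hotspotsel.codon_model.states import CodonStateSpace, get_state_space
from hotspotsel.io_formats import CodonAlignment, LabeledTree

_ACGT = set("ACGT")


def _codon_states(
    alignment: CodonAlignment, taxa: list[str], space: CodonStateSpace
) -> np.ndarray:
    """(n_taxa, n_sites) sense-codon indices; -1 marks missing data."""
    idx = space.index
    n_sites = alignment.n_codons
    out = np.full((len(taxa), n_sites), -1, dtype=np.int64)
    stop_seen = 0
    for r, taxon in enumerate(taxa):
        seq = alignment.sequences[taxon]
        for i in range(n_sites):
            codon = seq[3 * i : 3 * i + 3]
            if not _ACGT.issuperset(codon):
                continue
            j = idx.get(codon)
            if j is None:
                stop_seen += 1
                continue
            out[r, i] = j
    if stop_seen:
        warnings.warn(
            f"{stop_seen} observed stop codon(s) in {alignment.gene_id} "
            "treated as missing data"
        )
    return out


class PruningEngine:
    """Reusable likelihood evaluator for one alignment x tree pair."""

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: LabeledTree,
        freqs: CodonFrequencies,
        space: CodonStateSpace | None = None,
        gap_policy: str = "missing",
    ):
        self.space = space or get_state_space(1)
        self.freqs = freqs
        self.pi = np.asarray(freqs.pi, dtype=float)
        tips = set(tree.taxa)
        if tips != set(alignment.taxa):
            raise ValueError(
                f"tree tips and alignment taxa differ for {alignment.gene_id}: "
                f"only-in-tree={sorted(tips - set(alignment.taxa))}, "
                f"only-in-alignment={sorted(set(alignment.taxa) - tips)}"
            )
        self._build_topology(tree)
        states = _codon_states(alignment, self._leaf_taxa_order, self.space)
        if gap_policy == "strict":
            keep = (states >= 0).all(axis=0)
            states = states[:, keep]
        elif gap_policy != "missing":
            raise ValueError(f"unknown gap policy {gap_policy!r}")
        if states.shape[1] == 0:
            raise ValueError("no usable codon columns")
        patterns, weights = np.unique(states, axis=1, return_counts=True)
        self.patterns = patterns
        self.weights = weights.astype(float)
        self.n_sites = states.shape[1]
        self._eig_cache: dict[tuple[float, float], EigenSystem] = {}

    # -- topology -----------------------------------------------------------

    def _build_topology(self, tree: LabeledTree) -> None:
        """Postorder arrays; merges a basal bifurcation into one edge."""
        dt = tree.dendropy_tree
        root = dt.seed_node
        kids = root.child_nodes()
        merged: dict[int, object] = {}  # node id -> co-edge dendropy node
        extra_child = None
        start = root
        if len(kids) == 2:
            c1, c2 = kids
            start = c1 if not c1.is_leaf() else c2
            other = c2 if start is c1 else c1
            extra_child = other
            merged_len = (c1.edge.length or 0.0) + (c2.edge.length or 0.0) \
                if (c1.edge.length is not None or c2.edge.length is not None) else None
            self._merged = (other, start, merged_len)
        else:
            self._merged = None

        children: list[list[int]] = []
        leaf_state_row: list[int | None] = []
        init_len: list[float | None] = []
        is_fg: list[bool] = []
        dnodes: list[object] = []
        postorder: list[int] = []
        leaf_taxa: list[str] = []

        def add(nd, as_root: bool) -> int:
            child_ids = [add(c, False) for c in nd.child_nodes()]
            if as_root and extra_child is not None:
                child_ids.append(add(extra_child, False))
            my = len(children)
            children.append(child_ids)
            if nd.is_leaf():
                leaf_taxa.append(nd.taxon.label)
                leaf_state_row.append(len(leaf_taxa) - 1)
            else:
                leaf_state_row.append(None)
            if as_root:
                init_len.append(None)
            elif self._merged is not None and nd is self._merged[0]:
                init_len.append(self._merged[2])
            else:
                init_len.append(nd.edge.length)
            fg = getattr(nd, "foreground", False)
            if self._merged is not None and nd is self._merged[0]:
                fg = fg or getattr(self._merged[1], "foreground", False)
            is_fg.append(fg and not as_root)
            dnodes.append(nd)
            postorder.append(my)
            return my

        add(start, True)
        self.children = children
        self.leaf_state_row = leaf_state_row
        self.init_lengths = init_len
        self.branch_fg = is_fg
        self.dnodes = dnodes
        self.postorder = postorder
        self.root_id = postorder[-1]
        self._leaf_taxa_order = leaf_taxa
        # ids of nodes that own an optimizable branch (everything but root)
        self.edge_node_ids = [i for i in postorder if i != self.root_id]

    @property
    def n_edges(self) -> int:
        return len(self.edge_node_ids)

    def initial_edge_lengths(self, default: float = 0.1) -> np.ndarray:
        return np.array(
            [
                self.init_lengths[i] if self.init_lengths[i] is not None else default
                for i in self.edge_node_ids
            ],
            dtype=float,
        )

    def write_lengths(self, lengths: np.ndarray) -> None:
        """Push optimized lengths back onto the tree this engine was built on.

        With a merged basal bifurcation the full merged length goes on the
        subtree-side child and the co-edge is set to zero.
        """
        for node_id, t in zip(self.edge_node_ids, lengths):
            self.dnodes[node_id].edge.length = float(t)
        if self._merged is not None:
            self._merged[1].edge.length = 0.0

    # -- likelihood ---------------------------------------------------------

    def _eigen(self, kappa: float, omega: float) -> EigenSystem:
        key = (kappa, omega)
        eig = self._eig_cache.get(key)
        if eig is None:
            params = CodonModelParams(kappa, omega, self.freqs)
            Q = build_rate_matrix(params, BACKGROUND, self.space)
            eig = EigenSystem(Q, self.pi)
            if len(self._eig_cache) > 64:
                self._eig_cache.clear()
            self._eig_cache[key] = eig
        return eig

    def _root_onehot(self) -> np.ndarray:
        """Tip indicator for a root that is itself a leaf (2-taxon case)."""
        if getattr(self, "_root_onehot_cache", None) is None:
            row = self.leaf_state_row[self.root_id]
            states = self.patterns[row]
            npat = states.shape[0]
            onehot = np.zeros((npat, self.space.n))
            mask = states >= 0
            onehot[np.arange(npat)[mask], states[mask]] = 1.0
            onehot[~mask] = 1.0
            self._root_onehot_cache = onehot
        return self._root_onehot_cache

    def log_likelihood(
        self,
        kappa: float,
        omega_background: float,
        omega_foreground: float | None,
        edge_lengths: np.ndarray,
    ) -> float:
        lnl, _ = self.log_likelihood_and_gradient(
            kappa, omega_background, omega_foreground, edge_lengths, with_grad=False
        )
        return lnl

    def log_likelihood_and_gradient(
        self,
        kappa: float,
        omega_background: float,
        omega_foreground: float | None,
        edge_lengths: np.ndarray,
        with_grad: bool = True,
    ) -> tuple[float, np.ndarray | None]:
        """lnL and (optionally) its gradient wrt every branch length.

        The gradient comes from a second, preorder pass propagating the
        likelihood of the rest of the tree across each edge, with
        dP/dt = Q P taken from the cached spectral decomposition.
        """
        n = self.space.n
        npat = self.patterns.shape[1]
        eig_bg = self._eigen(kappa, omega_background)
        eig_fg = (
            self._eigen(kappa, omega_foreground)
            if omega_foreground is not None
            else eig_bg
        )
        P: dict[int, np.ndarray] = {}
        dP: dict[int, np.ndarray] = {}
        for node_id, t in zip(self.edge_node_ids, edge_lengths):
            eig = eig_fg if self.branch_fg[node_id] else eig_bg
            if with_grad:
                P[node_id], dP[node_id] = eig.transition_and_rate(t)
            else:
                P[node_id] = eig.transition(t)

        def is_plain_leaf(i: int) -> bool:
            return not self.children[i] and i != self.root_id

        messages: dict[int, np.ndarray] = {}  # child -> contribution to parent
        down: dict[int, np.ndarray] = {}      # internal node -> scaled partial
        log_scale = np.zeros(npat)
        for node_id in self.postorder:
            if is_plain_leaf(node_id):
                continue
            acc = (
                self._root_onehot().copy()
                if self.leaf_state_row[node_id] is not None
                else np.ones((npat, n))
            )
            for child in self.children[node_id]:
                crow = self.leaf_state_row[child]
                if crow is not None and is_plain_leaf(child):
                    states = self.patterns[crow]
                    M = P[child].T[np.maximum(states, 0)]
                    M[states < 0] = 1.0
                else:
                    M = down[child] @ P[child].T
                if with_grad:
                    messages[child] = M
                acc *= M
            m = acc.max(axis=1)
            if np.any(m <= 0):
                return -np.inf, None
            acc /= m[:, None]
            log_scale += np.log(m)
            down[node_id] = acc
        site_like = down[self.root_id] @ self.pi
        if np.any(site_like <= 0):
            return -np.inf, None
        lnl = float(np.dot(self.weights, np.log(site_like) + log_scale))
        if not with_grad:
            return lnl, None

        edge_pos = {node_id: k for k, node_id in enumerate(self.edge_node_ids)}
        grad = np.zeros(self.n_edges)
        outer: dict[int, np.ndarray] = {}
        root_outer = np.tile(self.pi, (npat, 1))
        if self.leaf_state_row[self.root_id] is not None:
            root_outer = root_outer * self._root_onehot()
        outer[self.root_id] = root_outer
        tiny = np.finfo(float).tiny
        for node_id in reversed(self.postorder):
            kids = self.children[node_id]
            if not kids:
                continue
            O_u = outer.pop(node_id)
            k = len(kids)
            if k == 1:
                siblings = [None]
            else:
                mats = [messages[c] for c in kids]
                prefix = [None] * k
                suffix = [None] * k
                run = None
                for i in range(k):
                    prefix[i] = run
                    run = mats[i] if run is None else run * mats[i]
                run = None
                for i in range(k - 1, -1, -1):
                    suffix[i] = run
                    run = mats[i] if run is None else run * mats[i]
                siblings = [
                    (prefix[i] if suffix[i] is None else
                     suffix[i] if prefix[i] is None else prefix[i] * suffix[i])
                    for i in range(k)
                ]
            for i, child in enumerate(kids):
                O_up = O_u if siblings[i] is None else O_u * siblings[i]
                mm = O_up.max(axis=1)
                mm[mm <= 0] = 1.0
                O_up = O_up / mm[:, None]
                OP = O_up @ P[child]
                OdP = O_up @ dP[child]
                crow = self.leaf_state_row[child]
                if crow is not None and is_plain_leaf(child):
                    states = self.patterns[crow]
                    miss = states < 0
                    sel = np.maximum(states, 0)[:, None]
                    den = np.take_along_axis(OP, sel, axis=1)[:, 0]
                    num = np.take_along_axis(OdP, sel, axis=1)[:, 0]
                    if miss.any():
                        den[miss] = OP[miss].sum(axis=1)
                        num[miss] = OdP[miss].sum(axis=1)
                else:
                    d = down[child]
                    den = (OP * d).sum(axis=1)
                    num = (OdP * d).sum(axis=1)
                grad[edge_pos[child]] = float(
                    np.dot(self.weights, num / np.maximum(den, tiny))
                )
                if self.children[child]:
                    outer[child] = OP
        return lnl, grad


def log_likelihood(
    alignment: CodonAlignment,
    tree: LabeledTree,
    params: CodonModelParams,
    space: CodonStateSpace | None = None,
    gap_policy: str = "missing",
) -> float:
    """Log-likelihood of the alignment under the given parameters and tree.

    Branch lengths are taken from the tree; foreground branches use the
    foreground omega when ``params.omega_foreground`` is set.
    """
    engine = PruningEngine(alignment, tree, params.freqs, space, gap_policy)
    lengths = engine.initial_edge_lengths(default=0.0)
    return engine.log_likelihood(
        params.kappa, params.omega_background, params.omega_foreground, lengths
    )


__all__ = ["PruningEngine", "log_likelihood", "f3x4_frequencies", "FOREGROUND"]
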