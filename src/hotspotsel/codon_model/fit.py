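"""Maximum-likelihood fitting of the one-ratio and two-ratio branch models.

Bounded quasi-Newton (L-BFGS-B) over log-transformed kappa, omega(s), and
all branch lengths; seeded random restarts are attempted only when the
first optimization fails to converge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from hotspotsel.codon_model.frequencies import CodonFrequencies, codon_frequencies
from hotspotsel.codon_model.likelihood import PruningEngine
from hotspotsel.codon_model.matrix import (
    KAPPA_BOUNDS,
    OMEGA_BOUNDS,
    CodonModelParams,
)
from hotspotsel.codon_model.states import CodonStateSpace
from hotspotsel.io_formats import CodonAlignment, LabeledTree

LENGTH_BOUNDS = (1e-7, 25.0)
DEFAULT_KAPPA0 = 2.0
DEFAULT_OMEGA0 = 0.4
CONVERGENCE_TOL = 1e-8


@dataclass
class ModelFit:
    """Result of one model optimization."""

    model: str  # "one-ratio" | "branch"
    params: CodonModelParams
    tree: LabeledTree
    lnL: float
    n_free_params: int
    converged: bool
    n_restarts_used: int

    @property
    def omega_background(self) -> float:
        return self.params.omega_background

    @property
    def omega_foreground(self) -> float:
        return self.params.omega(omega_class="foreground")


def _optimize(
    engine: PruningEngine,
    two_ratio: bool,
    init_kappa: float,
    init_omegas: tuple[float, ...],
    rng: np.random.Generator,
    n_restarts: int,
    maxiter: int,
) -> tuple[np.ndarray, float, bool, int]:
    n_omega = 2 if two_ratio else 1
    n_edges = engine.n_edges
    lb = np.concatenate(
        [
            [np.log(KAPPA_BOUNDS[0])],
            np.full(n_omega, np.log(OMEGA_BOUNDS[0])),
            np.full(n_edges, np.log(LENGTH_BOUNDS[0])),
        ]
    )
    ub = np.concatenate(
        [
            [np.log(KAPPA_BOUNDS[1])],
            np.full(n_omega, np.log(OMEGA_BOUNDS[1])),
            np.full(n_edges, np.log(LENGTH_BOUNDS[1])),
        ]
    )
    bounds = list(zip(lb, ub))
    t0 = np.clip(engine.initial_edge_lengths(), *LENGTH_BOUNDS)
    x0 = np.concatenate([[np.log(init_kappa)], np.log(init_omegas), np.log(t0)])
    x0 = np.clip(x0, lb, ub)

    def lnl_at(x: np.ndarray, with_grad: bool):
        # exp/log round-trip can overshoot the box by ~1 ulp; clip back
        kappa = float(np.clip(np.exp(x[0]), *KAPPA_BOUNDS))
        omegas = np.clip(np.exp(x[1 : 1 + n_omega]), *OMEGA_BOUNDS)
        lengths = np.exp(x[1 + n_omega :])
        return engine.log_likelihood_and_gradient(
            kappa,
            float(omegas[0]),
            float(omegas[1]) if two_ratio else None,
            lengths,
            with_grad=with_grad,
        )

    eps = 1e-5  # central-difference step for the log-scale rate parameters

    def nll_and_grad(x: np.ndarray):
        lnl, grad_t = lnl_at(x, True)
        if not np.isfinite(lnl):
            return 1e12, np.zeros_like(x)
        grad = np.empty_like(x)
        # branch lengths: analytic, chain rule through the log transform
        grad[1 + n_omega :] = -grad_t * np.exp(x[1 + n_omega :])
        # kappa and omega(s): central differences on the log scale
        for k in range(1 + n_omega):
            xp, xm = x.copy(), x.copy()
            xp[k] = min(x[k] + eps, ub[k])
            xm[k] = max(x[k] - eps, lb[k])
            fp, _ = lnl_at(xp, False)
            fm, _ = lnl_at(xm, False)
            grad[k] = -(fp - fm) / (xp[k] - xm[k])
        return -lnl, grad

    best = None
    restarts_used = 0
    start = x0
    for attempt in range(1 + max(0, n_restarts)):
        res = minimize(
            nll_and_grad,
            start,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": maxiter, "maxfun": 10 * maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - CONVERGENCE_TOL:
            best = res
        if attempt > 0:
            restarts_used = attempt
        if best.success:
            break
        # jittered restart around the incumbent optimum
        start = np.clip(best.x + rng.normal(0.0, 0.25, size=best.x.shape), lb, ub)
    return best.x, -best.fun, bool(best.success), restarts_used


def _fit(
    alignment: CodonAlignment,
    tree: LabeledTree,
    two_ratio: bool,
    freqs,
    gap_policy: str,
    seed: int,
    n_restarts: int,
    maxiter: int,
    init_kappa: float,
    init_omegas: tuple[float, ...],
    space: CodonStateSpace | None,
) -> ModelFit:
    if isinstance(freqs, CodonFrequencies):
        fr = freqs
    else:
        fr = codon_frequencies(alignment, mode=freqs, space=space)
    work = tree.copy()
    if two_ratio and work.n_foreground == 0:
        raise ValueError("branch model requires at least one foreground branch")
    engine = PruningEngine(alignment, work, fr, space, gap_policy)
    rng = np.random.default_rng(seed)
    x, lnl, ok, restarts = _optimize(
        engine, two_ratio, init_kappa, init_omegas, rng, n_restarts, maxiter
    )
    n_omega = 2 if two_ratio else 1
    kappa = float(np.clip(np.exp(x[0]), *KAPPA_BOUNDS))
    omegas = np.clip(np.exp(x[1 : 1 + n_omega]), *OMEGA_BOUNDS)
    lengths = np.exp(x[1 + n_omega :])
    engine.write_lengths(lengths)
    params = CodonModelParams(
        kappa,
        float(omegas[0]),
        fr,
        float(omegas[1]) if two_ratio else None,
    )
    return ModelFit(
        model="branch" if two_ratio else "one-ratio",
        params=params,
        tree=work,
        lnL=lnl,
        n_free_params=1 + n_omega + engine.n_edges,
        converged=ok,
        n_restarts_used=restarts,
    )


def fit_one_ratio(
    alignment: CodonAlignment,
    tree: LabeledTree,
    freqs="F3x4",
    gap_policy: str = "missing",
    seed: int = 0,
    n_restarts: int = 3,
    maxiter: int = 1000,
    init_kappa: float = DEFAULT_KAPPA0,
    init_omega: float = DEFAULT_OMEGA0,
    space: CodonStateSpace | None = None,
) -> ModelFit:
    """Fit kappa, a single omega, and all branch lengths by ML."""
    return _fit(
        alignment,
        tree,
        False,
        freqs,
        gap_policy,
        seed,
        n_restarts,
        maxiter,
        init_kappa,
        (init_omega,),
        space,
    )


def fit_branch_model(
    alignment: CodonAlignment,
    tree: LabeledTree,
    freqs="F3x4",
    gap_policy: str = "missing",
    seed: int = 0,
    n_restarts: int = 3,
    maxiter: int = 1000,
    init: ModelFit | None = None,
    space: CodonStateSpace | None = None,
) -> ModelFit:
    """Fit the two-ratio branch model (separate foreground omega).

    ``init`` (typically the one-ratio fit of the same gene) warm-starts the
    optimization: branch lengths are taken from its tree and both omegas
    from its background omega.
    """
    work_tree = tree
    init_kappa, init_omegas = DEFAULT_KAPPA0, (DEFAULT_OMEGA0, DEFAULT_OMEGA0)
    if init is not None:
        init_kappa = init.params.kappa
        w = init.params.omega_background
        init_omegas = (w, w)
        work_tree = init.tree.copy()
        # foreground labels follow the requested tree, not the init fit;
        # branches are matched by their descendant leaf sets
        def clade_map(lt: LabeledTree) -> dict[frozenset, object]:
            out = {}
            for node, _, _ in lt.branches():
                leaves = frozenset(l.taxon.label for l in node.leaf_iter())
                out[leaves] = node
            return out

        fg_clades = {
            frozenset(l.taxon.label for l in node.leaf_iter())
            for node, _, fg in tree.branches()
            if fg
        }
        for leaves, node in clade_map(work_tree).items():
            node.foreground = leaves in fg_clades
        if work_tree.n_foreground != tree.n_foreground:
            work_tree = tree  # topology mismatch: fall back to the cold tree
    return _fit(
        alignment,
        work_tree,
        True,
        freqs,
        gap_policy,
        seed,
        n_restarts,
        maxiter,
        init_kappa,
        init_omegas,
        space,
    )


__all__ = ["ModelFit", "fit_one_ratio", "fit_branch_model"]
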