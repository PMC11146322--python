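"""Branch-model likelihood-ratio tests and Benjamini-Hochberg FDR control."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from hotspotsel.codon_model.fit import ModelFit, fit_branch_model, fit_one_ratio
from hotspotsel.io_formats import CodonAlignment, LabeledTree

logger = logging.getLogger(__name__)

NEGATIVE_STAT_TOL = 1e-6


@dataclass(frozen=True)
class BranchTestResult:
    """One gene's branch test: lnL pair, LRT statistic, raw/adjusted P."""

    gene_id: str
    lnL0: float
    lnL1: float
    stat: float
    df: int
    p_raw: float
    omega_background: float
    omega_foreground: float
    p_adj: float | None = None
    converged: bool = True


def lrt_branch(fit0: ModelFit, fit1: ModelFit, gene_id: str | None = None) -> BranchTestResult:
    """LRT of the two-ratio model (fit1) against the one-ratio model (fit0).

    stat = 2 (lnL1 - lnL0), referred to chi-square with 1 df.  A negative
    statistic (optimizer noise) is clamped to zero with a warning.
    """
    if fit1.n_free_params != fit0.n_free_params + 1:
        raise ValueError("models are not nested with one extra free parameter")
    stat = 2.0 * (fit1.lnL - fit0.lnL)
    if stat < -NEGATIVE_STAT_TOL:
        warnings.warn(
            f"two-ratio lnL below one-ratio lnL by {-stat / 2:.6g} "
            f"for {gene_id or 'gene'}; statistic clamped to 0 (optimizer failure?)"
        )
    stat = max(stat, 0.0)
    p_raw = float(chi2.sf(stat, df=1))
    return BranchTestResult(
        gene_id=gene_id or "gene",
        lnL0=fit0.lnL,
        lnL1=fit1.lnL,
        stat=stat,
        df=1,
        p_raw=p_raw,
        omega_background=fit1.params.omega_background,
        omega_foreground=fit1.omega_foreground,
        converged=fit0.converged and fit1.converged,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_branch_screen(
    alignments: dict[str, CodonAlignment],
    tree: LabeledTree,
    foreground: list[str] | None = None,
    alpha: float = 0.01,
    freqs: str = "F3x4",
    gap_policy: str = "missing",
    seed: int = 0,
    n_restarts: int = 3,
    maxiter: int = 1000,
) -> tuple[pd.DataFrame, set[str]]:
    """Fit both models per gene, LRT, BH-adjust within the run, call candidates.

    The guide tree is pruned per gene to the taxa present in its alignment;
    ``foreground`` names (tips or internal labels) are applied after pruning
    when given, otherwise the tree's own labels are used.  Genes whose fits
    fail are recorded but excluded from the BH family.
    """
    if not alignments:
        raise ValueError("no alignments supplied")
    results: list[BranchTestResult] = []
    failures: list[tuple[str, str]] = []
    for gene_id in sorted(alignments):
        aln = alignments[gene_id]
        try:
            gene_tree = tree.prune_to(aln.taxa)
            if foreground:
                present = [f for f in foreground if f in aln.taxa or f not in tree.taxa]
                if not present:
                    raise LookupError("no foreground taxon present in alignment")
                gene_tree.set_foreground(present)
            fit0 = fit_one_ratio(
                aln, gene_tree, freqs=freqs, gap_policy=gap_policy,
                seed=seed, n_restarts=n_restarts, maxiter=maxiter,
            )
            fit1 = fit_branch_model(
                aln, gene_tree, freqs=freqs, gap_policy=gap_policy,
                seed=seed, n_restarts=n_restarts, maxiter=maxiter, init=fit0,
            )
            results.append(lrt_branch(fit0, fit1, gene_id=gene_id))
        except Exception as exc:  # noqa: BLE001 - per-gene isolation
            logger.warning("fit failed for %s: %s", gene_id, exc)
            failures.append((gene_id, str(exc)))
    if results:
        adj = bh_adjust([r.p_raw for r in results])
        results = [replace(r, p_adj=float(a)) for r, a in zip(results, adj)]
    rows = [
        {
            "gene": r.gene_id,
            "lnL0": r.lnL0,
            "lnL1": r.lnL1,
            "stat": r.stat,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "omega_bg": r.omega_background,
            "omega_fg": r.omega_foreground,
            "converged": r.converged,
            "status": "ok",
        }
        for r in results
    ]
    rows += [
        {
            "gene": g,
            "lnL0": np.nan, "lnL1": np.nan, "stat": np.nan,
            "p_raw": np.nan, "p_adj": np.nan,
            "omega_bg": np.nan, "omega_fg": np.nan,
            "converged": False,
            "status": f"failed: {msg}",
        }
        for g, msg in failures
    ]
    table = pd.DataFrame(rows)
    candidates = {r.gene_id for r in results if r.p_adj is not None and r.p_adj < alpha}
    return table, candidates


__all__ = ["BranchTestResult", "lrt_branch", "bh_adjust", "run_branch_screen"]
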