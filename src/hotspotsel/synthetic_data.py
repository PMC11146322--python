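"""Seeded generators of synthetic inputs for every pipeline stage.

The codon simulator reuses the production rate-matrix/transition code, so
simulation and inference share one model definition; genome, rearrangement,
and coverage generators plant known structure for the downstream tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from hotspotsel.codon_model.frequencies import CodonFrequencies, uniform_frequencies
from hotspotsel.codon_model.matrix import (
    BACKGROUND,
    FOREGROUND,
    CodonModelParams,
    EigenSystem,
    build_rate_matrix,
)
from hotspotsel.codon_model.states import get_state_space
from hotspotsel.genome_metrics import CoverageMatrix
from hotspotsel.io_formats import (
    CodonAlignment,
    GeneLocus,
    GenomeLayout,
    LabeledTree,
    read_labeled_tree,
)
from hotspotsel.synteny_map import BlockInstance, LandmarkPlacement


# --- codon alignments -------------------------------------------------------


@dataclass(frozen=True)
class SimCodonSpec:
    """Parameters for simulating one codon alignment along a labeled tree."""

    tree: LabeledTree
    kappa: float
    omega_background: float
    n_codons: int
    omega_foreground: float | None = None
    freqs: CodonFrequencies | None = None  # None => uniform over sense codons
    seed: int = 0
    gene_id: str = "simulated"

    def __post_init__(self):
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")


def default_test_tree(n_tips: int = 8, foreground_tip: str | None = "T1") -> LabeledTree:
    """Pectinate test tree, unrooted-style (basal trifurcation), with branch
    lengths in [0.05, 0.3]; foreground on one terminal branch."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    lengths = np.linspace(0.05, 0.3, n_tips)
    nested = f"T{n_tips}:{lengths[-1]:.4f}"
    for i in range(n_tips - 1, 2, -1):
        nested = f"(T{i}:{lengths[i - 1]:.4f},{nested}):{0.05 + 0.02 * i:.4f}"
    newick = f"(T1:{lengths[0]:.4f},T2:{lengths[1]:.4f},{nested});"
    tree = read_labeled_tree(newick)
    if foreground_tip is not None:
        tree.set_foreground([foreground_tip])
    return tree


def simulate_codon_alignment(spec: SimCodonSpec) -> CodonAlignment:
    """Evolve codons from a stationary root down the tree, branch by branch."""
    space = get_state_space(1)
    freqs = spec.freqs or uniform_frequencies(space)
    pi = np.asarray(freqs.pi)
    params = CodonModelParams(
        spec.kappa, spec.omega_background, freqs, spec.omega_foreground
    )
    eig = {BACKGROUND: EigenSystem(build_rate_matrix(params, BACKGROUND, space), pi)}
    if spec.omega_foreground is not None:
        eig[FOREGROUND] = EigenSystem(build_rate_matrix(params, FOREGROUND, space), pi)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_codons
    root_states = rng.choice(space.n, size=n, p=pi)
    tree = spec.tree.dendropy_tree
    states = {id(tree.seed_node): root_states}
    seqs: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            parent_states = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            cls = FOREGROUND if getattr(node, "foreground", False) else BACKGROUND
            P = eig.get(cls, eig[BACKGROUND]).transition(t)
            cum = np.cumsum(P, axis=1)
            u = rng.random(n)
            rows = cum[parent_states]
            child = (rows < u[:, None]).sum(axis=1)
            child = np.minimum(child, space.n - 1)
            states[id(node)] = child
        if node.is_leaf():
            codons = [space.codons[s] for s in states[id(node)]]
            seqs[node.taxon.label] = "".join(codons)
    taxa = tuple(leaf.taxon.label for leaf in tree.leaf_node_iter())
    return CodonAlignment(spec.gene_id, taxa, seqs)


# --- genome annotation ------------------------------------------------------


@dataclass(frozen=True)
class SimGenomeSpec:
    """Multi-chromosome annotation with a planted cluster of candidates."""

    chromosome_lengths: tuple[int, ...]
    n_genes: int
    n_candidates: int
    cluster_chrom: int = 0  # index into chromosome_lengths
    cluster_start: int = 0
    cluster_width: int = 12_000_000
    n_planted: int = 0
    gene_length: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (0 <= self.n_planted <= self.n_candidates <= self.n_genes):
            raise ValueError("need 0 <= n_planted <= n_candidates <= n_genes")
        if not (0 <= self.cluster_chrom < len(self.chromosome_lengths)):
            raise ValueError("cluster chromosome index out of range")
        chrom_len = self.chromosome_lengths[self.cluster_chrom]
        if self.cluster_start < 0 or self.cluster_start + self.cluster_width > chrom_len:
            raise ValueError("planted cluster exceeds its chromosome")
        if self.gene_length > min(self.chromosome_lengths) or self.gene_length > self.cluster_width:
            raise ValueError("gene length too large for placement")


def simulate_genome_annotation(
    spec: SimGenomeSpec,
) -> tuple[list[GeneLocus], set[str], GenomeLayout]:
    """Uniformly placed genes; planted candidates inside the cluster window,
    other candidates uniform outside it."""
    rng = np.random.default_rng(spec.seed)
    layout = GenomeLayout(
        tuple((f"chr{i + 1}", int(l)) for i, l in enumerate(spec.chromosome_lengths))
    )
    lengths = np.array(spec.chromosome_lengths, dtype=float)
    probs = lengths / lengths.sum()
    cluster_name = layout.names[spec.cluster_chrom]
    cluster_stop = spec.cluster_start + spec.cluster_width

    width = len(str(spec.n_genes))
    symbols = [f"gene{str(i + 1).zfill(width)}" for i in range(spec.n_genes)]
    candidates = set(symbols[: spec.n_candidates])
    planted = set(symbols[: spec.n_planted])

    genes: list[GeneLocus] = []
    for symbol in symbols:
        if symbol in planted:
            chrom = cluster_name
            start = int(
                rng.integers(spec.cluster_start, cluster_stop - spec.gene_length + 1)
            )
        else:
            for _ in range(10_000):
                c = int(rng.choice(len(probs), p=probs))
                chrom = layout.names[c]
                start = int(
                    rng.integers(0, spec.chromosome_lengths[c] - spec.gene_length + 1)
                )
                inside = (
                    chrom == cluster_name
                    and start < cluster_stop
                    and start + spec.gene_length > spec.cluster_start
                )
                if not (symbol in candidates and inside):
                    break
            else:  # pragma: no cover - essentially impossible genome shapes
                raise ValueError("could not place candidate outside the cluster")
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneLocus(symbol, chrom, start, start + spec.gene_length, strand))
    return genes, candidates, layout


# --- rearrangements ---------------------------------------------------------


def simulate_rearrangements(
    block: BlockInstance,
    operations,
    seed: int | None = None,
) -> tuple[BlockInstance, list[str]]:
    """Apply inversions/transpositions/fissions/deletions to a block instance.

    Operations are tuples applied left to right, with 0-based positions in
    the current species order of present landmarks:
    ``("inversion", i, j)`` (inclusive), ``("transposition", i, j, k)``,
    ``("fission", i)`` (suffix from i moves to a new linkage group),
    ``("deletion", i)``.  ``seed`` is accepted for signature symmetry with
    the other generators; all listed operations are deterministic.
    """
    sign = {"+": 1, "-": -1}
    items = [
        {"p": p, "sign": sign[p.strand], "group": 0}
        for p in sorted(block.present, key=lambda p: (p.chrom, p.start))
    ]
    deleted: list[LandmarkPlacement] = [p for p in block.landmarks if not p.present]
    next_group = 1
    log: list[str] = []

    def check(idx: int) -> None:
        if not (0 <= idx < len(items)):
            raise IndexError(f"operation index {idx} out of range (n={len(items)})")

    for op in operations:
        kind = op[0]
        if kind == "inversion":
            _, i, j = op
            check(i), check(j)
            if i > j:
                raise IndexError("inversion requires i <= j")
            if len({it["group"] for it in items[i : j + 1]}) > 1:
                raise ValueError("inversion span crosses a fission boundary")
            seg = items[i : j + 1][::-1]
            for it in seg:
                it["sign"] = -it["sign"]
            items[i : j + 1] = seg
            log.append(f"inversion({i},{j})")
        elif kind == "transposition":
            _, i, j, k = op
            check(i), check(j)
            if i > j:
                raise IndexError("transposition requires i <= j")
            seg = items[i : j + 1]
            rest = items[:i] + items[j + 1 :]
            if not (0 <= k <= len(rest)):
                raise IndexError(f"insertion point {k} out of range")
            group = rest[min(k, len(rest) - 1)]["group"] if rest else 0
            for it in seg:
                it["group"] = group
            items = rest[:k] + seg + rest[k:]
            log.append(f"transposition({i},{j},{k})")
        elif kind == "fission":
            (_, i) = op
            check(i)
            for it in items[i:]:
                it["group"] = next_group
            next_group += 1
            log.append(f"fission({i})")
        elif kind == "deletion":
            (_, i) = op
            check(i)
            gone = items.pop(i)
            deleted.append(replace(gone["p"], present=False, chrom=None, start=None,
                                   end=None, strand=None, order_index=None))
            log.append(f"deletion({i})")
        else:
            raise ValueError(f"unknown operation {kind!r}")

    # rebuild coordinates: landmarks spaced 1 Mb apart within each group
    spacing, gene_len = 1_000_000, 10_000
    base_chrom = next(iter(block.chromosomes)) if block.present else "chr1"
    placements: list[LandmarkPlacement] = []
    per_group_pos: dict[int, int] = {}
    order = 0
    for it in items:
        g = it["group"]
        pos = per_group_pos.get(g, 0)
        per_group_pos[g] = pos + 1
        chrom = base_chrom if g == 0 else f"{base_chrom}_fission{g}"
        start = spacing * (pos + 1)
        order += 1
        placements.append(
            LandmarkPlacement(
                it["p"].symbol,
                it["p"].ref_index,
                True,
                chrom,
                start,
                start + gene_len,
                "+" if it["sign"] > 0 else "-",
                order_index=None,
            )
        )
    from hotspotsel.synteny_map import _assign_order

    all_placements = _assign_order(placements + deleted)
    by_symbol = {p.symbol: p for p in all_placements}
    ordered = tuple(by_symbol[p.symbol] for p in block.landmarks)
    return BlockInstance(block.species, block.block, ordered), log


# --- coverage ---------------------------------------------------------------


def simulate_coverage(
    n_samples: int,
    scaffolds,
    x_scaffold: str | None = None,
    frac_half_dose: float = 0.5,
    noise_sigma: float = 0.05,
    reads_per_sample: int = 2_000_000,
    seed: int = 0,
) -> CoverageMatrix:
    """Counts proportional to scaffold length; a chosen fraction of samples
    get half dose on ``x_scaffold``; multiplicative lognormal noise."""
    if not (0.0 <= frac_half_dose <= 1.0):
        raise ValueError("frac_half_dose must be in [0, 1]")
    scaffolds = tuple(scaffolds)
    names = tuple(n for n, _ in scaffolds)
    lengths = np.array([l for _, l in scaffolds], dtype=float)
    if x_scaffold is not None and x_scaffold not in names:
        raise ValueError(f"unknown x_scaffold {x_scaffold!r}")
    rng = np.random.default_rng(seed)
    dose = np.ones((n_samples, len(names)))
    if x_scaffold is not None:
        n_half = int(round(frac_half_dose * n_samples))
        dose[:n_half, names.index(x_scaffold)] = 0.5
    expected = reads_per_sample * (lengths / lengths.sum())[None, :] * dose
    if noise_sigma > 0:
        expected = expected * rng.lognormal(0.0, noise_sigma, size=expected.shape)
    counts = np.round(expected)
    samples = tuple(f"sample{i + 1:02d}" for i in range(n_samples))
    return CoverageMatrix(samples, names, counts, lengths)


def write_coverage_table(m: CoverageMatrix, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {"scaffold": list(m.scaffolds), "length": np.asarray(m.scaffold_lengths, dtype=int)}
    )
    for i, s in enumerate(m.samples):
        df[s] = np.asarray(m.raw_counts[i], dtype=int)
    df.to_csv(path, sep="\t", index=False)


__all__ = [
    "SimCodonSpec",
    "SimGenomeSpec",
    "default_test_tree",
    "simulate_codon_alignment",
    "simulate_genome_annotation",
    "simulate_rearrangements",
    "simulate_coverage",
    "write_coverage_table",
]
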