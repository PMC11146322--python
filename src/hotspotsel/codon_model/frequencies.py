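"""Equilibrium codon frequencies (F3x4 default; F1x4/empirical/uniform modes)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hotspotsel.codon_model.states import CodonStateSpace, get_state_space
from hotspotsel.io_formats import CodonAlignment

_NUC = "ACGT"


@dataclass(frozen=True)
class CodonFrequencies:
    """Stationary distribution over sense codons plus its positional basis."""

    pi: np.ndarray  # (n_sense,)
    positional: np.ndarray | None = None  # (3, 4) nucleotide freqs per position

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if np.any(pi < 0):
            raise ValueError("negative codon frequency")
        if abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must sum to 1")


def _positional_counts(alignment: CodonAlignment) -> np.ndarray:
    counts = np.zeros((3, 4), dtype=float)
    lut = {n: k for k, n in enumerate(_NUC)}
    for seq in alignment.sequences.values():
        for pos in range(len(seq)):
            k = lut.get(seq[pos])
            if k is not None:
                counts[pos % 3, k] += 1
    return counts


def f3x4_frequencies(
    alignment: CodonAlignment, space: CodonStateSpace | None = None
) -> CodonFrequencies:
    """Positional nucleotide frequencies -> codon frequencies over sense codons.

    pi_c is proportional to f1(c1) * f2(c2) * f3(c3), renormalized after
    excluding stop codons.  Ambiguity characters and gaps are ignored when
    counting.
    """
    space = space or get_state_space(1)
    counts = _positional_counts(alignment)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        empty = [k + 1 for k in range(3) if totals[k] == 0]
        raise ValueError(f"no unambiguous nucleotides at codon position(s) {empty}")
    positional = counts / totals[:, None]
    nuc_idx = space.codon_position_nucleotides()
    pi = (
        positional[0, nuc_idx[:, 0]]
        * positional[1, nuc_idx[:, 1]]
        * positional[2, nuc_idx[:, 2]]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate composition: all mass on stop codons")
    return CodonFrequencies(pi / total, positional)


def f1x4_frequencies(
    alignment: CodonAlignment, space: CodonStateSpace | None = None
) -> CodonFrequencies:
    space = space or get_state_space(1)
    counts = _positional_counts(alignment).sum(axis=0)
    if counts.sum() == 0:
        raise ValueError("no unambiguous nucleotides in alignment")
    f = counts / counts.sum()
    nuc_idx = space.codon_position_nucleotides()
    pi = f[nuc_idx[:, 0]] * f[nuc_idx[:, 1]] * f[nuc_idx[:, 2]]
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate composition: all mass on stop codons")
    return CodonFrequencies(pi / total, np.tile(f, (3, 1)))


def empirical_codon_frequencies(
    alignment: CodonAlignment, space: CodonStateSpace | None = None
) -> CodonFrequencies:
    """Observed sense-codon proportions with a small floor to avoid zeros."""
    space = space or get_state_space(1)
    idx = space.index
    counts = np.zeros(space.n, dtype=float)
    for taxon in alignment.taxa:
        seq = alignment.sequences[taxon]
        for i in range(0, len(seq), 3):
            j = idx.get(seq[i : i + 3])
            if j is not None:
                counts[j] += 1
    if counts.sum() == 0:
        raise ValueError("no unambiguous sense codons observed")
    counts += 0.5  # pseudocount keeps the chain irreducible
    return CodonFrequencies(counts / counts.sum(), None)


def uniform_frequencies(space: CodonStateSpace | None = None) -> CodonFrequencies:
    space = space or get_state_space(1)
    return CodonFrequencies(np.full(space.n, 1.0 / space.n), np.full((3, 4), 0.25))


def codon_frequencies(
    alignment: CodonAlignment,
    mode: str = "F3x4",
    space: CodonStateSpace | None = None,
) -> CodonFrequencies:
    mode_l = mode.lower()
    if mode_l == "f3x4":
        return f3x4_frequencies(alignment, space)
    if mode_l == "f1x4":
        return f1x4_frequencies(alignment, space)
    if mode_l in ("empirical", "fcodon"):
        return empirical_codon_frequencies(alignment, space)
    if mode_l == "uniform":
        return uniform_frequencies(space)
    raise ValueError(f"unknown frequency mode {mode!r}")
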