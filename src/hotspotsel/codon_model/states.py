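"""Sense-codon state space derived from an NCBI genetic code table."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

import numpy as np
from Bio.Data import CodonTable

_NUC = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass(frozen=True)
class CodonStateSpace:
    """Ordered sense codons for one genetic code, with single-step structure."""

    genetic_code_id: int
    codons: tuple[str, ...]
    stop_codons: frozenset[str]
    amino_acids: tuple[str, ...]
    # parallel arrays over single-nucleotide-difference codon pairs (i < j)
    pair_i: np.ndarray = field(repr=False, compare=False, default=None)
    pair_j: np.ndarray = field(repr=False, compare=False, default=None)
    pair_transition: np.ndarray = field(repr=False, compare=False, default=None)
    pair_nonsyn: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def n(self) -> int:
        return len(self.codons)

    @property
    def index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.codons)}

    def codon_position_nucleotides(self) -> np.ndarray:
        """(n, 3) array of nucleotide indices (A=0,C=1,G=2,T=3) per codon."""
        lut = {n: k for k, n in enumerate(_NUC)}
        return np.array([[lut[n] for n in c] for c in self.codons], dtype=np.int64)


@lru_cache(maxsize=8)
def get_state_space(genetic_code_id: int = 1) -> CodonStateSpace:
    table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    stops = frozenset(table.stop_codons)
    codons = tuple(
        "".join(c) for c in product(_NUC, repeat=3) if "".join(c) not in stops
    )
    aas = tuple(table.forward_table["".join(c)] for c in codons)
    pi_, pj_, tr_, ns_ = [], [], [], []
    for i, ci in enumerate(codons):
        for j in range(i + 1, len(codons)):
            cj = codons[j]
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            (k,) = diff
            pi_.append(i)
            pj_.append(j)
            tr_.append(_is_transition(ci[k], cj[k]))
            ns_.append(aas[i] != aas[j])
    return CodonStateSpace(
        genetic_code_id,
        codons,
        stops,
        aas,
        np.array(pi_, dtype=np.int64),
        np.array(pj_, dtype=np.int64),
        np.array(tr_, dtype=bool),
        np.array(ns_, dtype=bool),
    )
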