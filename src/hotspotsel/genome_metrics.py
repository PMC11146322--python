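"""GC composition of coding sequences and coverage normalization with
sex-chromosome (bimodality) detection."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

GC_CHARS = set("GC")
AT_CHARS = set("AT")

LOW_BAND = (0.35, 0.65)
HIGH_BAND = (0.85, 1.15)
MIN_FRAC = 0.2


def gc_content(sequence: str) -> float:
    """Percent G+C among unambiguous bases; gaps/ambiguity codes excluded."""
    seq = sequence.upper()
    gc = sum(1 for c in seq if c in GC_CHARS)
    at = sum(1 for c in seq if c in AT_CHARS)
    if gc + at == 0:
        raise ValueError("no unambiguous A/C/G/T bases in sequence")
    return 100.0 * gc / (gc + at)


@dataclass(frozen=True)
class CoverageMatrix:
    """Per-sample, per-scaffold mapped-read sums plus scaffold lengths."""

    samples: tuple[str, ...]
    scaffolds: tuple[str, ...]
    raw_counts: np.ndarray  # (n_samples, n_scaffolds)
    scaffold_lengths: np.ndarray  # (n_scaffolds,)

    def __post_init__(self):
        counts = np.asarray(self.raw_counts, dtype=float)
        if counts.shape != (len(self.samples), len(self.scaffolds)):
            raise ValueError("count matrix shape does not match labels")
        if np.any(counts < 0):
            raise ValueError("negative read counts")
        if len(self.scaffold_lengths) != len(self.scaffolds):
            raise ValueError("scaffold length vector shape mismatch")
        if np.any(np.asarray(self.scaffold_lengths) <= 0):
            raise ValueError("scaffold lengths must be positive")


def read_coverage_table(path) -> CoverageMatrix:
    """bedcov-style TSV: scaffold, length, then one count column per sample."""
    df = pd.read_csv(Path(path), sep="\t")
    if df.shape[1] < 3:
        raise ValueError("expected columns: scaffold, length, >=1 sample")
    scaffolds = tuple(df.iloc[:, 0].astype(str))
    lengths = df.iloc[:, 1].to_numpy(dtype=float)
    samples = tuple(df.columns[2:])
    counts = df.iloc[:, 2:].to_numpy(dtype=float).T
    return CoverageMatrix(samples, scaffolds, counts, lengths)


@dataclass(frozen=True)
class NormalizedCoverage:
    """Relative coverage (grand mean 1) and per-scaffold CV across samples."""

    samples: tuple[str, ...]
    scaffolds: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_scaffolds)
    cv: np.ndarray  # (n_scaffolds,)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.samples), columns=list(self.scaffolds))


def normalize_coverage(m: CoverageMatrix) -> NormalizedCoverage:
    """v_ij = (c_ij / (len_j * T_i)) / grand mean of that quantity.

    T_i is the per-sample total over the analyzed scaffolds only.  By
    construction the mean over all sample-scaffold pairs is 1.
    """
    counts = np.asarray(m.raw_counts, dtype=float)
    totals = counts.sum(axis=1)
    zero = [m.samples[i] for i in np.nonzero(totals == 0)[0]]
    if zero:
        raise ValueError(f"sample(s) with zero mapped reads: {zero}")
    lengths = np.asarray(m.scaffold_lengths, dtype=float)
    rel = counts / (lengths[None, :] * totals[:, None])
    values = rel / rel.mean()
    means = values.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(means > 0, values.std(axis=0, ddof=1) / means, np.nan)
    return NormalizedCoverage(m.samples, m.scaffolds, values, cv)


def detect_sex_linked(
    n: NormalizedCoverage,
    low_band: tuple[float, float] = LOW_BAND,
    high_band: tuple[float, float] = HIGH_BAND,
    min_frac: float = MIN_FRAC,
    gap_tolerance: float = 0.0,
) -> list[str]:
    """Flag scaffolds with a bimodal coverage dose across samples.

    Each sample's values are expressed relative to its own autosomal
    baseline (median over all scaffolds).  A scaffold is flagged when at
    least ``min_frac`` of samples sit in each of the low (~0.5x) and high
    (~1x) bands and no sample falls strictly between the bands by more
    than ``gap_tolerance``.
    """
    values = np.asarray(n.values, dtype=float)
    n_samples = values.shape[0]
    if n_samples < 4:
        raise ValueError(f"need >= 4 samples to assess bimodality; got {n_samples}")
    baseline = np.median(values, axis=1)
    ratios = values / baseline[:, None]
    flagged = []
    for j, scaffold in enumerate(n.scaffolds):
        r = ratios[:, j]
        in_low = (low_band[0] <= r) & (r <= low_band[1])
        in_high = (high_band[0] <= r) & (r <= high_band[1])
        between = (r > low_band[1] + gap_tolerance) & (r < high_band[0] - gap_tolerance)
        if (
            in_low.mean() >= min_frac
            and in_high.mean() >= min_frac
            and not between.any()
        ):
            flagged.append(scaffold)
    return flagged


__all__ = [
    "gc_content",
    "CoverageMatrix",
    "NormalizedCoverage",
    "read_coverage_table",
    "normalize_coverage",
    "detect_sex_linked",
]
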