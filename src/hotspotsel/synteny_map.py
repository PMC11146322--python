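"""Cross-species synteny-block extraction and comparison.

Blocks are landmark-list driven: a block definition names ordered landmark
genes in a reference species, and a per-species instance records presence,
coordinates, orientation, and order of those landmarks.  Comparisons are
computed up to whole-linkage-group reversal, since the plus-strand
designation of a linkage group is arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import pandas as pd

from hotspotsel.io_formats import GeneLocus

GAP_THRESHOLD = 10_000_000

LINKED = "linked"
SAME_GROUP_DISTANT = "same-group-distant"
UNLINKED = "unlinked"


@dataclass(frozen=True)
class BlockDef:
    """Named block: ordered landmark symbols in the reference species."""

    name: str
    landmark_symbols: tuple[str, ...]
    reference_species: str = "human"

    def __post_init__(self):
        if len(set(self.landmark_symbols)) != len(self.landmark_symbols):
            raise ValueError(f"duplicate landmark symbols in block {self.name}")
        if not self.landmark_symbols:
            raise ValueError(f"block {self.name} has no landmarks")


@dataclass(frozen=True)
class LandmarkPlacement:
    """One landmark's state within one species' block instance."""

    symbol: str
    ref_index: int  # 1-based order in the reference
    present: bool
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    order_index: int | None = None  # 1-based rank among present landmarks


@dataclass(frozen=True)
class BlockInstance:
    """A block as realized in one species."""

    species: str
    block: str
    landmarks: tuple[LandmarkPlacement, ...]

    @property
    def present(self) -> tuple[LandmarkPlacement, ...]:
        return tuple(p for p in self.landmarks if p.present)

    @property
    def chromosomes(self) -> set[str]:
        return {p.chrom for p in self.present}

    def extent(self, chrom: str) -> tuple[int, int]:
        placed = [p for p in self.present if p.chrom == chrom]
        return min(p.start for p in placed), max(p.end for p in placed)


@dataclass(frozen=True)
class LinkageCall:
    """Linkage relation between two blocks (or genes)."""

    a: str
    b: str
    category: str  # LINKED | SAME_GROUP_DISTANT | UNLINKED
    gap: int | None = None
    species: str | None = None

    def __post_init__(self):
        if (self.category == UNLINKED) != (self.gap is None):
            raise ValueError("gap must be defined iff blocks share a linkage group")


def extract_block(annotation: Sequence[GeneLocus], block: BlockDef, species: str = "") -> BlockInstance:
    """Locate each landmark of ``block`` in a species annotation.

    Order indices rank present landmarks by (chromosome, start); a landmark
    nested entirely within another shares the outer landmark's rank.
    """
    wanted = set(block.landmark_symbols)
    loci: dict[str, GeneLocus] = {}
    for g in annotation:
        if g.symbol in wanted:
            if g.symbol in loci:
                raise ValueError(
                    f"ambiguous landmark {g.symbol}: "
                    f"{loci[g.symbol].chrom}:{loci[g.symbol].start} and {g.chrom}:{g.start}"
                )
            loci[g.symbol] = g
    placements = []
    for ref_index, symbol in enumerate(block.landmark_symbols, start=1):
        g = loci.get(symbol)
        if g is None:
            placements.append(LandmarkPlacement(symbol, ref_index, present=False))
        else:
            placements.append(
                LandmarkPlacement(
                    symbol, ref_index, True, g.chrom, g.start, g.end, g.strand
                )
            )
    placements = _assign_order(placements)
    return BlockInstance(species or block.reference_species, block.name, tuple(placements))


def _assign_order(placements: list[LandmarkPlacement]) -> list[LandmarkPlacement]:
    present = sorted(
        (p for p in placements if p.present), key=lambda p: (p.chrom, p.start, p.end)
    )
    ranks: dict[str, int] = {}
    rank = 0
    prev = None
    for p in present:
        nested = (
            prev is not None
            and p.chrom == prev.chrom
            and p.start >= prev.start
            and p.end <= prev.end
        )
        if not nested:
            rank += 1
            prev = p
        ranks[p.symbol] = rank
    return [
        replace(p, order_index=ranks.get(p.symbol)) if p.present else p
        for p in placements
    ]


def _extents(obj) -> dict[str, tuple[int, int]]:
    if isinstance(obj, GeneLocus):
        return {obj.chrom: (obj.start, obj.end)}
    if isinstance(obj, BlockInstance):
        if not obj.present:
            raise ValueError(f"block {obj.block} has no present landmarks")
        return {c: obj.extent(c) for c in obj.chromosomes}
    raise TypeError(f"cannot classify linkage of {type(obj).__name__}")


def _label(obj) -> str:
    return obj.symbol if isinstance(obj, GeneLocus) else obj.block


def classify_linkage(a, b, gap_threshold: int = GAP_THRESHOLD, species: str | None = None) -> LinkageCall:
    """Linked / same-group-distant / unlinked call for two blocks or genes.

    The gap is measured edge-to-edge between the nearest landmark
    boundaries on a shared linkage group (0 if the extents overlap).
    """
    ea, eb = _extents(a), _extents(b)
    shared = set(ea) & set(eb)
    if not shared:
        return LinkageCall(_label(a), _label(b), UNLINKED, species=species)
    gap = None
    for chrom in shared:
        (sa, xa), (sb, xb) = ea[chrom], eb[chrom]
        g = max(0, max(sa, sb) - min(xa, xb))
        gap = g if gap is None else min(gap, g)
    category = LINKED if gap <= gap_threshold else SAME_GROUP_DISTANT
    return LinkageCall(_label(a), _label(b), category, gap=gap, species=species)


def _signed_adjacencies(inst: BlockInstance, shared: set[str]) -> set[tuple]:
    """Orientation-symmetric adjacency set over the shared landmarks.

    Landmarks are read per linkage group in coordinate order; each
    consecutive pair yields a canonical signed adjacency, invariant to
    reading direction (global reversal of the group).
    """
    sign = {"+": 1, "-": -1}
    adjacencies = set()
    by_chrom: dict[str, list[LandmarkPlacement]] = {}
    for p in inst.present:
        if p.symbol in shared:
            by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, placed in by_chrom.items():
        placed.sort(key=lambda p: (p.start, p.end))
        for left, right in zip(placed, placed[1:]):
            fwd = ((left.ref_index, sign[left.strand]), (right.ref_index, sign[right.strand]))
            rev = ((right.ref_index, -sign[right.strand]), (left.ref_index, -sign[left.strand]))
            adjacencies.add(min(fwd, rev))
    return adjacencies


def breakpoint_distance(a: BlockInstance, b: BlockInstance) -> int:
    """Signed adjacencies present in ``a`` but absent in ``b`` on the
    shared-landmark restriction."""
    shared = {p.symbol for p in a.present} & {p.symbol for p in b.present}
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 shared landmarks to compare {a.block}; got {len(shared)}"
        )
    return len(_signed_adjacencies(a, shared) - _signed_adjacencies(b, shared))


def scaffold_partition_count(inst: BlockInstance) -> int:
    """Number of linkage groups the present landmarks occupy (fission state)."""
    return len(inst.chromosomes)


def render_comparison_table(
    instances: Sequence[BlockInstance],
    calls: Sequence[LinkageCall] = (),
) -> pd.DataFrame:
    """One row per species x landmark, plus per-species linkage annotations."""
    call_by_species: dict[str | None, list[LinkageCall]] = {}
    for c in calls:
        call_by_species.setdefault(c.species, []).append(c)
    rows = []
    for inst in instances:
        linkage = "; ".join(
            f"{c.a}~{c.b}:{c.category}" for c in call_by_species.get(inst.species, [])
        )
        for p in inst.landmarks:
            rows.append(
                {
                    "species": inst.species,
                    "block": inst.block,
                    "symbol": p.symbol,
                    "chrom": p.chrom,
                    "start": p.start,
                    "strand": p.strand,
                    "species_order": p.order_index,
                    "reference_order": p.ref_index,
                    "present": p.present,
                    "linkage": linkage,
                }
            )
    columns = [
        "species", "block", "symbol", "chrom", "start", "strand",
        "species_order", "reference_order", "present", "linkage",
    ]
    return pd.DataFrame(rows, columns=columns)


__all__ = [
    "GAP_THRESHOLD",
    "LINKED",
    "SAME_GROUP_DISTANT",
    "UNLINKED",
    "BlockDef",
    "LandmarkPlacement",
    "BlockInstance",
    "LinkageCall",
    "extract_block",
    "classify_linkage",
    "breakpoint_distance",
    "scaffold_partition_count",
    "render_comparison_table",
]
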