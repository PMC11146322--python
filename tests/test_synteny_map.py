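import numpy as np
import pytest

from hotspotsel.io_formats import GeneLocus
from hotspotsel.synteny_map import (
    LINKED,
    SAME_GROUP_DISTANT,
    UNLINKED,
    BlockDef,
    breakpoint_distance,
    classify_linkage,
    extract_block,
    render_comparison_table,
    scaffold_partition_count,
)
from hotspotsel.synthetic_data import simulate_rearrangements

MB = 1_000_000


def reference_annotation(n=6, chrom="chrR", spacing=MB, strand="+"):
    return [
        GeneLocus(f"G{i + 1}", chrom, spacing * (i + 1), spacing * (i + 1) + 10_000, strand)
        for i in range(n)
    ]


def block_def(n=6):
    return BlockDef("NF", tuple(f"G{i + 1}" for i in range(n)))


class TestExtractBlock:
    def test_reference_identity(self):
        inst = extract_block(reference_annotation(), block_def(), species="ref")
        assert [p.order_index for p in inst.landmarks] == [1, 2, 3, 4, 5, 6]
        assert all(p.present for p in inst.landmarks)
        assert all(p.strand == "+" for p in inst.landmarks)

    def test_missing_landmark_flagged(self):
        ann = [g for g in reference_annotation() if g.symbol != "G3"]
        inst = extract_block(ann, block_def(), species="sp")
        by = {p.symbol: p for p in inst.landmarks}
        assert not by["G3"].present
        assert by["G3"].order_index is None
        assert [p.order_index for p in inst.present] == [1, 2, 3, 4, 5]

    def test_duplicate_symbol_ambiguity(self):
        ann = reference_annotation() + [GeneLocus("G2", "chrX", 5, 10)]
        with pytest.raises(ValueError, match="ambiguous"):
            extract_block(ann, block_def())

    def test_invariant_to_record_order(self, rng):
        ann = reference_annotation()
        shuffled = [ann[i] for i in rng.permutation(len(ann))]
        assert extract_block(ann, block_def()) == extract_block(shuffled, block_def())

    def test_nested_gene_shares_order_index(self):
        ann = [
            GeneLocus("G1", "chrR", 1 * MB, 3 * MB),
            GeneLocus("G2", "chrR", 2 * MB, int(2.1 * MB)),  # inside G1
            GeneLocus("G3", "chrR", 5 * MB, 6 * MB),
        ]
        inst = extract_block(ann, block_def(3))
        by = {p.symbol: p for p in inst.landmarks}
        assert by["G1"].order_index == by["G2"].order_index == 1
        assert by["G3"].order_index == 2

    def test_inverted_segment_order_and_signs(self):
        base = extract_block(reference_annotation(5), block_def(5), species="ref")
        mutated, _ = simulate_rearrangements(base, [("inversion", 2, 4)])
        order = [p.order_index for p in mutated.present]
        ref_at_order = sorted(mutated.present, key=lambda p: p.order_index)
        assert [p.ref_index for p in ref_at_order] == [1, 2, 5, 4, 3]
        signs = {p.symbol: p.strand for p in mutated.present}
        assert signs["G1"] == signs["G2"] == "+"
        assert signs["G3"] == signs["G4"] == signs["G5"] == "-"


class TestClassifyLinkage:
    def mk(self, chrom, start_mb, n=3, name="B"):
        ann = [
            GeneLocus(f"{name}{i}", chrom, int((start_mb + i) * MB),
                      int((start_mb + i) * MB) + 10_000)
            for i in range(n)
        ]
        return extract_block(ann, BlockDef(name, tuple(f"{name}{i}" for i in range(n))))

    def test_small_gap_linked(self):
        call = classify_linkage(self.mk("chr1", 0, name="A"), self.mk("chr1", 4, name="B"))
        assert call.category == LINKED
        assert call.gap == pytest.approx(4 * MB - 10_000 - 2 * MB)

    def test_large_gap_same_group_distant(self):
        call = classify_linkage(self.mk("chr1", 0, name="A"), self.mk("chr1", 15, name="B"))
        assert call.category == SAME_GROUP_DISTANT
        assert call.gap > 10 * MB

    def test_threshold_rule_exact(self):
        a = GeneLocus("x", "chr1", 0, MB)
        b = GeneLocus("y", "chr1", MB + 10 * MB, MB + 10 * MB + 1)
        assert classify_linkage(a, b).category == LINKED  # gap exactly 10 Mb
        b2 = GeneLocus("y", "chr1", MB + 10 * MB + 1, MB + 10 * MB + 2)
        assert classify_linkage(a, b2).category == SAME_GROUP_DISTANT

    def test_different_scaffolds_unlinked(self):
        call = classify_linkage(self.mk("chr1", 0, name="A"), self.mk("chr2", 0, name="B"))
        assert call.category == UNLINKED
        assert call.gap is None

    def test_overlapping_extents_gap_zero(self):
        call = classify_linkage(self.mk("chr1", 0, name="A"), self.mk("chr1", 1, name="B"))
        assert call.gap == 0


class TestBreakpointDistance:
    def base(self, n=6):
        return extract_block(reference_annotation(n), block_def(n), species="ref")

    def test_identity_zero(self):
        assert breakpoint_distance(self.base(), self.base()) == 0

    def test_full_reversal_zero(self):
        fwd = self.base()
        rev_ann = [
            GeneLocus(f"G{i + 1}", "chrR", MB * (6 - i), MB * (6 - i) + 10_000, "-")
            for i in range(6)
        ]
        rev = extract_block(rev_ann, block_def(), species="rev")
        assert breakpoint_distance(fwd, rev) == 0
        assert breakpoint_distance(rev, fwd) == 0

    def test_single_internal_inversion_is_two(self):
        fwd = self.base()
        mutated, _ = simulate_rearrangements(fwd, [("inversion", 2, 4)])
        assert breakpoint_distance(fwd, mutated) == 2
        assert breakpoint_distance(mutated, fwd) == 2

    def test_symmetric_on_single_group(self, rng):
        for _ in range(25):
            a, _ = simulate_rearrangements(
                self.base(), [("inversion", *sorted(rng.choice(6, 2, replace=False)))]
            )
            b, _ = simulate_rearrangements(
                self.base(), [("inversion", *sorted(rng.choice(6, 2, replace=False)))]
            )
            assert breakpoint_distance(a, b) == breakpoint_distance(b, a)

    def test_triangle_inequality(self, rng):
        insts = [self.base()]
        for _ in range(6):
            ops = [
                ("inversion", *sorted(rng.choice(6, 2, replace=False)))
                for _ in range(int(rng.integers(1, 3)))
            ]
            insts.append(simulate_rearrangements(self.base(), ops)[0])
        for a in insts:
            for b in insts:
                for c in insts:
                    assert breakpoint_distance(a, c) <= (
                        breakpoint_distance(a, b) + breakpoint_distance(b, c)
                    )

    def test_bounded_by_twice_inversions(self, rng):
        for _ in range(20):
            k = int(rng.integers(1, 4))
            ops = [
                ("inversion", *sorted(rng.choice(6, 2, replace=False)))
                for _ in range(k)
            ]
            mutated, _ = simulate_rearrangements(self.base(), ops)
            assert breakpoint_distance(self.base(), mutated) <= 2 * k

    def test_too_few_shared_landmarks(self):
        a = self.base(6)
        lone = extract_block(reference_annotation(1), block_def(1))
        with pytest.raises(ValueError, match="shared"):
            breakpoint_distance(a, lone)


class TestRenderComparisonTable:
    def test_single_species_rows(self):
        inst = extract_block(reference_annotation(3), block_def(3), species="sp1")
        table = render_comparison_table([inst])
        assert len(table) == 3
        assert list(table["symbol"]) == ["G1", "G2", "G3"]

    def test_empty_instances_header_only(self):
        table = render_comparison_table([])
        assert len(table) == 0
        assert "reference_order" in table.columns

    def test_merged_blocks_linked_in_one_species_only(self):
        nf_def = BlockDef("NF", ("N1", "N2"))
        ce_def = BlockDef("CE", ("C1", "C2"))

        def ann(merged: bool):
            chrom_ce = "chr1" if merged else "chr2"
            return [
                GeneLocus("N1", "chr1", 1 * MB, 1 * MB + 10_000),
                GeneLocus("N2", "chr1", 2 * MB, 2 * MB + 10_000),
                GeneLocus("C1", chrom_ce, 4 * MB, 4 * MB + 10_000),
                GeneLocus("C2", chrom_ce, 5 * MB, 5 * MB + 10_000),
            ]

        calls, instances = [], []
        for species, merged in (("merged_sp", True), ("split_sp", False)):
            nf = extract_block(ann(merged), nf_def, species=species)
            ce = extract_block(ann(merged), ce_def, species=species)
            instances += [nf, ce]
            calls.append(classify_linkage(nf, ce, species=species))
        table = render_comparison_table(instances, calls)
        merged_rows = table[table["species"] == "merged_sp"]
        split_rows = table[table["species"] == "split_sp"]
        assert (merged_rows["linkage"] == "NF~CE:linked").all()
        assert (split_rows["linkage"] == "NF~CE:unlinked").all()


class TestFission:
    def test_partition_count(self):
        base = extract_block(reference_annotation(6), block_def(6))
        split, _ = simulate_rearrangements(base, [("fission", 3)])
        assert scaffold_partition_count(base) == 1
        assert scaffold_partition_count(split) == 2
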