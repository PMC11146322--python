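
import numpy as np
import pytest

from hotspotsel.codon_model import (
    CodonModelParams,
    build_rate_matrix,
    f3x4_frequencies,
    log_likelihood,
    transition_matrix,
)
from hotspotsel.codon_model.frequencies import (
    CodonFrequencies,
    codon_frequencies,
    uniform_frequencies,
)
from hotspotsel.codon_model.likelihood import PruningEngine
from hotspotsel.codon_model.states import get_state_space
from hotspotsel.io_formats import CodonAlignment, read_labeled_tree

SPACE = get_state_space(1)


class TestStateSpace:
    def test_standard_code_has_61_sense_codons(self):
        assert SPACE.n == 61
        assert SPACE.stop_codons == {"TAA", "TAG", "TGA"}

    def test_single_step_pairs_only(self):
        for i, j in zip(SPACE.pair_i, SPACE.pair_j):
            ci, cj = SPACE.codons[i], SPACE.codons[j]
            assert sum(a != b for a, b in zip(ci, cj)) == 1


class TestF3x4:
    def test_uniform_composition_gives_uniform_pi(self):
        # one sequence per nucleotide rotation: every position sees A,C,G,T equally
        seqs = {
            "t1": "AAA CCC GGG TTT".replace(" ", ""),
            "t2": "CCC GGG TTT AAA".replace(" ", ""),
            "t3": "GGG TTT AAA CCC".replace(" ", ""),
            "t4": "TTT AAA CCC GGG".replace(" ", ""),
        }
        aln = CodonAlignment("u", tuple(seqs), seqs)
        fr = f3x4_frequencies(aln)
        np.testing.assert_allclose(fr.pi, np.full(61, 1 / 61), atol=1e-12)

    def test_all_aaa_degenerate(self):
        aln = CodonAlignment("d", ("a", "b"), {"a": "AAAAAA", "b": "AAAAAA"})
        fr = f3x4_frequencies(aln)
        # all mass on the single observable codon (AAA, a lysine codon)
        assert fr.pi[SPACE.index["AAA"]] == pytest.approx(1.0)

    def test_random_alignment_sums_to_one(self, rng):
        nt = "ACGT"
        seqs = {
            f"t{i}": "".join(rng.choice(list(nt), size=1500)) for i in range(6)
        }
        aln = CodonAlignment("r", tuple(seqs), seqs)
        fr = f3x4_frequencies(aln)
        assert abs(fr.pi.sum() - 1.0) < 1e-12

    def test_gap_only_position_errors(self):
        aln = CodonAlignment("g", ("a",), {"a": "A-A"})
        with pytest.raises(ValueError):
            f3x4_frequencies(aln)

    @pytest.mark.parametrize("mode", ["F3x4", "F1x4", "empirical", "uniform"])
    def test_modes_all_normalized(self, mode, small_alignment):
        fr = codon_frequencies(small_alignment, mode=mode)
        assert abs(fr.pi.sum() - 1.0) < 1e-9


class TestRateMatrix:
    def params(self, kappa=2.0, omega=0.5):
        return CodonModelParams(kappa, omega, uniform_frequencies(SPACE))

    def test_rows_sum_to_zero(self):
        Q = build_rate_matrix(self.params())
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_multi_step_rate_zero(self):
        Q = build_rate_matrix(self.params())
        i, j = SPACE.index["AAA"], SPACE.index["GGA"]
        assert Q[i, j] == 0.0
        assert Q[j, i] == 0.0

    def test_scaling_identity(self, small_alignment):
        fr = f3x4_frequencies(small_alignment)
        params = CodonModelParams(3.1, 1.7, fr)
        Q = build_rate_matrix(params)
        assert abs(-np.dot(fr.pi, np.diag(Q)) - 1.0) < 1e-10

    def test_neutral_uniform_symmetric(self):
        Q = build_rate_matrix(self.params(kappa=1.0, omega=1.0))
        np.testing.assert_allclose(Q, Q.T, atol=1e-12)

    def test_detailed_balance(self, small_alignment):
        fr = f3x4_frequencies(small_alignment)
        Q = build_rate_matrix(CodonModelParams(2.5, 0.3, fr))
        flux = fr.pi[:, None] * Q
        np.testing.assert_allclose(flux, flux.T, atol=1e-12)


class TestTransitionMatrix:
    def setup_method(self):
        self.fr = uniform_frequencies(SPACE)
        self.Q = build_rate_matrix(CodonModelParams(2.0, 0.5, self.fr))

    def test_zero_time_identity(self):
        np.testing.assert_allclose(
            transition_matrix(self.Q, 0.0, self.fr.pi), np.eye(61), atol=1e-12
        )

    def test_ergodic_limit(self):
        P = transition_matrix(self.Q, 50.0, self.fr.pi)
        np.testing.assert_allclose(P, np.tile(self.fr.pi, (61, 1)), atol=1e-6)

    def test_rows_sum_to_one(self):
        P = transition_matrix(self.Q, 0.1, self.fr.pi)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_spectral_matches_expm(self):
        P_eig = transition_matrix(self.Q, 0.37, self.fr.pi)
        P_expm = transition_matrix(self.Q, 0.37)  # scipy expm route
        np.testing.assert_allclose(P_eig, P_expm, atol=1e-10)


def brute_force_lnl(aln, ta, tb, tcd, tc, td, params, fg=()):
    """Exhaustive 61x61 internal-state enumeration for ((A,B),(C,D))."""
    space = SPACE
    pi = params.freqs.pi

    def pmat(t, which):
        Q = build_rate_matrix(params, which, space)
        return transition_matrix(Q, t)

    Pa = pmat(ta, "foreground" if "a" in fg else "background")
    Pb = pmat(tb, "foreground" if "b" in fg else "background")
    Pcd = pmat(tcd, "foreground" if "cd" in fg else "background")
    Pc = pmat(tc, "foreground" if "c" in fg else "background")
    Pd = pmat(td, "foreground" if "d" in fg else "background")
    idx = space.index
    total = 0.0
    for site in range(aln.n_codons):
        obs = {t: idx[aln.codon(t, site)] for t in aln.taxa}
        like = 0.0
        for x in range(61):
            left = pi[x] * Pa[x, obs["A"]] * Pb[x, obs["B"]]
            inner = 0.0
            for y in range(61):
                inner += Pcd[x, y] * Pc[y, obs["C"]] * Pd[y, obs["D"]]
            like += left * inner
        total += np.log(like)
    return total


class TestLogLikelihood:
    def test_zero_distance_two_taxa(self):
        aln = CodonAlignment("z", ("A", "B"), {"A": "ATG", "B": "ATG"})
        fr = uniform_frequencies(SPACE)
        tree = read_labeled_tree("(A:0.0,B:0.0);")
        lnl = log_likelihood(aln, tree, CodonModelParams(2.0, 0.5, fr))
        assert lnl == pytest.approx(np.log(fr.pi[SPACE.index["ATG"]]), abs=1e-10)

    def test_matches_exhaustive_enumeration(self, rng):
        taxa = ("A", "B", "C", "D")
        seqs = {
            t: "".join(rng.choice(SPACE.codons, size=5)) for t in taxa
        }
        aln = CodonAlignment("toy", taxa, seqs)
        fr = f3x4_frequencies(aln)
        params = CodonModelParams(1.8, 0.6, fr)
        tree = read_labeled_tree("((A:0.12,B:0.21):0.07,(C:0.33,D:0.09):0.11);")
        lnl = log_likelihood(aln, tree, params)
        # basal bifurcation: the two inner edges act as one 0.07+0.11 edge
        expected = brute_force_lnl(aln, 0.12, 0.21, 0.18, 0.33, 0.09, params)
        assert lnl == pytest.approx(expected, abs=1e-10)

    def test_matches_enumeration_with_foreground(self, rng):
        taxa = ("A", "B", "C", "D")
        seqs = {t: "".join(rng.choice(SPACE.codons, size=5)) for t in taxa}
        aln = CodonAlignment("toy", taxa, seqs)
        fr = f3x4_frequencies(aln)
        params = CodonModelParams(2.2, 0.3, fr, omega_foreground=1.9)
        tree = read_labeled_tree(
            "((A:0.12,B:0.21):0.07,(C:0.33,D:0.09):0.11);", foreground_tags=["C"]
        )
        lnl = log_likelihood(aln, tree, params)
        expected = brute_force_lnl(
            aln, 0.12, 0.21, 0.18, 0.33, 0.09, params, fg={"c"}
        )
        assert lnl == pytest.approx(expected, abs=1e-10)

    def test_doubling_columns_doubles_lnl(self, quartet_tree, rng):
        taxa = ("A", "B", "C", "D")
        seqs = {t: "".join(rng.choice(SPACE.codons, size=10)) for t in taxa}
        aln = CodonAlignment("toy", taxa, seqs)
        doubled = CodonAlignment("toy2", taxa, {t: s + s for t, s in seqs.items()})
        fr = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, 0.5, fr)
        assert log_likelihood(doubled, quartet_tree, params) == pytest.approx(
            2 * log_likelihood(aln, quartet_tree, params), abs=1e-8
        )

    def test_invariant_to_taxon_order(self, quartet_tree, rng):
        taxa = ("A", "B", "C", "D")
        seqs = {t: "".join(rng.choice(SPACE.codons, size=20)) for t in taxa}
        aln = CodonAlignment("toy", taxa, seqs)
        rev = CodonAlignment("toy", taxa[::-1], seqs)
        fr = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, 0.5, fr)
        assert log_likelihood(aln, quartet_tree, params) == pytest.approx(
            log_likelihood(rev, quartet_tree, params), abs=1e-10
        )

    def test_gap_codons_are_missing_data(self, quartet_tree):
        seqs = {"A": "ATG", "B": "AT-", "C": "ATG", "D": "ATG"}
        aln = CodonAlignment("g", ("A", "B", "C", "D"), seqs)
        full = CodonAlignment("g", ("A", "C", "D"), {t: "ATG" for t in "ACD"})
        fr = uniform_frequencies(SPACE)
        params = CodonModelParams(2.0, 0.5, fr)
        lnl = log_likelihood(aln, quartet_tree, params)
        pruned = quartet_tree.prune_to(["A", "C", "D"])
        # with B fully missing at the only site, B's tip integrates out:
        # equal to the 3-taxon likelihood on the pruned tree
        lnl3 = log_likelihood(full, pruned, params)
        assert lnl == pytest.approx(lnl3, abs=1e-10)

    def test_taxon_mismatch_raises(self, quartet_tree):
        aln = CodonAlignment("m", ("A", "B"), {"A": "ATG", "B": "ATG"})
        with pytest.raises(ValueError, match="differ"):
            log_likelihood(aln, quartet_tree, CodonModelParams(2.0, 0.5, uniform_frequencies(SPACE)))

    def test_stop_codon_treated_missing_with_warning(self, quartet_tree):
        seqs = {"A": "TAA", "B": "ATG", "C": "ATG", "D": "ATG"}
        aln = CodonAlignment("s", ("A", "B", "C", "D"), seqs)
        params = CodonModelParams(2.0, 0.5, uniform_frequencies(SPACE))
        with pytest.warns(UserWarning, match="stop codon"):
            lnl = log_likelihood(aln, quartet_tree, params)
        assert np.isfinite(lnl)


class TestGradient:
    def test_analytic_matches_numeric(self, small_tree, small_alignment):
        fr = f3x4_frequencies(small_alignment)
        eng = PruningEngine(small_alignment, small_tree.copy(), fr)
        t = eng.initial_edge_lengths()
        _, grad = eng.log_likelihood_and_gradient(2.0, 0.3, 0.9, t)
        for i in range(len(t)):
            tp, tm = t.copy(), t.copy()
            tp[i] += 1e-6
            tm[i] -= 1e-6
            numeric = (
                eng.log_likelihood(2.0, 0.3, 0.9, tp)
                - eng.log_likelihood(2.0, 0.3, 0.9, tm)
            ) / 2e-6
            assert grad[i] == pytest.approx(numeric, rel=1e-4, abs=1e-4)
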