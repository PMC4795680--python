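"""Motif model: backgrounds, log-odds conversion, exact p-value calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sitefree as sf
from sitefree.motifs import MotifError, UnreachablePValueError
from sitefree.synthetic import toy_pwm

from conftest import enumerate_word_scores


class TestBackground:
    @pytest.mark.parametrize(
        "gc,expected",
        [
            (0.5, (0.25, 0.25, 0.25, 0.25)),
            (0.0, (0.5, 0.0, 0.0, 0.5)),
            (0.4, (0.3, 0.2, 0.2, 0.3)),
        ],
    )
    def test_base_probabilities(self, gc, expected):
        np.testing.assert_allclose(sf.make_background(gc).probs, expected)

    @pytest.mark.parametrize("gc", [-0.1, 1.5])
    def test_rejects_out_of_range_gc(self, gc):
        with pytest.raises(MotifError):
            sf.make_background(gc)

    @given(st.floats(0.0, 1.0))
    def test_probs_sum_to_one_and_pair_up(self, gc):
        p = sf.make_background(gc).probs
        assert abs(p.sum() - 1.0) < 1e-12
        assert p[0] == p[3] and p[1] == p[2]
        assert (p >= 0).all()


class TestFrequencyToPwm:
    def test_hand_arithmetic_column(self):
        # counts (10,0,0,0), uniform background, pseudocount scale 1:
        # p_A = 10.25/11, weight_A = ln(p_A / 0.25)
        freq = sf.FrequencyMatrix("m", np.array([[10.0], [0.0], [0.0], [0.0]]))
        pwm = sf.frequency_to_pwm(freq, sf.make_background(0.5), 1.0)
        assert pwm.weights[0, 0] == pytest.approx(math.log((10.25 / 11) / 0.25))
        assert pwm.weights[1, 0] == pytest.approx(math.log((0.25 / 11) / 0.25))

    def test_background_proportional_matrix_is_zero_information(self, rng):
        bg = sf.make_background(0.4)
        counts = np.tile(40.0 * bg.probs[:, None], (1, 7))
        pwm = sf.frequency_to_pwm(sf.FrequencyMatrix("flat", counts), bg, 1.0)
        np.testing.assert_allclose(pwm.weights, 0.0, atol=1e-12)

    def test_degenerate_matrix_without_pseudocount_errors(self):
        freq = sf.FrequencyMatrix("m", np.zeros((4, 3)))
        with pytest.raises(MotifError):
            sf.frequency_to_pwm(freq, sf.make_background(0.5), 0.0)

    def test_reverse_complement_symmetry(self, rng):
        """RC matrix's PWM = original PWM with columns reversed, A<->T, C<->G."""
        counts = rng.random((4, 9)) * 50
        bg = sf.make_background(0.35)
        pwm = sf.frequency_to_pwm(sf.FrequencyMatrix("m", counts), bg)
        rc_counts = counts[[3, 2, 1, 0], :][:, ::-1]
        rc_pwm = sf.frequency_to_pwm(sf.FrequencyMatrix("m_rc", rc_counts), bg)
        np.testing.assert_allclose(rc_pwm.weights, pwm.reverse_complement().weights)
        word = "ACGTGACTA"
        assert pwm.score_word(word) == pytest.approx(
            rc_pwm.score_word(sf.revcomp(word))
        )


class TestScoreDistribution:
    def test_single_zero_column_is_point_mass_at_zero(self):
        pwm = sf.PWM("z", np.zeros((4, 1)))
        dist = sf.score_distribution(pwm, sf.make_background(0.5))
        nonzero = np.flatnonzero(dist.probs)
        assert len(nonzero) == 1
        assert dist.scores[nonzero[0]] == 0
        assert dist.probs[nonzero[0]] == pytest.approx(1.0)

    @pytest.mark.parametrize("length,gc", [(3, 0.5), (5, 0.3), (6, 0.62)])
    def test_matches_exhaustive_enumeration(self, length, gc, rng):
        bg = sf.make_background(gc)
        pwm = sf.frequency_to_pwm(toy_pwm(length, 0.7, rng), bg)
        dist = sf.score_distribution(pwm, bg, resolution=1000)
        # discretize as the distribution does: per column, then sum
        col_grid = np.rint(pwm.weights * 1000).astype(int)
        grid_pwm = sf.PWM(pwm.motif_id, col_grid / 1000.0)
        scores, probs = enumerate_word_scores(grid_pwm, bg)
        grid = np.rint(scores * 1000).astype(int)
        for t in np.unique(grid):
            exact_tail = probs[grid >= t].sum()
            assert dist.tail_at(t / 1000) == pytest.approx(exact_tail, abs=1e-9)

    def test_total_mass_is_one_up_to_l20(self, rng):
        bg = sf.make_background(0.45)
        for length in (2, 8, 14, 20):
            pwm = sf.frequency_to_pwm(toy_pwm(length, 0.8, rng), bg)
            dist = sf.score_distribution(pwm, bg)
            assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestThresholdForPvalue:
    def test_p_near_one_admits_all_but_the_bottom_atom(self, rng):
        # tail probability at the minimum score is exactly 1, so for p just
        # below 1 the threshold lands on the second-lowest attainable score:
        # every word except the worst-scoring ones is a site
        bg = sf.make_background(0.5)
        pwm = sf.frequency_to_pwm(toy_pwm(5, 0.9, rng), bg)
        dist = sf.score_distribution(pwm, bg)
        t = sf.threshold_for_pvalue(dist, 0.999999)
        attained = dist.scores[dist.probs > 0]
        assert round(t * dist.resolution) <= attained[1]

    def test_sharp_length5_pwm_at_p003_admits_one_to_three_words(self, rng):
        # exact-match motif: one strongly preferred base per column; at
        # p=0.003 the threshold admits between 1 and floor(0.003 * 4^5) = 3
        # of the 1024 equiprobable words
        bg = sf.make_background(0.5)
        pwm = sf.frequency_to_pwm(toy_pwm(5, 1.0, rng), bg)
        dist = sf.score_distribution(pwm, bg)
        t = sf.threshold_for_pvalue(dist, 0.003)
        scores, _ = enumerate_word_scores(pwm, bg)
        admitted = (np.rint(scores * 1000) >= round(t * 1000)).sum()
        assert 1 <= admitted <= 3

    def test_antitone_in_p(self, rng):
        bg = sf.make_background(0.4)
        pwm = sf.frequency_to_pwm(toy_pwm(6, 0.75, rng), bg)
        dist = sf.score_distribution(pwm, bg)
        thresholds = [
            sf.threshold_for_pvalue(dist, p) for p in (0.2, 0.05, 0.01, 0.003, 0.0005)
        ]
        assert thresholds == sorted(thresholds)

    def test_resolution_independence_within_a_bin(self, rng):
        bg = sf.make_background(0.5)
        pwm = sf.frequency_to_pwm(toy_pwm(6, 0.8, rng), bg)
        coarse = sf.threshold_for_pvalue(sf.score_distribution(pwm, bg, 200), 0.01)
        fine = sf.threshold_for_pvalue(sf.score_distribution(pwm, bg, 1000), 0.01)
        # per-column rounding can move a word by 0.5/res, the whole score by
        # L/2 bins of the coarser grid
        assert abs(coarse - fine) <= (pwm.length / 2 + 1) / 200

    def test_unreachable_pvalue_reports_attainable_minimum(self, rng):
        bg = sf.make_background(0.5)
        pwm = sf.frequency_to_pwm(toy_pwm(4, 1.0, rng), bg)
        dist = sf.score_distribution(pwm, bg)
        # the single best word has probability 4^-4; anything below that is
        # unreachable
        with pytest.raises(UnreachablePValueError) as exc:
            sf.threshold_for_pvalue(dist, 1e-6)
        assert exc.value.attainable >= 4.0**-4 - 1e-12


class TestParseMotifFile:
    def test_jaspar_style(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">m1\n"
            "A [ 1 2 3 4 5 6 7 8 ]\n"
            "C [ 0 1 0 1 0 1 0 1 ]\n"
            "G [ 2 2 2 2 2 2 2 2 ]\n"
            "T [ 5 4 3 2 1 0 1 2 ]\n"
        )
        matrices, sites = sf.parse_motif_file(path)
        assert sites == []
        assert len(matrices) == 1
        assert matrices[0].motif_id == "m1"
        assert matrices[0].length == 8
        assert matrices[0].counts[0, 3] == 4.0

    def test_headerless_four_row_table(self, tmp_path):
        path = tmp_path / "counts.txt"
        path.write_text("1 2 3\n4 5 6\n7 8 9\n1 1 1\n")
        matrices, _ = sf.parse_motif_file(path)
        assert matrices[0].length == 3
        assert matrices[0].counts[3, 0] == 1.0

    def test_transposed_table_detected_when_unambiguous(self, tmp_path):
        path = tmp_path / "t.txt"
        rows = ["1 0 0 9"] * 6  # 6 rows of 4 columns: positions-as-rows
        path.write_text("\n".join(rows) + "\n")
        matrices, _ = sf.parse_motif_file(path)
        assert matrices[0].length == 6
        assert matrices[0].counts[3, 0] == 9.0

    def test_sites_file_single_pattern(self, tmp_path):
        path = tmp_path / "one.sites"
        path.write_text("CAGGTAG\n")
        _, sites = sf.parse_motif_file(path)
        assert len(sites) == 1
        assert sites[0].patterns == ("CAGGTAG",)

    def test_iupac_expansion_count(self, tmp_path):
        path = tmp_path / "amb.sites"
        path.write_text("# degenerate site\nRGGNCA\n")
        _, sites = sf.parse_motif_file(path)
        assert len(sf.expand_iupac(sites[0].patterns[0])) == 8

    def test_tabbed_ids_group_patterns(self, tmp_path):
        path = tmp_path / "named.sites"
        path.write_text("tf1\tGAATTC\ntf1\tGGATCC\ntf2\tACGT\n")
        _, sites = sf.parse_motif_file(path)
        assert {s.motif_id: len(s.patterns) for s in sites} == {"tf1": 2, "tf2": 1}

    @pytest.mark.parametrize(
        "content,fragment",
        [
            (">m\nA [1 2]\nC [1 2 3]\nG [1 2]\nT [1 2]\n", "unequal"),
            ("GAXTTC\n", "line 1"),
            (">m\nA [1]\nC [1]\nG [1]\n", "3 rows"),
        ],
    )
    def test_malformed_inputs_report_context(self, tmp_path, content, fragment):
        path = tmp_path / "bad.txt"
        path.write_text(content)
        with pytest.raises(MotifError, match=fragment):
            sf.parse_motif_file(path)

    def test_library_rejects_duplicate_ids(self):
        s1 = sf.ExactSiteSet("x", ("ACGT",))
        s2 = sf.ExactSiteSet("x", ("TTTT",))
        with pytest.raises(MotifError, match="duplicate"):
            sf.MotifLibrary(exact_sets=(s1, s2))


@given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=6))
def test_iupac_expansion_size_is_product_of_code_sizes(pattern):
    from sitefree.motifs import IUPAC_CODES

    expected = 1
    for ch in pattern:
        expected *= len(IUPAC_CODES[ch])
    words = sf.expand_iupac(pattern)
    assert len(words) == expected
    assert len(set(words)) == expected
    assert all(set(w) <= set("ACGT") for w in words)


@given(st.text(alphabet="ACGT", min_size=0, max_size=40))
def test_revcomp_is_an_involution(seq):
    assert sf.revcomp(sf.revcomp(seq)) == seq
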