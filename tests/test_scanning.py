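"""Scoring matrices, exact p-values and ranked scans."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _helpers import build_protein, code_table_from_columns
from pprcode.alignment import AlignmentError, SiteWindow
from pprcode.scanning import (
    ALL_MOTIFS,
    P_AND_S_ONLY,
    PPRTargetRanker,
    ScanMode,
    ScoreMatrix,
    binding_matrix,
    exact_pvalues,
    log_odds,
    scan_and_rank,
    scan_transcriptome,
    to_meme,
    to_probability_matrix,
)
from pprcode.training import CodeKey, NUCLEOTIDES
from pprcode.synthetic import make_code, sample_factor, sample_target

MEF11_COLUMN = {"A": 0.73, "C": 0.29, "G": 0.41, "U": 0.0}


class TestBindingMatrix:
    def test_unknown_key_gives_neutral_column(self, bg):
        protein = build_protein(["P", "L2", "S2"],
                                [("T", "N"), ("T", "N"), ("A", "D")])
        code = code_table_from_columns({}, bg)
        bm = binding_matrix(protein, code)
        assert all(col == {n: 1.0 for n in NUCLEOTIDES} for col in bm.columns)

    def test_combo_takes_precedence_over_single_positions(self, bg):
        protein = build_protein(["P", "L2", "S2"],
                                [("T", "N"), ("T", "N"), ("A", "D")])
        code = code_table_from_columns(
            {
                CodeKey("P", "combo", "T", "N"): {"A": 2.0},
                CodeKey("P", "pos6", "T", None): {"C": 2.0},
                CodeKey("P", "pos1p", None, "N"): {"G": 2.0},
            },
            bg,
        )
        bm = binding_matrix(protein, code)
        assert bm.columns[0]["A"] == 2.0 and bm.columns[0]["C"] == 0.0

    def test_pos6_fallback_when_no_combo(self, bg):
        protein = build_protein(["P", "L2", "S2"],
                                [("T", "N"), ("T", "N"), ("A", "D")])
        code = code_table_from_columns(
            {
                CodeKey("P", "pos6", "T", None): {"C": 2.0},
                CodeKey("P", "pos1p", None, "N"): {"G": 2.0},
            },
            bg,
        )
        assert binding_matrix(protein, code).columns[0]["C"] == 2.0

    def test_l_position6_overrules_position1p(self, bg):
        # aa6='P' is in the overruling set: the 1' marginal must not fire
        protein = build_protein(["L", "L2", "S2"],
                                [("P", "N"), ("T", "N"), ("A", "D")])
        code = code_table_from_columns(
            {CodeKey("L", "pos1p", None, "N"): {"G": 3.0}}, bg
        )
        bm = binding_matrix(protein, code)
        assert bm.columns[0] == {n: 1.0 for n in NUCLEOTIDES}
        # with a non-overruling aa6 the stratified marginal is consulted
        protein2 = build_protein(["L", "L2", "S2"],
                                 [("N", "N"), ("T", "N"), ("A", "D")])
        code2 = code_table_from_columns(
            {
                CodeKey("L", "pos1p_ex", None, "N"): {"G": 3.0},
                CodeKey("L", "pos1p", None, "N"): {"U": 3.0},
            },
            bg,
        )
        assert binding_matrix(protein2, code2).columns[0]["G"] == 3.0

    def test_trained_column_surfaces_at_aligned_position(self, bg):
        # 14 scoring motifs: positions -17..-4; the P repeat third from the
        # N-terminus faces nucleotide -15
        classes = ["L", "S", "P", "L", "S", "P", "L", "S", "P", "L", "S",
                   "P", "L2", "S2"]
        pairs = [("V", "V")] * 14
        pairs[2] = ("T", "N")
        protein = build_protein(classes, pairs, protein_id="mef11-shaped")
        code = code_table_from_columns(
            {CodeKey("P", "combo", "T", "N"): MEF11_COLUMN}, bg
        )
        bm = binding_matrix(protein, code)
        idx = bm.positions.index(-15)
        assert bm.columns[idx] == MEF11_COLUMN

    def test_class_restriction_neutralizes_without_moving_positions(self, bg):
        protein = build_protein(["P", "L", "L2", "S2"],
                                [("T", "N"), ("N", "N"), ("T", "N"), ("A", "D")])
        code = code_table_from_columns(
            {
                CodeKey("P", "combo", "T", "N"): {"A": 2.0},
                CodeKey("L", "combo", "N", "N"): {"G": 2.0},
            },
            bg,
        )
        bm = binding_matrix(protein, code, mode=P_AND_S_ONLY)
        assert bm.positions == (-7, -6, -5, -4)
        assert bm.columns[0]["A"] == 2.0  # P still scores
        assert bm.columns[1] == {n: 1.0 for n in NUCLEOTIDES}  # L neutral

    def test_drop_mode_contracts_the_span(self, bg):
        protein = build_protein(["P", "L", "L2", "S2"],
                                [("T", "N"), ("N", "N"), ("T", "N"), ("A", "D")])
        code = code_table_from_columns({}, bg)
        mode = ScanMode(include_classes=frozenset({"P", "S"}), excluded="drop")
        bm = binding_matrix(protein, code, mode=mode)
        assert bm.positions == (-4,)

    def test_cterm_truncation_keeps_c_terminal_repeats(self, bg):
        classes = ["P", "L", "S", "P", "L", "S", "P", "L", "L2", "S2"]
        protein = build_protein(classes, [("T", "N")] * 10)
        code = code_table_from_columns({}, bg)
        bm = binding_matrix(protein, code, mode=ScanMode(cterm_k=8))
        assert bm.positions == tuple(range(-11, -3))


class TestProbabilityMatrix:
    def test_worked_pseudocount_example(self, bg):
        protein = build_protein(["S2"], [("A", "D")])
        code = code_table_from_columns(
            {CodeKey("S2", "combo", "A", "D"): MEF11_COLUMN}, bg
        )
        pm = to_probability_matrix(binding_matrix(protein, code), pseudocount=0.01)
        assert pm.columns[0]["U"] == pytest.approx(0.01 / 1.47, abs=1e-9)

    def test_neutral_and_zero_columns_become_uniform(self, bg):
        protein = build_protein(["L2", "S2"], [("T", "N"), ("A", "D")])
        code = code_table_from_columns(
            {CodeKey("S2", "combo", "A", "D"): {}}, bg  # all-zero entry
        )
        pm = to_probability_matrix(binding_matrix(protein, code))
        for col in pm.columns:
            assert all(v == pytest.approx(0.25) for v in col.values())

    @given(
        an=st.lists(
            st.tuples(*[st.floats(0, 50) for _ in range(4)]),
            min_size=1,
            max_size=8,
        ),
        pseudocount=st.floats(1e-4, 1.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_columns_always_sum_to_one(self, an, pseudocount):
        from pprcode.scanning import BindingMatrix

        bm = BindingMatrix(
            protein_id="h",
            positions=tuple(range(-len(an) - 3, -3)),
            columns=tuple(dict(zip(NUCLEOTIDES, row)) for row in an),
        )
        pm = to_probability_matrix(bm, pseudocount=pseudocount)
        for col in pm.columns:
            assert sum(col.values()) == pytest.approx(1.0, abs=1e-9)

    def test_negative_binding_value_rejected(self, bg):
        from pprcode.scanning import BindingMatrix

        bm = BindingMatrix(
            protein_id="x",
            positions=(-4,),
            columns=({"A": -0.1, "C": 1.0, "G": 1.0, "U": 1.0},),
        )
        with pytest.raises(ValueError, match="negative"):
            to_probability_matrix(bm)


class TestLogOdds:
    def _pm(self, columns, bg):
        from pprcode.scanning import ProbabilityMatrix

        return ProbabilityMatrix(
            protein_id="x",
            positions=tuple(range(-3 - len(columns), -3)),
            columns=tuple(columns),
            pseudocount=0.01,
        )

    def test_background_probabilities_score_zero(self, bg):
        pm = self._pm([dict(bg.probs)], bg)
        assert np.allclose(log_odds(pm, bg).scores, 0.0)

    def test_uniform_column_hand_value(self, bg):
        pm = self._pm([{n: 0.25 for n in NUCLEOTIDES}], bg)
        sm = log_odds(pm, bg)
        assert sm.scores[0, 3] == pytest.approx(
            math.log2(0.25 / (13724 / 42026)), abs=1e-9
        )

    def test_enriched_g_hand_value(self, bg):
        col = {"A": 0.1, "C": 0.05, "G": 0.8, "U": 0.05}
        sm = log_odds(self._pm([col], bg), bg)
        assert sm.scores[0, 2] == pytest.approx(
            math.log2(0.8 / (8633 / 42026)), abs=1e-9
        )


def _enumeration_pvalues(bins, bgv):
    """Brute-force tail probabilities over all 4^L sequences."""
    totals = np.zeros(1, dtype=np.int64)
    probs = np.ones(1)
    for row in bins:
        totals = (totals[:, None] + row[None, :]).ravel()
        probs = (probs[:, None] * bgv[None, :]).ravel()
    return totals, probs


class TestExactPvalues:
    def test_single_winner_column_has_quarter_tail(self):
        from pprcode.training import Background

        uniform = Background(probs={n: 0.25 for n in NUCLEOTIDES})
        sm = ScoreMatrix("x", (-4,), np.array([[2.0, -1.0, -1.0, -1.0]]))
        dist = exact_pvalues(sm, uniform)
        assert dist.pvalue(2.0) == pytest.approx(0.25, abs=1e-12)

    def test_all_zero_matrix_is_degenerate(self, bg):
        sm = ScoreMatrix("x", (-5, -4), np.zeros((2, 4)))
        dist = exact_pvalues(sm, bg)
        assert dist.pvalue(0.0) == pytest.approx(1.0)

    def test_non_positive_step_rejected(self, bg):
        sm = ScoreMatrix("x", (-4,), np.zeros((1, 4)))
        with pytest.raises(ValueError, match="step"):
            exact_pvalues(sm, bg, step=0)

    def test_matches_exhaustive_enumeration(self, bg, rng):
        bgv = bg.as_array()
        for _ in range(10):
            L = int(rng.integers(1, 5))
            sm = ScoreMatrix(
                "x", tuple(range(-3 - L, -3)), rng.normal(0, 2, (L, 4))
            )
            dist = exact_pvalues(sm, bg, step=1e-3)
            totals, probs = _enumeration_pvalues(dist.column_bins, bgv)
            for t in np.unique(totals):
                assert dist.pvalue_of_bin(int(t)) == pytest.approx(
                    probs[totals >= t].sum(), abs=1e-9
                )

    def test_survival_is_monotone_non_increasing(self, bg, rng):
        sm = ScoreMatrix(
            "x", tuple(range(-9, -3)), rng.normal(0, 1.5, (6, 4))
        )
        dist = exact_pvalues(sm, bg)
        assert np.all(np.diff(dist.survival) <= 1e-15)
        assert dist.survival[0] == pytest.approx(1.0, abs=1e-9)


def _window(site_id, seq):
    return SiteWindow(site_id, "t", len(seq) + 1, seq)


class TestScanAndRank:
    def _simple_pm(self, bg):
        protein = build_protein(["L2", "S2"], [("T", "N"), ("A", "D")])
        code = code_table_from_columns(
            {
                CodeKey("S2", "combo", "A", "D"): {"G": 4.0},
                CodeKey("L2", "combo", "T", "N"): {"A": 4.0},
            },
            bg,
        )
        return to_probability_matrix(binding_matrix(protein, code))

    def test_identical_windows_tie_broken_by_site_id(self, bg):
        pm = self._simple_pm(bg)
        seq = "U" * 25 + "AG" + "UUU"
        preds = scan_and_rank(pm, [_window("b", seq), _window("a", seq)], bg)
        assert [p.site_id for p in preds] == ["a", "b"]
        assert preds[0].p_value == preds[1].p_value
        assert [p.rank for p in preds] == [1, 2]

    def test_matching_window_outranks_background_windows(self, bg, rng):
        pm = self._simple_pm(bg)
        decoys = [
            _window(f"d{i}", "".join(rng.choice(list("ACGU"), 30)))
            for i in range(50)
        ]
        target = _window("hit", "U" * 25 + "AG" + "UUU")
        preds = scan_and_rank(pm, decoys + [target], bg)
        # the planted window attains the best achievable score; random
        # decoys can tie it but never beat it
        hit = next(p for p in preds if p.site_id == "hit")
        assert hit.p_value == preds[0].p_value
        assert hit.score_bits == pytest.approx(preds[0].score_bits, abs=1e-12)

    def test_n_bases_score_background_expectation(self, bg):
        pm = self._simple_pm(bg)
        all_n = _window("nn", "N" * 30)
        preds = scan_and_rank(pm, [all_n], bg)
        dist = exact_pvalues(log_odds(pm, bg), bg)
        expected = float(dist.expected_bins.sum()) * dist.step
        assert preds[0].score_bits == pytest.approx(expected, abs=1e-9)

    def test_window_shorter_than_span_rejected(self, bg):
        pm = self._simple_pm(bg)
        with pytest.raises(AlignmentError, match="shorter"):
            scan_and_rank(pm, [SiteWindow("s", "t", 5, "ACG")], bg)

    def test_ranks_are_a_permutation(self, bg, rng):
        pm = self._simple_pm(bg)
        windows = [
            _window(f"w{i}", "".join(rng.choice(list("ACGU"), 30)))
            for i in range(20)
        ]
        preds = scan_and_rank(pm, windows, bg)
        assert sorted(p.rank for p in preds) == list(range(1, 21))

    def test_mode_consistency_without_l_entries(self, bg):
        # if the code carries no L/L2/S2 entries, P+S-only scanning equals
        # all-motif scanning
        protein = build_protein(
            ["P", "L", "S", "L2", "S2"],
            [("T", "N"), ("N", "N"), ("N", "D"), ("T", "N"), ("A", "D")],
        )
        code = code_table_from_columns(
            {
                CodeKey("P", "combo", "T", "N"): {"A": 3.0},
                CodeKey("S", "combo", "N", "D"): {"U": 3.0},
            },
            bg,
        )
        windows = [
            _window(f"w{i}", seq)
            for i, seq in enumerate(
                ["".join(c) * 30 for c in "ACGU"]
                + ["U" * 21 + "A" + "GGG" + "U" + "CCCC"]
            )
        ]
        preds_all = scan_and_rank(
            to_probability_matrix(binding_matrix(protein, code, ALL_MOTIFS)),
            windows, bg,
        )
        preds_ps = scan_and_rank(
            to_probability_matrix(binding_matrix(protein, code, P_AND_S_ONLY)),
            windows, bg,
        )
        assert [(p.site_id, p.rank, p.p_value) for p in preds_all] == [
            (p.site_id, p.rank, p.p_value) for p in preds_ps
        ]

    def test_repeat_scan_is_deterministic(self, bg, rng):
        pm = self._simple_pm(bg)
        windows = [
            _window(f"w{i}", "".join(rng.choice(list("ACGU"), 30)))
            for i in range(25)
        ]
        first = scan_and_rank(pm, windows, bg)
        second = scan_and_rank(pm, list(windows), bg)
        assert first == second


class TestScanTranscriptome:
    def test_transcript_without_c_yields_empty(self, bg):
        protein = build_protein(["L2", "S2"], [("T", "N"), ("A", "D")])
        code = code_table_from_columns({}, bg)
        pm = to_probability_matrix(binding_matrix(protein, code))
        assert scan_transcriptome(pm, {"tx": "AUGAUGAUG"}, bg) == []

    def test_embedded_target_ranks_first(self, bg):
        code = make_code(seed=9, n_entries_per_class=4, kappa=0.1,
                         fraction_neutral=0.0)
        factor = sample_factor(code, 12, seed=9)
        target = sample_target(factor, code, 0.0, seed=9)
        bgv = code.background.as_array()
        seq = "".join(
            np.random.default_rng(10).choice(list("ACGU"), p=bgv, size=6000)
        )
        pos = 4000
        seq = seq[: pos - 31] + target.upstream + "C" + seq[pos:]
        pm = to_probability_matrix(binding_matrix(factor, code.exact_code_table()))
        preds = scan_transcriptome(pm, {"tx": seq}, bg)
        assert seq.count("C") >= 1000
        assert preds[0].site_id == f"tx-{pos}"


class TestMemeExport:
    def test_minimal_motif_format_fields(self, bg):
        protein = build_protein(["L2", "S2"], [("T", "N"), ("A", "D")])
        code = code_table_from_columns(
            {CodeKey("S2", "combo", "A", "D"): MEF11_COLUMN}, bg
        )
        pm = to_probability_matrix(binding_matrix(protein, code))
        text = to_meme(pm, bg)
        lines = text.splitlines()
        assert lines[0].startswith("MEME version")
        assert "ALPHABET= ACGU" in text
        header = next(l for l in lines if l.startswith("letter-probability"))
        assert "w= 2" in header
        matrix_rows = [
            l for l in lines if l.startswith(" ") and len(l.split()) == 4
        ]
        assert len(matrix_rows) == 2
        for row in matrix_rows:
            assert sum(float(x) for x in row.split()) == pytest.approx(1.0, abs=1e-5)


class TestRankerEstimator:
    def test_fit_predict_round_trip(self, bg):
        code = make_code(seed=4, n_entries_per_class=3, fraction_neutral=0.0)
        factor = sample_factor(code, 10, seed=4)
        target = sample_target(factor, code, 0.0, seed=4, site_id="truth")
        rng = np.random.default_rng(8)
        decoys = [
            _window(f"d{i}", "".join(rng.choice(list("ACGU"), 30)))
            for i in range(40)
        ]
        ranker = PPRTargetRanker(code=code.exact_code_table()).fit(factor)
        preds = ranker.predict(decoys + [target])
        assert preds[0].site_id == "truth"
        scores = ranker.score_samples([target])
        assert scores[0] == pytest.approx(preds[0].score_bits, abs=1e-9)

    def test_sklearn_params_round_trip(self):
        ranker = PPRTargetRanker(pseudocount=0.05, step=1e-2)
        params = ranker.get_params()
        assert params["pseudocount"] == 0.05
        ranker.set_params(step=1e-3)
        assert ranker.step == 1e-3
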