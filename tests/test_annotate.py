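"""PTS1 classification, internal-motif and PTS2 scanning, whole-protein annotation.

Brute-force oracles here are written from the published rules directly
(literal residue sets, nested loops) and stay independent of the package's
code paths.
"""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptscan.annotate import (
    CANONICAL,
    CAT_INTERNAL,
    CAT_NONE,
    CAT_PTS1_CANONICAL,
    CAT_PTS1_NONCANONICAL,
    CAT_PTS2,
    NON_CANONICAL,
    NO_OBVIOUS_I,
    NO_OBVIOUS_II,
    NO_OBVIOUS_III,
    AnnotatorOptions,
    annotate_protein,
    annotate_proteome,
    classify_pts1,
    extract_tripeptide,
    match_pts2_site,
    scan_internal_pts1,
    scan_pts2,
)
from ptscan.errors import InputError
from ptscan.signal_tables import STANDARD_AA

AA = sorted(STANDARD_AA)

# Independent oracle: literal residue-class sets and a direct restatement of
# the five-way labelling rule.
ORACLE_HIGH = {-3: set("SA"), -2: set("KR"), -1: set("LMI")}
ORACLE_LOW = {-3: set("PTQIV"), -2: set("NSTYHMLQFA"), -1: set("FVY")}


def oracle_label(tri: str) -> str:
    classes = []
    for pos, res in zip((-3, -2, -1), tri):
        if res in ORACLE_HIGH[pos]:
            classes.append("high")
        elif res in ORACLE_LOW[pos]:
            classes.append("low")
        else:
            classes.append("unproven")
    n_low, n_unp = classes.count("low"), classes.count("unproven")
    if n_unp >= 2:
        return NO_OBVIOUS_III
    if n_unp == 1:
        return NO_OBVIOUS_II
    if n_low >= 2:
        return NO_OBVIOUS_I
    if n_low == 1:
        return NON_CANONICAL
    return CANONICAL


class TestExtractTripeptide:
    def test_suffix(self):
        assert extract_tripeptide("MDDSAPSKL") == "SKL"

    def test_trailing_stop_stripped(self):
        assert extract_tripeptide("MDDSAPSKL*") == "SKL"

    def test_internal_motif_is_not_the_terminus(self):
        seq = "M" * 30 + "QKL" + "ACDEFGHIKL"  # catalase-like: QKL then 10 residues
        assert extract_tripeptide(seq) != "QKL"

    def test_too_short(self):
        with pytest.raises(InputError):
            extract_tripeptide("ML")


class TestClassifyPts1:
    @pytest.mark.parametrize(
        "tri, label",
        [
            ("SKL", CANONICAL),
            ("SNL", NON_CANONICAL),
            ("PML", NO_OBVIOUS_I),
            ("SAK", NO_OBVIOUS_II),
            ("VVA", NO_OBVIOUS_III),
        ],
    )
    def test_worked_examples(self, tri, label, tables):
        assert classify_pts1(tri, tables).label == label

    def test_non_canonical_reports_low_position(self, tables):
        call = classify_pts1("SNL", tables)
        assert call.low_position == frozenset({-2})

    def test_all_8000_tripeptides_match_oracle(self, tables):
        for a, b, c in itertools.product(AA, AA, AA):
            tri = a + b + c
            assert classify_pts1(tri, tables).label == oracle_label(tri), tri

    def test_canonical_count_is_consensus_product(self, tables):
        # |{S,A}| * |{K,R}| * |{L,M,I}| = 12 canonical tripeptides
        n = sum(
            classify_pts1(a + b + c, tables).label == CANONICAL
            for a, b, c in itertools.product(AA, AA, AA)
        )
        assert n == len(tables.high[-3]) * len(tables.high[-2]) * len(tables.high[-1]) == 12

    @given(st.sampled_from([a + b + c for a, b, c in itertools.product("SA", "KR", "LMI")]),
           st.integers(0, 2),
           st.data())
    @settings(deadline=None, max_examples=60)
    def test_low_substitution_breaks_canonical(self, tables, tri, idx, data):
        pos = (-3, -2, -1)[idx]
        low = sorted(ORACLE_LOW[pos])
        res = data.draw(st.sampled_from(low))
        mutated = tri[:idx] + res + tri[idx + 1 :]
        assert classify_pts1(mutated, tables).label != CANONICAL

    @given(st.text(alphabet=AA, min_size=3, max_size=3), st.integers(0, 2), st.data())
    @settings(deadline=None, max_examples=60)
    def test_unproven_substitution_gives_category_ii_or_iii(self, tables, tri, idx, data):
        pos = (-3, -2, -1)[idx]
        unproven = sorted(set(AA) - ORACLE_HIGH[pos] - ORACLE_LOW[pos])
        res = data.draw(st.sampled_from(unproven))
        mutated = tri[:idx] + res + tri[idx + 1 :]
        assert classify_pts1(mutated, tables).label in (NO_OBVIOUS_II, NO_OBVIOUS_III)

    def test_wrong_length_rejected(self, tables):
        with pytest.raises(InputError):
            classify_pts1("SK", tables)


class TestInternalScan:
    def test_catalase_convention(self, tables):
        # Q is a low-abundance residue at -3 (cf. QKF), so QKL scores non-canonical
        seq = "M" * 40 + "QKL" + "ACDEFGHIKW"  # exactly 10 residues after QKL
        hits = scan_internal_pts1(seq, tables)
        assert [(h.tripeptide, h.end_offset, h.label) for h in hits] == [
            ("QKL", 10, NON_CANONICAL)
        ]

    def test_terminal_tripeptide_excluded(self, tables):
        seq = "W" * 60 + "SKL"
        assert scan_internal_pts1(seq, tables) == []

    def test_short_sequence_gives_empty_list(self, tables):
        assert scan_internal_pts1("SKL", tables) == []

    def test_matches_sliding_window_oracle_on_random_sequences(self, tables):
        rng = random.Random(7)
        for _ in range(25):
            seq = "".join(rng.choice(AA) for _ in range(200))
            hits = scan_internal_pts1(seq, tables, min_offset=1, max_offset=50)
            expected = []
            for start in range(len(seq) - 3):  # brute force over all windows
                end_offset = len(seq) - (start + 3)
                if 1 <= end_offset <= 50 and oracle_label(seq[start : start + 3]) in (
                    CANONICAL,
                    NON_CANONICAL,
                ):
                    expected.append((seq[start : start + 3], end_offset))
            assert [(h.tripeptide, h.end_offset) for h in hits] == sorted(
                expected, key=lambda te: te[1]
            )

    def test_inclusive_convention_shifts_offsets(self, tables):
        seq = "W" * 40 + "QKL" + "ACDEFGHIKW"
        hits = scan_internal_pts1(seq, tables, offset_convention="inclusive")
        assert [(h.tripeptide, h.end_offset) for h in hits] == [("QKL", 11)]

    def test_bad_offsets_rejected(self, tables):
        with pytest.raises(InputError):
            scan_internal_pts1("A" * 50, tables, min_offset=0)
        with pytest.raises(InputError):
            scan_internal_pts1("A" * 50, tables, min_offset=5, max_offset=4)


class TestPts2Matcher:
    def test_strict_conforming_nonapeptide(self, strict_spec):
        m = match_pts2_site("RLAALLSHL", strict_spec)
        assert m.matched and m.deviations == ()

    def test_relaxed_reports_single_deviation(self, relaxed_spec, strict_spec):
        m = match_pts2_site("RTAALLSHL", relaxed_spec)
        assert m.matched and m.deviations == ((2, "T"),)
        assert not match_pts2_site("RTAALLSHL", strict_spec).matched

    def test_anchor_failure_rejects_both_modes(self, relaxed_spec, strict_spec):
        for spec in (relaxed_spec, strict_spec):
            assert not match_pts2_site("GLAALLSHL", spec).matched

    def test_wrong_length_rejected(self, relaxed_spec):
        with pytest.raises(InputError):
            match_pts2_site("RLAALLSH", relaxed_spec)

    @given(st.text(alphabet=AA, min_size=300, max_size=300))
    @settings(deadline=None, max_examples=30)
    def test_strict_matches_subset_of_relaxed(self, strict_spec, relaxed_spec, seq):
        strict = {m.start for m in scan_pts2(seq, strict_spec, window=300)}
        relaxed = {m.start for m in scan_pts2(seq, relaxed_spec, window=300)}
        assert strict <= relaxed


class TestScanPts2:
    BACKGROUND = "W" * 200  # W is outside every anchor set at every frame

    def _with_site(self, start, background=None):
        seq = background or self.BACKGROUND
        return seq[: start - 1] + "RLAALLSHL" + seq[start + 8 :]

    def test_site_within_window(self, relaxed_spec):
        matches = scan_pts2(self._with_site(5), relaxed_spec, window=40)
        assert [(m.start, m.internal) for m in matches] == [(5, False)]

    def test_internal_site_needs_flag(self, relaxed_spec):
        seq = self._with_site(120)
        assert scan_pts2(seq, relaxed_spec, window=40) == []
        matches = scan_pts2(seq, relaxed_spec, window=40, allow_internal=True)
        assert [(m.start, m.internal) for m in matches] == [(120, True)]

    def test_background_is_signal_free(self, relaxed_spec):
        assert scan_pts2(self.BACKGROUND, relaxed_spec, window=200) == []


class TestAnnotateProtein:
    BACKGROUND = "W" * 120

    def test_pts2_category(self):
        seq = "M" + "RQAALLSHL" + self.BACKGROUND
        a = annotate_protein(seq)
        assert a.summary_category == CAT_PTS2

    def test_no_obvious_terminal_gives_none(self):
        a = annotate_protein(self.BACKGROUND + "TNL")
        assert a.summary_category == CAT_NONE
        assert a.terminal.label == NO_OBVIOUS_I

    def test_internal_pts_category(self):
        a = annotate_protein(self.BACKGROUND + "QKL" + "W" * 10)
        assert a.summary_category == CAT_INTERNAL
        assert a.internal_hits[0].token() == "QKL-10"

    def test_terminal_categories(self):
        assert annotate_protein(self.BACKGROUND + "SKL").summary_category == CAT_PTS1_CANONICAL
        assert annotate_protein(self.BACKGROUND + "SNL").summary_category == CAT_PTS1_NONCANONICAL

    def test_dual_signal_keeps_all_evidence_pts2_wins(self):
        seq = "M" + "RQAALLSHL" + self.BACKGROUND + "SKL"
        a = annotate_protein(seq)
        assert a.summary_category == CAT_PTS2
        assert a.dual_signal
        assert a.terminal.label == CANONICAL
        assert len(a.pts2_matches) == 1


class TestAnnotateProteome:
    def test_empty_input(self):
        assert annotate_proteome([]) == []

    def test_three_record_fixture(self):
        records = [
            ("p1", "M" + "RQAALLSHL" + "W" * 100),
            ("p2", "W" * 100 + "SKL"),
            ("p3", "W" * 100),
        ]
        cats = [a.summary_category for a in annotate_proteome(records)]
        assert cats == [CAT_PTS2, CAT_PTS1_CANONICAL, CAT_NONE]

    def test_order_preserved_and_deterministic(self):
        records = [(f"p{i}", "W" * 50 + "SKL") for i in range(5)]
        first = annotate_proteome(records)
        second = annotate_proteome(records)
        assert [a.protein_id for a in first] == [r[0] for r in records]
        assert first == second

    def test_duplicate_id_rejected_by_name(self):
        records = [("dup", "W" * 50 + "SKL"), ("dup", "W" * 50 + "SNL")]
        with pytest.raises(InputError, match="dup"):
            annotate_proteome(records)


def test_annotator_equals_naive_enumeration_on_random_proteins(tables, relaxed_spec):
    """Oracle equivalence: full annotation vs direct brute-force scans."""
    rng = random.Random(11)
    options = AnnotatorOptions()
    for _ in range(60):
        seq = "".join(rng.choice(AA) for _ in range(rng.randint(50, 300)))
        a = annotate_protein(seq, tables, relaxed_spec, options)
        # brute-force PTS2: anchors 1, 8, 9 within window 40
        pts2_starts = [
            s
            for s in range(1, min(40, len(seq) - 8) + 1)
            if seq[s - 1] in "RK" and seq[s + 6] in "HQ" and seq[s + 7] in "LAF"
        ]
        assert [m.start for m in a.pts2_matches] == pts2_starts
        # brute-force internal PTS1
        internal = [
            (seq[i : i + 3], len(seq) - i - 3)
            for i in range(len(seq) - 3)
            if 1 <= len(seq) - i - 3 <= 50
            and oracle_label(seq[i : i + 3]) in (CANONICAL, NON_CANONICAL)
        ]
        assert [(h.tripeptide, h.end_offset) for h in a.internal_hits] == sorted(
            internal, key=lambda te: te[1]
        )
        assert a.terminal.label == oracle_label(seq[-3:])
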