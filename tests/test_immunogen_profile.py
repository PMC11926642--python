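import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoprofile.immunogen_profile import (
    ImmunogenWindow,
    build_profile,
    classify_disorder,
    classify_position,
    functional_overlap,
    locate_immunogen,
    majority_ss,
)
from immunoprofile.io_formats import ProteinAnnotations
from immunoprofile.structure_features import ss_segments


class TestLocate:
    def test_simple_substring(self):
        w = locate_immunogen("P", "MKLVNNAG", "LVN")
        assert (w.start, w.end) == (3, 5)

    def test_full_protein(self):
        w = locate_immunogen("P", "MKLVNNAG", "MKLVNNAG")
        assert (w.start, w.end) == (1, 8)

    def test_overlapping_repeat_warns_and_returns_first(self):
        with pytest.warns(UserWarning, match="more than once"):
            w = locate_immunogen("P", "AAAA", "AAA")
        assert (w.start, w.end) == (1, 3)

    def test_strict_mode_raises_on_repeat(self):
        with pytest.raises(ValueError, match="more than once"):
            locate_immunogen("P", "AAAA", "AAA", strict=True)

    def test_missing_immunogen_is_error(self):
        with pytest.raises(ValueError, match="not found"):
            locate_immunogen("P", "MKLV", "WWW")


class TestPosition:
    @pytest.mark.parametrize("start,end,length,expected", [
        (10, 40, 500, "terminus"),    # partly within first 25
        (26, 60, 500, "center"),
        (480, 500, 500, "terminus"),  # last-25 span is 476..500
        (476, 490, 500, "terminus"),
        (26, 475, 500, "center"),     # both boundaries just inside center
        (25, 30, 500, "terminus"),
    ])
    def test_rule(self, start, end, length, expected):
        assert classify_position(start, end, length) == expected

    def test_window_beyond_protein_is_error(self):
        with pytest.raises(ValueError):
            classify_position(10, 40, 30)

    @given(st.integers(60, 500), st.data())
    @settings(max_examples=100, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, length, data):
        start = data.draw(st.integers(1, length))
        end = data.draw(st.integers(start, length))
        cls = classify_position(start, end, length)
        assert cls in ("terminus", "center")
        overlaps_edge = start <= 25 or end >= length - 24
        assert (cls == "terminus") == overlaps_edge


class TestDisorder:
    def test_all_high(self):
        assert classify_disorder([0.9, 0.95, 0.8]) == "high"

    def test_all_low(self):
        assert classify_disorder([0.1, 0.0, 0.2]) == "low"

    def test_mixed_is_medium(self):
        assert classify_disorder([0.1, 0.9]) == "medium"

    def test_missing_scores_are_unavailable(self):
        assert classify_disorder([0.5, np.nan]) == "unavailable"
        assert classify_disorder([]) == "unavailable"

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            classify_disorder([0.5, 1.4])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, scores):
        cls = classify_disorder(scores)
        assert cls in ("high", "low", "medium")
        assert (cls == "high") == (min(scores) >= 0.8)
        assert (cls == "low") == (max(scores) <= 0.2)


class TestMajoritySS:
    def test_plurality(self):
        labels = ["coil"] * 20 + ["helix"] * 5
        assert majority_ss(labels) == "coil"
        labels = ["sheet"] * 15 + ["coil"] * 10 + ["helix"] * 5
        assert majority_ss(labels) == "sheet"

    def test_tie_breaks_coil_then_helix_then_sheet(self):
        assert majority_ss(["coil"] * 10 + ["helix"] * 10) == "coil"
        assert majority_ss(["helix"] * 7 + ["sheet"] * 7) == "helix"

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError):
            majority_ss([])


def annotations(length=500, tm=(), ss=(), ptm=()):
    seq = list("A" * length)
    for i, j in ss:
        seq[i - 1] = seq[j - 1] = "C"
    return ProteinAnnotations("P", "".join(seq), tm_ranges=list(tm),
                              disulfide_pairs=list(ss),
                              ptm_sites={k: "modified_residue" for k in ptm})


class TestFunctionalOverlap:
    def test_tm_overlap(self):
        ann = annotations(tm=[(30, 55)])
        assert functional_overlap(10, 40, ann)[0] == "overlap"

    def test_tm_vicinity(self):
        ann = annotations(tm=[(200, 220)])
        assert functional_overlap(10, 40, ann)[0] == "vicinity"

    def test_no_tm_with_ptm(self):
        ann = annotations(ptm=[12])
        tm_class, has_ss, has_ptm = functional_overlap(10, 40, ann)
        assert (tm_class, has_ss, has_ptm) == ("no_tm", False, True)

    def test_half_cystine_in_window_sets_flag(self):
        ann = annotations(ss=[(5, 400)])
        assert functional_overlap(1, 10, ann)[1] is True
        assert functional_overlap(390, 410, ann)[1] is True
        assert functional_overlap(50, 80, ann)[1] is False

    def test_overlap_is_monotone_under_window_extension(self):
        ann = annotations(tm=[(100, 120)])
        classes = [functional_overlap(s, 130, ann)[0] for s in (125, 110, 50, 1)]
        # once a growing window overlaps, it stays overlapping
        first_overlap = classes.index("overlap")
        assert all(c == "overlap" for c in classes[first_overlap:])


class TestBuildProfile:
    def test_aggregate_arithmetic(self):
        ann = annotations(length=5)
        window = ImmunogenWindow("P", 1, 5, "AAAAA")
        profile = build_profile(
            window, ["coil"] * 5, [True, False, False, True, False],
            [3, 4, 5, 4, 4], [0.5] * 5, ann)
        assert profile.n_buried == 2
        assert profile.mean_contacts == 4.0
        assert profile.n_ss_segments == 1

    def test_composition_of_rules(self):
        ann = annotations(length=200)
        window = ImmunogenWindow("P", 1, 30, "A" * 30)
        profile = build_profile(window, ["coil"] * 200, [False] * 200,
                                [2] * 200, [0.95] * 200, ann)
        assert (profile.position_class, profile.disorder_class,
                profile.majority_ss) == ("terminus", "high", "coil")

    def test_track_length_mismatch_is_error(self):
        ann = annotations(length=100)
        window = ImmunogenWindow("P", 1, 10, "A" * 10)
        with pytest.raises(ValueError, match="track"):
            build_profile(window, ["coil"] * 99, [False] * 100, [0] * 100,
                          None, ann)

    def test_matches_field_by_field_recomputation(self):
        rng = np.random.default_rng(5)
        length = 300
        ss3 = [("coil", "helix", "sheet")[i] for i in rng.integers(0, 3, length)]
        buried = rng.random(length) < 0.3
        contacts = rng.integers(0, 12, length)
        disorder = rng.random(length)
        ann = annotations(length=length, tm=[(120, 140)], ptm=[33, 150])
        for _ in range(25):
            start = int(rng.integers(1, length - 20))
            end = int(start + rng.integers(5, 20))
            window = ImmunogenWindow("P", start, end, "A" * (end - start + 1))
            p = build_profile(window, ss3, buried, contacts, disorder, ann)
            sl = slice(start - 1, end)
            # independent aggregation, field by field
            assert p.n_buried == sum(bool(b) for b in buried[sl])
            assert p.mean_contacts == pytest.approx(
                sum(contacts[sl]) / (end - start + 1))
            counts = {c: ss3[sl].count(c) for c in ("coil", "helix", "sheet")}
            best = max(counts.values())
            winners = [c for c in ("coil", "helix", "sheet") if counts[c] == best]
            assert p.majority_ss == winners[0]
            assert p.n_ss_segments == ss_segments(ss3, (start, end))
            assert p.disorder_class == classify_disorder(disorder[sl])

    def test_order_independent_in_annotation_rows(self):
        ann_fwd = annotations(length=100, tm=[(10, 20), (60, 70)], ptm=[5, 90])
        ann_rev = annotations(length=100, tm=[(60, 70), (10, 20)], ptm=[90, 5])
        window = ImmunogenWindow("P", 5, 40, "A" * 36)
        args = (["coil"] * 100, [False] * 100, [1] * 100, [0.5] * 100)
        assert build_profile(window, *args, ann_fwd) == \
            build_profile(window, *args, ann_rev)
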