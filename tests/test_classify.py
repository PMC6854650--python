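"""Match-rate scoring, T/M gating, point accumulation, and sample classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metafingerprint.classify import (
    SKIPPED,
    UNASSIGNED,
    ClassifierParams,
    EmptySampleError,
    MatchProfile,
    accumulate_points,
    classify_sample,
    match_rate_score,
    matched_classes,
    score_read,
)
from metafingerprint.kmer_db import KmerSet
from metafingerprint.read_prep import QuerySample
from .conftest import oracle_match_rate

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def _db(k, members):
    return KmerSet.from_strings(k, members)


class TestMatchRateScore:
    def test_no_hit_is_zero(self):
        assert match_rate_score("ACGTACGT", _db(4, {"TTTT"})) == 0.0

    def test_full_coverage_is_100(self):
        # every window of AAAAAA is AAAA
        assert match_rate_score("AAAAAA", _db(4, {"AAAA"})) == 100.0

    def test_partial_coverage(self):
        # 10-nt read, k=4: windows at 0 and 4 match -> positions 0..7 covered
        read = "AACCTTGGCA"
        db = _db(4, {read[0:4], read[4:8]})
        assert match_rate_score(read, db) == pytest.approx(80.0)

    def test_separator_excluded_from_denominator(self):
        # fused pair: both halves fully covered -> 100% despite the 'N'
        db = _db(4, {"AAAA", "CCCC"})
        assert match_rate_score("AAAANGGGG", db) == pytest.approx(100.0)
        assert match_rate_score("AAAANGGGG", db, include_ns=True) == pytest.approx(
            100.0 * 8 / 9
        )

    def test_short_read_scores_zero(self):
        assert match_rate_score("ACG", _db(4, {"ACGT"})) == 0.0

    @settings(max_examples=300, deadline=None)
    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=60),
        st.sets(st.text(alphabet="ACGT", min_size=4, max_size=4), max_size=50),
        st.sampled_from([4, 8, 24]),
    )
    def test_matches_coverage_oracle(self, read, members, k):
        members = {m * (k // 4) for m in members}  # scale members to length k
        db = KmerSet.from_strings(k, members)
        assert match_rate_score(read, db) == pytest.approx(
            oracle_match_rate(read, {min(m, _rc(m)) for m in members}, k)
        )

    @settings(max_examples=100, deadline=None)
    @given(dna, st.sets(st.text(alphabet="ACGT", min_size=4, max_size=4), max_size=10))
    def test_monotone_in_database(self, read, members):
        """Adding k-mers to the database never lowers the score."""
        small = KmerSet.from_strings(4, set(list(members)[: len(members) // 2]))
        big = KmerSet.from_strings(4, members | small.to_strings())
        assert match_rate_score(read, big) >= match_rate_score(read, small)


def _rc(s):
    return "".join({"A": "T", "C": "G", "G": "C", "T": "A"}[c] for c in reversed(s))


class TestScoreRead:
    def test_empty_db_component_zero(self):
        dbs = [_db(4, {"AAAA"}), _db(4, set()), _db(4, {"CCCC"})]
        prof = score_read("AAAACCCC", dbs)
        assert prof.scores[1] == 0.0

    def test_identical_dbs_identical_scores(self):
        dbs = [_db(4, {"AAAA"})] * 3
        prof = score_read("AAAATTTT", dbs)
        assert prof.scores[0] == prof.scores[1] == prof.scores[2]

    @settings(max_examples=100, deadline=None)
    @given(
        dna,
        st.lists(
            st.sets(st.text(alphabet="ACGT", min_size=5, max_size=5), max_size=20),
            min_size=1,
            max_size=3,
        ),
    )
    def test_components_match_per_class_oracle(self, read, member_sets):
        dbs = [KmerSet.from_strings(5, m) for m in member_sets]
        prof = score_read(read, dbs)
        for j, m in enumerate(member_sets):
            canon = {min(x, _rc(x)) for x in m}
            assert prof.scores[j] == pytest.approx(oracle_match_rate(read, canon, 5))


class TestGating:
    def test_promiscuous_read_skipped(self, worked_example_profiles):
        assert matched_classes(worked_example_profiles[0], 50, 3) is SKIPPED

    def test_specific_read_matched(self, worked_example_profiles):
        assert matched_classes(worked_example_profiles[1], 50, 3) == {1}

    def test_multi_class_match(self, worked_example_profiles):
        assert matched_classes(worked_example_profiles[2], 50, 3) == {1, 2, 5}

    def test_no_class_above_threshold_skipped(self):
        prof = MatchProfile(0, np.array([10.0, 20.0]))
        assert matched_classes(prof, 50, 2) is SKIPPED

    def test_threshold_is_inclusive(self):
        prof = MatchProfile(0, np.array([50.0, 49.999]))
        assert matched_classes(prof, 50, 2) == {0}

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(min_value=0, max_value=100), min_size=4, max_size=4),
            min_size=1,
            max_size=10,
        ),
        st.floats(min_value=0, max_value=100),
        st.integers(min_value=1, max_value=4),
    )
    def test_gating_monotonicity(self, rows, T, M):
        """Lowering M never increases simple-sum points; with M=N the same
        holds for raising T (when M < N a raised T can shrink A below M and
        un-skip a previously promiscuous read, so no claim is made there)."""
        profs = [MatchProfile(i, np.array(r)) for i, r in enumerate(rows)]
        base = accumulate_points(profs, ClassifierParams(T=T, M=M, scheme="simple"))
        if M > 1:
            down_m = accumulate_points(
                profs, ClassifierParams(T=T, M=M - 1, scheme="simple")
            )
            assert (down_m <= base + 1e-12).all()
        if T <= 90:
            n = len(rows[0])
            base_full = accumulate_points(profs, ClassifierParams(T=T, M=n, scheme="simple"))
            up_t = accumulate_points(profs, ClassifierParams(T=T + 10, M=n, scheme="simple"))
            assert (up_t <= base_full + 1e-12).all()

    def test_permissive_params_match_every_scoring_read(self):
        """With M=N and T=0, every read with >=1 nonzero score is matched to
        exactly its nonzero-score classes; all-zero reads are skipped."""
        assert matched_classes(MatchProfile(0, np.array([0.0, 5.0, 0.0])), 0.0, 3) == {1}
        assert matched_classes(MatchProfile(1, np.array([0.0, 0.0, 0.0])), 0.0, 3) is SKIPPED
        assert matched_classes(MatchProfile(2, np.array([1.0, 1.0, 1.0])), 0.0, 3) == {0, 1, 2}


class TestAccumulatePoints:
    def test_simple_sum(self, worked_example_profiles):
        pts = accumulate_points(
            worked_example_profiles, ClassifierParams(T=50, M=3, scheme="simple")
        )
        assert pts.tolist() == [0, 2, 1, 0, 0, 1]

    def test_fractional_sum(self, worked_example_profiles):
        pts = accumulate_points(
            worked_example_profiles, ClassifierParams(T=50, M=3, scheme="fractional")
        )
        assert pts == pytest.approx([0, 4 / 3, 1 / 3, 0, 0, 1 / 3])

    def test_weighted_sum(self, worked_example_profiles):
        pts = accumulate_points(
            worked_example_profiles, ClassifierParams(T=50, M=3, scheme="weighted")
        )
        assert np.round(pts, 2).tolist() == [0, 1.39, 0.39, 0, 0, 0.22]

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=8),
        st.floats(min_value=0.1, max_value=100),
    )
    def test_conservation_per_read(self, scores, T):
        """Fractional and weighted contributions of one matched read sum to 1."""
        prof = MatchProfile(0, np.array(scores))
        n = len(scores)
        A = matched_classes(prof, T, n)
        for scheme in ("fractional", "weighted"):
            pts = accumulate_points([prof], ClassifierParams(T=T, M=n, scheme=scheme))
            if A is SKIPPED:
                assert pts.sum() == 0.0
            else:
                assert pts.sum() == pytest.approx(1.0, abs=1e-9)


class TestClassifySample:
    def test_worked_example_similarities(self, worked_example_profiles):
        pts = accumulate_points(
            worked_example_profiles, ClassifierParams(T=50, M=3, scheme="weighted")
        )
        sims = 100.0 * pts / 3
        # full precision: class 2 clearly wins
        assert sims.argmax() == 1
        # the illustrative percentages (46.33, 13, 7.33) normalize the
        # 2-d.p.-rounded point values 1.39, 0.39, 0.22
        printed = np.round(100.0 * np.round(pts, 2) / 3, 2)
        assert printed.tolist() == [0.0, 46.33, 13.0, 0.0, 0.0, 7.33]

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptySampleError):
            classify_sample(QuerySample(id="s", reads=[]), [_db(4, {"AAAA"})], ClassifierParams())

    def test_all_skipped_unassigned(self):
        sample = QuerySample(id="s", reads=["TTTT"])
        sv = classify_sample(sample, [_db(4, {"GGGG"})], ClassifierParams())
        assert sv.predicted_class is UNASSIGNED
        assert sv.similarities.tolist() == [0.0]

    def test_single_matched_read_contributes_one_point(self):
        sample = QuerySample(id="s", reads=["AAAAAA", "CCGGCC"])
        dbs = [_db(4, {"AAAA"}), _db(4, {"TGCA"})]
        for scheme in ("simple", "fractional", "weighted"):
            sv = classify_sample(sample, dbs, ClassifierParams(T=50, scheme=scheme))
            assert sv.similarities[0] == pytest.approx(100.0 / 2)
            assert sv.predicted_class == dbs[0].label or sv.predicted_class == "class_1"

    def test_tie_goes_to_lexicographically_smallest(self):
        sample = QuerySample(id="s", reads=["AAAAAA"])
        dbs = [
            KmerSet.from_strings(4, {"AAAA"}, label="zeta"),
            KmerSet.from_strings(4, {"AAAA"}, label="alpha"),
        ]
        sv = classify_sample(sample, dbs, ClassifierParams(T=50, scheme="fractional"))
        assert sv.tie_flag and sv.predicted_class == "alpha"

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(dna, min_size=1, max_size=6),
        st.sampled_from(["fractional", "weighted"]),
    )
    def test_similarity_sums_to_matched_fraction(self, reads, scheme):
        """Sum of similarities == 100 * matched/q for conserving schemes."""
        dbs = [_db(4, {"AAAA", "ACGT"}), _db(4, {"GGGG", "CCCC"})]
        sample = QuerySample(id="s", reads=reads)
        sv = classify_sample(sample, dbs, ClassifierParams(T=10, scheme=scheme))
        assert sv.similarities.sum() == pytest.approx(
            100.0 * sv.matched_read_count / sample.q, abs=1e-9
        )
        assert sv.similarities.sum() <= 100.0 + 1e-9
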