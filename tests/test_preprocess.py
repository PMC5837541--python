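"""Non-wear detection, state categorization and participant validation."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actibigram import (
    CutPoints,
    EpochSeries,
    ValidityRules,
    categorize,
    detect_nonwear,
    pad_trailing,
    validate_participant,
    wear_summaries,
)
from actibigram.preprocess import (
    EmptyInputError,
    InvalidCountsError,
    UndefinedSummaryError,
)


def series(counts, n_days=1, epochs_per_day=None, pid="p"):
    counts = np.asarray(counts, dtype=np.int64)
    if epochs_per_day is None:
        epochs_per_day = max(1, -(-counts.size // n_days))
    return EpochSeries(pid, counts, n_days=n_days, epochs_per_day=epochs_per_day)


class TestNonwearDetection:
    @pytest.mark.parametrize(
        "run_len,expect_masked",
        [(61, True), (60, False), (100, True), (1, False)],
    )
    def test_zero_run_length_threshold(self, run_len, expect_masked):
        """Only zero runs strictly longer than 60 epochs become non-wear."""
        counts = [50] * 10 + [0] * run_len + [50] * 10
        out = detect_nonwear(series(counts))
        run = out.missing_mask[10 : 10 + run_len]
        flanks = np.concatenate([out.missing_mask[:10], out.missing_mask[10 + run_len :]])
        assert run.all() if expect_masked else not run.any()
        assert not flanks.any()

    def test_all_nonzero_unmasked(self):
        out = detect_nonwear(series([5, 10, 3, 900]))
        assert not out.missing_mask.any()

    def test_empty_sequence_rejected(self):
        with pytest.raises(EmptyInputError):
            detect_nonwear(series([]))

    def test_run_at_sequence_edges_masked(self):
        counts = [0] * 61 + [50] * 5 + [0] * 61
        out = detect_nonwear(series(counts))
        assert out.missing_mask[:61].all() and out.missing_mask[-61:].all()
        assert not out.missing_mask[61:66].any()

    @given(st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=400))
    def test_idempotent(self, counts):
        """Re-running detection on its own output changes nothing."""
        once = detect_nonwear(series(counts), ValidityRules(nonwear_run_min_epochs=5))
        twice = detect_nonwear(once, ValidityRules(nonwear_run_min_epochs=5))
        assert np.array_equal(once.missing_mask, twice.missing_mask)


class TestCategorize:
    def test_default_cutpoint_boundaries(self):
        """100/101, 2019/2020, 5998/5999 are the exact S/L, L/M, M/V edges."""
        s = series([0, 100, 101, 2019, 2020, 5998, 5999])
        assert str(categorize(s)) == "SSLLMMV"

    def test_mask_takes_precedence_over_counts(self):
        counts = [50] * 5 + [0] * 70 + [50] * 5
        seq = categorize(detect_nonwear(series(counts)))
        assert str(seq) == "S" * 5 + "." * 70 + "S" * 5

    def test_custom_cutpoints(self):
        cuts = CutPoints(sedentary_max=10, low_max=20, moderate_max=30)
        assert str(categorize(series([10, 11, 21, 31]), cuts)) == "SLMV"

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidCountsError):
            series([5, -1, 3])

    @given(st.lists(st.integers(min_value=0, max_value=20000), min_size=1, max_size=300))
    def test_total_on_nonnegative_counts(self, counts):
        """Every worn epoch maps to exactly one state; lengths are conserved."""
        seq = categorize(detect_nonwear(series(counts)))
        tallies = {sym: int((seq.states == sym).sum()) for sym in "SLMV."}
        assert sum(tallies.values()) == len(counts)
        assert set(np.unique(seq.states)) <= set("SLMV.")


class TestWearSummaries:
    def test_constant_series(self):
        summary = wear_summaries(series([500] * 20))
        assert summary.mcpm == 500 and summary.sdcpm == 0

    def test_two_point_mean(self):
        assert wear_summaries(series([100, 300])).mcpm == 200

    def test_matches_bruteforce_on_random_masked_series(self):
        """mCPM/sdCPM equal direct summation over the worn epochs."""
        rng = np.random.default_rng(42)
        counts = rng.integers(0, 3000, size=2000)
        s = series(counts, n_days=2, epochs_per_day=1000)
        s.missing_mask = rng.random(2000) < 0.3
        summary = wear_summaries(s)
        worn = [float(c) for c, m in zip(counts, s.missing_mask) if not m]
        mean = sum(worn) / len(worn)
        sd = (sum((v - mean) ** 2 for v in worn) / (len(worn) - 1)) ** 0.5
        assert summary.mcpm == pytest.approx(mean, rel=1e-12)
        assert summary.sdcpm == pytest.approx(sd, rel=1e-12)
        by_day = [int((~s.missing_mask[:1000]).sum()), int((~s.missing_mask[1000:]).sum())]
        assert summary.wear_epochs_per_day.tolist() == by_day

    def test_zero_wear_undefined(self):
        s = series([0] * 100)
        s.missing_mask[:] = True
        with pytest.raises(UndefinedSummaryError):
            wear_summaries(s)


def day_counts(wear_per_day, epochs_per_day=1440, level=300):
    """Counts with a given number of worn (nonzero) epochs at each day start."""
    chunks = []
    for w in wear_per_day:
        chunks += [level] * w + [0] * (epochs_per_day - w)
    return chunks


class TestValidateParticipant:
    def test_all_rules_pass(self):
        s = series(day_counts([500] * 7), n_days=7, epochs_per_day=1440)
        report = validate_participant(detect_nonwear(s))
        assert report.valid and report.reasons == []
        assert report.n_valid_days == 7 and report.mcpm == 300

    def test_too_few_valid_days(self):
        s = series(day_counts([500, 500, 100, 100, 100, 100, 100]),
                   n_days=7, epochs_per_day=1440)
        report = validate_participant(detect_nonwear(s))
        assert not report.valid
        assert report.n_valid_days == 2
        assert any("fewer than three valid days" in r for r in report.reasons)

    def test_mean_cpm_cap(self):
        s = series([1501] * (7 * 1440), n_days=7, epochs_per_day=1440)
        report = validate_participant(detect_nonwear(s))
        assert not report.valid
        assert any("mean cpm exceeds 1500" in r for r in report.reasons)
        # boundary: exactly 1500 is allowed
        s_ok = series([1500] * (7 * 1440), n_days=7, epochs_per_day=1440)
        assert validate_participant(detect_nonwear(s_ok)).valid

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            validate_participant(series([]))


class TestSequenceLength:
    def test_overlong_sequence_rejected(self):
        with pytest.raises(ValueError):
            EpochSeries("p", np.ones(11, dtype=int), n_days=1, epochs_per_day=10)

    def test_pad_trailing_marks_missing(self):
        s = EpochSeries("p", np.full(7, 50), n_days=1, epochs_per_day=10)
        padded = pad_trailing(s)
        assert len(padded) == 10
        assert padded.missing_mask.tolist() == [False] * 7 + [True] * 3
        # padding survives non-wear detection even though the pad run is short
        assert detect_nonwear(padded).missing_mask[-3:].all()
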