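"""Bigram and u-bigram frequency profiles from activity-state sequences.

An *epoch pair* is two consecutive epochs; pairs overlap, so a sequence of
n epochs contains n-1 of them. The bigram AB counts pairs that are in state
A at time t and state B at time t+1; its per-day frequency is

    b(A,B) = (1/D) * sum_{i=1..n-1} 1[x_i = A and x_{i+1} = B]

for D recorded days. With four states there are 16 bigrams. The unordered
variant (u-bigram) [AB] pools reciprocal bigrams, bu[AB] = b(A,B) + b(B,A)
for A != B and bu[AA] = b(A,A), giving 10 u-bigrams. Pairs that touch a
missing (non-wear) epoch contribute to no bigram; pairs spanning a day
boundary inside the continuous recording do count.

Because pairs overlap, a bigram's frequency does not map to a fixed amount
of time: SSSLS and SSLSS both contain two SS pairs, covering 3 and 4
distinct minutes respectively (:func:`bigram_minute_span` measures this).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import (
    MISSING,
    STATES,
    CutPoints,
    EpochSeries,
    StateSequence,
    UndefinedSummaryError,
    ValidityRules,
    categorize,
    detect_nonwear,
    validate_participant,
    wear_summaries,
)

#: The 16 ordered bigrams in fixed (row-major) order: SS, SL, ..., VV.
BIGRAMS: tuple[str, ...] = tuple(a + b for a in STATES for b in STATES)

#: The 10 u-bigrams in fixed order: [SS], [SL], ..., [VV].
UBIGRAMS: tuple[str, ...] = tuple(
    f"[{STATES[i]}{STATES[j]}]"
    for i in range(len(STATES))
    for j in range(i, len(STATES))
)

#: State-minutes-per-day columns: Sd, Ld, Md, Vd.
DURATION_COLUMNS: tuple[str, ...] = tuple(s + "d" for s in STATES)

#: Fixed column order of the per-participant feature table.
FEATURE_COLUMNS: tuple[str, ...] = (
    ("participant_id",)
    + BIGRAMS
    + UBIGRAMS
    + DURATION_COLUMNS
    + ("mCPM", "sdCPM", "D", "n_valid_pairs")
)

_STATE_CODE = {s: i for i, s in enumerate(STATES)}


def ubigram_key(a: str, b: str) -> str:
    """Canonical u-bigram key for an unordered state pair, e.g. ``[MV]``."""
    i, j = sorted((_STATE_CODE[a], _STATE_CODE[b]))
    return f"[{STATES[i]}{STATES[j]}]"


_CODE_LUT = np.full(128, -1, dtype=np.int8)
for _s, _c in _STATE_CODE.items():
    _CODE_LUT[ord(_s)] = _c


def _codes(seq: StateSequence) -> np.ndarray:
    """States as integer codes 0..3, with -1 for missing epochs."""
    # a '<U1' array is UCS-4, so a view exposes the code points directly
    ords = seq.states.view(np.uint32)
    return _CODE_LUT[ords].astype(np.int64)


def _pair_codes(codes: np.ndarray) -> np.ndarray:
    """Codes 0..15 of adjacent pairs with both epochs non-missing."""
    a, b = codes[:-1], codes[1:]
    valid = (a >= 0) & (b >= 0)
    return 4 * a[valid] + b[valid]


def count_bigrams(seq: StateSequence) -> dict[str, int]:
    """Raw occurrence counts of all 16 bigrams over adjacent epoch pairs.

    Every adjacent index pair (i, i+1) of the full multi-day sequence is
    inspected, including pairs spanning day boundaries; pairs touching a
    missing epoch are skipped. A length-1 sequence has no pairs and yields
    all zeros.
    """
    if len(seq) == 0:
        return {bg: 0 for bg in BIGRAMS}
    tallies = np.bincount(_pair_codes(_codes(seq)), minlength=16)
    return {bg: int(tallies[i]) for i, bg in enumerate(BIGRAMS)}


def n_valid_pairs(seq: StateSequence) -> int:
    """Number of adjacent epoch pairs with both epochs non-missing."""
    if len(seq) == 0:
        return 0
    return int(_pair_codes(_codes(seq)).size)


@dataclass
class BigramProfile:
    """Average-per-day frequencies of the 16 ordered bigrams.

    Invariant: sum over all b(A,B) times D equals ``n_valid_pairs``.
    """

    b: dict[str, float]
    D: float
    n_valid_pairs: int


@dataclass
class UBigramProfile:
    """Average-per-day frequencies of the 10 unordered bigrams."""

    bu: dict[str, float]
    D: float


@dataclass
class StateDurations:
    """Average minutes per day spent in each activity state."""

    Sd: float
    Ld: float
    Md: float
    Vd: float
    D: float

    def as_dict(self) -> dict[str, float]:
        return {"Sd": self.Sd, "Ld": self.Ld, "Md": self.Md, "Vd": self.Vd}


def bigram_profile(seq: StateSequence, D: float) -> BigramProfile:
    """Per-day bigram frequencies: raw pair counts divided by D days."""
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    raw = count_bigrams(seq)
    return BigramProfile(
        b={bg: raw[bg] / D for bg in BIGRAMS},
        D=D,
        n_valid_pairs=sum(raw.values()),
    )


def ubigram_profile(profile: BigramProfile) -> UBigramProfile:
    """Pool reciprocal bigrams into the 10 u-bigram frequencies.

    bu[AB] = b(A,B) + b(B,A) for A != B; bu[AA] = b(A,A) (each same-state
    pair satisfies both indicator clauses at once, so it counts once).
    """
    bu: dict[str, float] = {}
    for key in UBIGRAMS:
        a, b = key[1], key[2]
        bu[key] = profile.b[a + b] if a == b else profile.b[a + b] + profile.b[b + a]
    return UBigramProfile(bu=bu, D=profile.D)


def state_durations(seq: StateSequence, D: float) -> StateDurations:
    """Minutes per day in each state: non-missing epoch tallies over D days."""
    if D <= 0:
        raise ValueError(f"D must be positive, got {D}")
    codes = _codes(seq)
    tallies = np.bincount(codes[codes >= 0], minlength=4)
    sd, ld, md, vd = (tallies / D).tolist()
    return StateDurations(Sd=sd, Ld=ld, Md=md, Vd=vd, D=D)


def bigram_minute_span(seq: StateSequence, pair: str | tuple[str, str]) -> int:
    """Distinct epochs covered by at least one occurrence of a bigram.

    Diagnostic for the overlap effect: because epoch pairs overlap, equal
    bigram frequencies can cover different amounts of time (SSSLS and SSLSS
    both have two SS pairs, over 3 and 4 minutes).
    """
    if isinstance(pair, str):
        a, b = pair[0], pair[1]
    else:
        a, b = pair
    codes = _codes(seq)
    ca, cb = _STATE_CODE[a], _STATE_CODE[b]
    hits = np.flatnonzero((codes[:-1] == ca) & (codes[1:] == cb))
    return int(np.union1d(hits, hits + 1).size)


def _restrict_to_valid_days(
    series: EpochSeries, rules: ValidityRules
) -> tuple[EpochSeries, int]:
    """Mask whole days with under the minimum wear time; return valid-day count.

    Removed days become missing, so epoch pairs touching them drop out of
    the bigram counts while pairs across the boundary of two adjacent
    retained days are kept.
    """
    report = validate_participant(series, rules)
    masked = series.missing_mask.copy()
    for d, sl in enumerate(series.day_slices()):
        if d < report.valid_day_flags.size and not report.valid_day_flags[d]:
            masked[sl] = True
    out = EpochSeries(
        participant_id=series.participant_id,
        counts=series.counts,
        n_days=series.n_days,
        epochs_per_day=series.epochs_per_day,
        missing_mask=masked,
    )
    return out, report.n_valid_days


def participant_features(
    series: EpochSeries,
    cuts: CutPoints | None = None,
    rules: ValidityRules | None = None,
    day_policy: str = "all_days",
) -> dict[str, float | str | int]:
    """One participant's full feature row (non-wear must not yet be applied).

    ``day_policy`` selects the frequency divisor: ``all_days`` uses every
    recorded day (D = n_days) regardless of wear; ``valid_days_only``
    restricts the sequence to days with at least 8 h wear, drops pairs
    touching removed days, and divides by the number of valid days.
    """
    cuts = cuts or CutPoints()
    rules = rules or ValidityRules()
    series = detect_nonwear(series, rules)
    if day_policy == "all_days":
        D = float(series.n_days)
    elif day_policy == "valid_days_only":
        series, n_valid = _restrict_to_valid_days(series, rules)
        if n_valid == 0:
            raise UndefinedSummaryError(
                f"participant {series.participant_id!r} has no valid days"
            )
        D = float(n_valid)
    else:
        raise ValueError(f"unknown day_policy {day_policy!r}")
    seq = categorize(series, cuts)
    prof = bigram_profile(seq, D)
    uprof = ubigram_profile(prof)
    durs = state_durations(seq, D)
    summary = wear_summaries(series)
    row: dict[str, float | str | int] = {"participant_id": series.participant_id}
    row.update(prof.b)
    row.update(uprof.bu)
    row.update(durs.as_dict())
    row.update(
        mCPM=summary.mcpm,
        sdCPM=summary.sdcpm,
        D=D,
        n_valid_pairs=prof.n_valid_pairs,
    )
    return row


def cohort_features(
    cohort: list[EpochSeries],
    cuts: CutPoints | None = None,
    rules: ValidityRules | None = None,
    day_policy: str = "all_days",
) -> pd.DataFrame:
    """Feature table for a cohort, one row per participant, fixed columns."""
    rows = [participant_features(s, cuts, rules, day_policy) for s in cohort]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
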