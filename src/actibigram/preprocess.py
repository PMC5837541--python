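"""Pre-processing of minute-epoch accelerometer count sequences.

A participant's recording is a sequence of integer activity counts, one per
1-minute epoch, laid out as ``n_days`` consecutive blocks of
``epochs_per_day`` epochs from the recording start (no realignment to
calendar midnight). Pre-processing has three stages:

1. non-wear detection — maximal runs of zero counts strictly longer than an
   hour are treated as time the device was not worn and masked as missing;
2. state categorization — each worn epoch is mapped onto one of four
   activity states, Sedentary / Low / Moderate / Vigorous, by count
   cut-points (defaults: S 0-100, L 101-2019, M 2020-5998, V 5999+
   counts/min, the conventional uni-axial waist cut-points for children);
3. participant validation — a day is valid with at least 8 h of wear; a
   participant is valid with at least 3 valid days and a wear-time mean
   count level of at most 1500 counts/min.

Zero counts that survive non-wear masking are ordinary sedentary time.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Activity-state alphabet, ordered from least to most intense.
STATES: tuple[str, ...] = ("S", "L", "M", "V")

#: Sentinel state for masked (non-wear) epochs.
MISSING: str = "."


class EmptyInputError(ValueError):
    """Raised when an operation receives an empty count sequence."""


class InvalidCountsError(ValueError):
    """Raised when activity counts are negative or non-integral."""


class UndefinedSummaryError(ValueError):
    """Raised when a summary is requested over zero wear epochs."""


@dataclass(frozen=True)
class CutPoints:
    """Count thresholds (counts/min) separating the four activity states.

    An epoch with count ``c`` is S if ``c <= sedentary_max``, L if
    ``sedentary_max < c <= low_max``, M if ``low_max < c <= moderate_max``
    and V otherwise.
    """

    sedentary_max: int = 100
    low_max: int = 2019
    moderate_max: int = 5998

    def __post_init__(self) -> None:
        if not (0 <= self.sedentary_max < self.low_max < self.moderate_max):
            raise ValueError(
                "cut-points must satisfy 0 <= sedentary_max < low_max < moderate_max, "
                f"got {self.sedentary_max}, {self.low_max}, {self.moderate_max}"
            )

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([self.sedentary_max, self.low_max, self.moderate_max])


@dataclass(frozen=True)
class ValidityRules:
    """Non-wear and participant-validity parameters.

    nonwear_run_min_epochs
        Minimum length (epochs) of a zero run that counts as non-wear.
        The default 61 encodes "strictly longer than 60 epochs (1 hour)":
        a run of exactly 60 zeros remains wear time.
    valid_day_min_wear_epochs
        Wear epochs a day needs to be valid (default 480 = 8 h).
    min_valid_days
        Valid days a participant needs (default 3).
    max_mean_cpm
        Upper bound on the wear-time mean counts/min; higher values are
        deemed infeasible device output (default 1500).
    """

    nonwear_run_min_epochs: int = 61
    valid_day_min_wear_epochs: int = 480
    min_valid_days: int = 3
    max_mean_cpm: float = 1500.0

    def __post_init__(self) -> None:
        for name in (
            "nonwear_run_min_epochs",
            "valid_day_min_wear_epochs",
            "min_valid_days",
            "max_mean_cpm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochSeries:
    """One participant's per-minute activity counts with day structure.

    ``counts`` holds non-negative integer counts per 1-min epoch, ordered
    from recording start; ``missing_mask`` is True where the epoch is
    treated as missing (non-wear). Day ``d`` is the epoch block
    ``[d * epochs_per_day, (d + 1) * epochs_per_day)``.
    """

    participant_id: str
    counts: np.ndarray
    n_days: int = 7
    epochs_per_day: int = 1440
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise InvalidCountsError("counts must be a 1-D sequence")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64, casting="unsafe")
            if self.counts.size and not np.array_equal(as_int, self.counts):
                raise InvalidCountsError("counts must be integers")
            self.counts = as_int
        if self.counts.size and self.counts.min() < 0:
            raise InvalidCountsError("counts must be non-negative")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.counts.size, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.size != self.counts.size:
            raise ValueError("missing_mask must align 1:1 with counts")
        if self.n_days <= 0 or self.epochs_per_day <= 0:
            raise ValueError("n_days and epochs_per_day must be positive")
        if self.counts.size > self.n_days * self.epochs_per_day:
            raise ValueError(
                f"sequence of {self.counts.size} epochs exceeds "
                f"{self.n_days} days x {self.epochs_per_day} epochs/day"
            )

    def __len__(self) -> int:
        return self.counts.size

    @property
    def is_full_length(self) -> bool:
        return self.counts.size == self.n_days * self.epochs_per_day

    def day_slices(self) -> list[slice]:
        """Fixed epoch blocks for each recorded day (last may be partial)."""
        nd = self.epochs_per_day
        return [
            slice(d * nd, min((d + 1) * nd, self.counts.size))
            for d in range(self.n_days)
        ]


@dataclass
class StateSequence:
    """Categorical activity-state sequence aligned 1:1 with an EpochSeries.

    ``states`` is an array over {S, L, M, V} with '.' marking missing
    (non-wear) epochs.
    """

    states: np.ndarray
    n_days: int = 7
    epochs_per_day: int = 1440
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        ords = self.states.view(np.uint32) if self.states.size else np.array([], dtype=np.uint32)
        allowed = np.array([ord(s) for s in STATES] + [ord(MISSING)], dtype=np.uint32)
        bad = ~np.isin(ords, allowed)
        if bad.any():
            symbols = sorted(set(self.states[bad].tolist()))
            raise ValueError(f"unexpected state symbols: {symbols}")

    def __len__(self) -> int:
        return self.states.size

    def __str__(self) -> str:
        return "".join(self.states.tolist())

    @classmethod
    def from_string(
        cls,
        text: str,
        n_days: int = 1,
        epochs_per_day: int | None = None,
        participant_id: str = "",
    ) -> "StateSequence":
        """Build a sequence from a string like ``"SSSLS"`` ('.' = missing)."""
        arr = np.array(list(text), dtype="<U1")
        if epochs_per_day is None:
            epochs_per_day = max(1, int(np.ceil(len(text) / n_days)))
        return cls(arr, n_days=n_days, epochs_per_day=epochs_per_day,
                   participant_id=participant_id)


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as half-open (start, stop) index pairs."""
    is_zero = counts == 0
    if not is_zero.any():
        return []
    padded = np.concatenate(([False], is_zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[0::2], edges[1::2]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_nonwear(series: EpochSeries, rules: ValidityRules | None = None) -> EpochSeries:
    """Mask maximal zero-count runs longer than the non-wear threshold.

    Returns a new :class:`EpochSeries` whose ``missing_mask`` is True exactly
    on maximal runs of zero counts of length >= ``nonwear_run_min_epochs``
    (default 61, i.e. strictly more than one hour of consecutive zeros).
    Epochs already masked (e.g. trailing padding) stay masked. The zero-run
    mask depends on the counts alone, so the operation is idempotent.
    """
    if rules is None:
        rules = ValidityRules()
    if len(series) == 0:
        raise EmptyInputError("cannot detect non-wear on an empty sequence")
    mask = series.missing_mask.copy()
    for start, stop in _zero_runs(series.counts):
        if stop - start >= rules.nonwear_run_min_epochs:
            mask[start:stop] = True
    return replace(series, missing_mask=mask)


def categorize(series: EpochSeries, cuts: CutPoints | None = None) -> StateSequence:
    """Map each worn epoch onto an activity state via count cut-points.

    Missing (non-wear) epochs map to '.'; every worn epoch maps to exactly
    one of S/L/M/V, so categorization is total on non-negative counts.
    """
    if cuts is None:
        cuts = CutPoints()
    if series.counts.size and series.counts.min() < 0:
        raise InvalidCountsError("counts must be non-negative")
    idx = np.searchsorted(cuts.thresholds, series.counts, side="left")
    states = np.array(STATES, dtype="<U1")[idx]
    states[series.missing_mask] = MISSING
    return StateSequence(
        states,
        n_days=series.n_days,
        epochs_per_day=series.epochs_per_day,
        participant_id=series.participant_id,
    )


@dataclass
class WearSummary:
    """Wear-time count summaries for one participant."""

    mcpm: float                    # mean counts/min over worn epochs
    sdcpm: float                   # sample SD of counts/min over worn epochs
    wear_epochs_per_day: np.ndarray  # worn epochs in each fixed day block


def wear_summaries(series: EpochSeries) -> WearSummary:
    """Mean (mCPM) and sample SD (sdCPM) of counts over worn epochs.

    Raises :class:`UndefinedSummaryError` if no epoch is worn. With a single
    worn epoch the sample SD is reported as 0.0.
    """
    worn = ~series.missing_mask
    n_worn = int(worn.sum())
    if n_worn == 0:
        raise UndefinedSummaryError("no wear epochs: mCPM/sdCPM undefined")
    vals = series.counts[worn].astype(float)
    mcpm = float(vals.mean())
    sdcpm = float(vals.std(ddof=1)) if n_worn > 1 else 0.0
    per_day = np.array([int(worn[s].sum()) for s in series.day_slices()])
    return WearSummary(mcpm=mcpm, sdcpm=sdcpm, wear_epochs_per_day=per_day)


@dataclass
class ValidityReport:
    """Outcome of participant-level wear validation."""

    participant_id: str
    valid: bool
    reasons: list[str]
    valid_day_flags: np.ndarray
    n_valid_days: int
    mcpm: float
    sdcpm: float


def validate_participant(
    series: EpochSeries, rules: ValidityRules | None = None
) -> ValidityReport:
    """Apply the valid-day and mean-count participant filters.

    A day is valid with at least ``valid_day_min_wear_epochs`` worn epochs;
    a participant is valid with at least ``min_valid_days`` valid days and a
    wear-time mean of at most ``max_mean_cpm`` counts/min. The wear-time
    (not whole-recording) mean is used, consistent with mCPM's definition.
    """
    if rules is None:
        rules = ValidityRules()
    if series.n_days == 0 or len(series) == 0:
        raise EmptyInputError("no recorded days to validate")
    reasons: list[str] = []
    try:
        summary = wear_summaries(series)
        mcpm, sdcpm = summary.mcpm, summary.sdcpm
        wear_per_day = summary.wear_epochs_per_day
    except UndefinedSummaryError:
        mcpm, sdcpm = float("nan"), float("nan")
        wear_per_day = np.zeros(series.n_days, dtype=int)
        reasons.append("no wear time")
    day_flags = wear_per_day >= rules.valid_day_min_wear_epochs
    n_valid = int(day_flags.sum())
    if n_valid < rules.min_valid_days:
        reasons.append(f"fewer than {_spell(rules.min_valid_days)} valid days")
    if np.isfinite(mcpm) and mcpm > rules.max_mean_cpm:
        reasons.append(f"mean cpm exceeds {rules.max_mean_cpm:g}")
    return ValidityReport(
        participant_id=series.participant_id,
        valid=not reasons,
        reasons=reasons,
        valid_day_flags=day_flags,
        n_valid_days=n_valid,
        mcpm=mcpm,
        sdcpm=sdcpm,
    )


def _spell(n: int) -> str:
    words = {2: "two", 3: "three", 4: "four", 5: "five"}
    return words.get(n, str(n))


def pad_trailing(series: EpochSeries) -> EpochSeries:
    """Pad a short recording to full length with trailing missing epochs.

    Recordings shorter than ``n_days * epochs_per_day`` are rejected by the
    readers by default; this helper appends zero-count epochs that are
    pre-masked as missing, for cohorts where trailing partial days should be
    kept rather than excluded.
    """
    total = series.n_days * series.epochs_per_day
    short = total - len(series)
    if short <= 0:
        return series
    counts = np.concatenate([series.counts, np.zeros(short, dtype=series.counts.dtype)])
    mask = np.concatenate([series.missing_mask, np.ones(short, dtype=bool)])
    return replace(series, counts=counts, missing_mask=mask)
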