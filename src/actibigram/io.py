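"""Readers and writers for the plain-text interchange formats.

Counts travel as long-format CSV (``participant_id,epoch_index,counts``,
epoch_index 0-based from recording start); state sequences as CSV with one
row per participant and the states packed into a string over S/L/M/V/'.';
feature tables, validity reports and association results as TSV with a
header row. Floats are written with 17 significant digits so that
re-reading an output reproduces the in-memory table exactly.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS
from .models import _RESULT_COLUMNS
from .preprocess import EpochSeries, StateSequence, ValidityReport, pad_trailing

FLOAT_FMT = "%.17g"


class CountsParseError(ValueError):
    """Raised for a malformed counts CSV; carries the offending line."""


def read_counts_csv(
    path: str | Path,
    n_days: int = 7,
    epochs_per_day: int = 1440,
    pad_partial: bool = False,
) -> list[EpochSeries]:
    """Read long-format counts into one :class:`EpochSeries` per participant.

    Epochs must be contiguous from 0 within each participant. Recordings
    shorter than ``n_days * epochs_per_day`` are rejected unless
    ``pad_partial`` is set, in which case trailing epochs are padded as
    missing.
    """
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "epoch_index", "counts"}
    if not required <= set(df.columns):
        raise CountsParseError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    for col in ("epoch_index", "counts"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals)) | (vals < 0)
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header is line 1
            raise CountsParseError(
                f"{path}, line {line}: non-integer or negative {col!r}"
            )
        df[col] = vals.astype(np.int64)
    out: list[EpochSeries] = []
    for pid, grp in df.groupby("participant_id", sort=True):
        grp = grp.sort_values("epoch_index")
        idx = grp["epoch_index"].to_numpy()
        if not np.array_equal(idx, np.arange(idx.size)):
            raise CountsParseError(
                f"{path}: participant {pid!r} epochs are not contiguous from 0"
            )
        series = EpochSeries(
            participant_id=str(pid),
            counts=grp["counts"].to_numpy(),
            n_days=n_days,
            epochs_per_day=epochs_per_day,
        )
        if not series.is_full_length:
            if not pad_partial:
                raise CountsParseError(
                    f"{path}: participant {pid!r} has {len(series)} epochs, "
                    f"expected {n_days * epochs_per_day} (use pad_partial to keep)"
                )
            series = pad_trailing(series)
        out.append(series)
    if not out:
        raise CountsParseError(f"{path}: no participants found")
    return out


def write_counts_csv(cohort: list[EpochSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": s.participant_id,
                "epoch_index": np.arange(len(s)),
                "counts": s.counts,
            }
        )
        for s in cohort
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_state_sequences(seqs: list[StateSequence], path: str | Path) -> None:
    """One row per participant: id plus the packed S/L/M/V/'.' string."""
    pd.DataFrame(
        {"participant_id": [s.participant_id for s in seqs],
         "states": [str(s) for s in seqs]}
    ).to_csv(path, index=False)


def read_state_sequences(
    path: str | Path, n_days: int = 7, epochs_per_day: int = 1440
) -> list[StateSequence]:
    df = pd.read_csv(path, dtype=str)
    return [
        StateSequence.from_string(
            row["states"], n_days=n_days, epochs_per_day=epochs_per_day,
            participant_id=row["participant_id"],
        )
        for _, row in df.iterrows()
    ]


def write_validity_report(reports: list[ValidityReport], path: str | Path) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in reports],
            "valid": [r.valid for r in reports],
            "reasons": ["; ".join(r.reasons) for r in reports],
            "n_valid_days": [r.n_valid_days for r in reports],
            "mCPM": [r.mcpm for r in reports],
            "sdCPM": [r.sdcpm for r in reports],
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    features[list(FEATURE_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str})


def write_association_results(results: pd.DataFrame, path: str | Path) -> None:
    results[list(_RESULT_COLUMNS)].to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def read_association_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    """Participant phenotype table: outcome and covariates keyed by id."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise CountsParseError(f"{path}: phenotype table needs a participant_id column")
    return df


def write_phenotypes_csv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False, float_format=FLOAT_FMT)
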